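"""Genotype-stratified survival validation: KM, log-rank, Cox PH, LD and concordance QC.

The validation stage of the pipeline tests whether a candidate SNP's genotype
stratifies progression-free survival in an independent cohort. The estimators
are the field's standard ones — the Kaplan–Meier product-limit curve with
Greenwood variance, the k-sample log-rank test, and a Cox proportional-hazards
model with Efron tie handling, adjusted for tumour stage, reporting the hazard
ratio with a Wald 95% CI. Pairwise linkage disequilibrium between candidate
SNPs is estimated from unphased genotypes by an EM algorithm over the
double-heterozygote phase ambiguity, and platform concordance (NGS vs array)
is a per-sample agreement rate.

Kaplan–Meier estimation is delegated to ``statsmodels`` (SurvfuncRight), Cox
fits to ``lifelines`` (Efron) or ``statsmodels`` PHReg (Breslow), and the
log-rank test to ``lifelines``; the EM haplotype-frequency estimator is local.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test
from statsmodels.duration.hazard_regression import PHReg
from statsmodels.duration.survfunc import SurvfuncRight

from .core_io import MISSING, GenotypeMatrix, SurvivalRecord

__all__ = [
    "KMCurve",
    "CoxResult",
    "LDResult",
    "km_estimate",
    "logrank_test",
    "cox_fit",
    "genotype_strata",
    "genotype_allele_counts",
    "ld_pairwise",
    "concordance",
]

#: Wald standard errors above this are treated as monotone-likelihood blowup.
_SE_DIVERGED = 50.0


@dataclass
class KMCurve:
    """Product-limit survival estimate at the distinct event times."""

    times: np.ndarray  # distinct event times, ascending
    survival: np.ndarray  # S(t) just after each event time
    n_risk: np.ndarray  # subjects at risk at each event time
    variance: np.ndarray  # Greenwood variance of S(t)

    @property
    def median(self) -> float | None:
        """Smallest event time with S(t) <= 0.5, or None if S never reaches it."""
        below = np.nonzero(self.survival <= 0.5)[0]
        return float(self.times[below[0]]) if below.size else None

    def at(self, t: float) -> float:
        """S(t): right-continuous step function, S = 1 before the first event."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class CoxResult:
    """Per-term Cox PH estimates (Wald inference on the log-hazard scale)."""

    terms: list[str]
    beta: dict[str, float]
    se: dict[str, float]
    hr: dict[str, float]
    ci95: dict[str, tuple[float, float] | None]
    wald_p: dict[str, float | None]
    converged: bool
    n_iterations: int | None = None
    ties: str = "efron"


@dataclass
class LDResult:
    """Pairwise linkage disequilibrium from EM haplotype frequencies."""

    D: float
    Dprime: float
    r2: float
    haplotype_freqs: dict[str, float]  # keys AB, Ab, aB, ab (A/B = alt alleles)
    converged: bool
    n_iterations: int


def _to_frame(records: Sequence[SurvivalRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "time": [r.time for r in records],
            "event": [r.event for r in records],
            "group": [r.group for r in records],
            "stage": [r.stage for r in records],
        }
    )


def km_estimate(records: Sequence[SurvivalRecord]) -> KMCurve:
    """Kaplan–Meier curve over a set of survival records.

    Subjects censored exactly at an event time are counted at risk for that
    time and removed afterwards (the standard convention). With no events the
    curve is identically 1 and the median undefined.
    """
    if not records:
        raise ValueError("no survival records")
    time = np.array([r.time for r in records], dtype=float)
    event = np.array([r.event for r in records], dtype=int)
    if event.sum() == 0:
        return KMCurve(
            np.empty(0), np.empty(0), np.empty(0, dtype=int), np.empty(0)
        )
    sf = SurvfuncRight(time, event)
    var = np.square(np.nan_to_num(sf.surv_prob_se, nan=0.0))
    return KMCurve(
        np.asarray(sf.surv_times, dtype=float),
        np.asarray(sf.surv_prob, dtype=float),
        np.asarray(sf.n_risk, dtype=int),
        var,
    )


def logrank_test(groups: Mapping[str, Sequence[SurvivalRecord]]) -> tuple[float, int, float]:
    """k-sample log-rank test; returns (chi-square statistic, df, p)."""
    if len(groups) < 2:
        raise ValueError("log-rank test needs >= 2 groups")
    for name, recs in groups.items():
        if len(recs) == 0:
            raise ValueError(f"log-rank group {name!r} is empty")
    time, event, label = [], [], []
    for name, recs in groups.items():
        for r in recs:
            time.append(r.time)
            event.append(r.event)
            label.append(name)
    res = multivariate_logrank_test(
        np.asarray(time), np.asarray(label), np.asarray(event)
    )
    df = len(groups) - 1
    return float(res.test_statistic), df, float(res.p_value)


def cox_fit(
    records: Sequence[SurvivalRecord],
    covariates: Sequence[str] = ("group", "stage"),
    ties: str = "efron",
    risk_group: str | None = None,
) -> CoxResult:
    """Fit a Cox proportional-hazards model by partial-likelihood maximization.

    ``group`` enters as a binary indicator of the risk stratum (``risk_group``;
    defaults to the lexicographically first label, which puts the
    homozygous-reference stratum first under the ``"C/C"`` vs ``"C/T or T/T"``
    labelling); ``stage`` enters as an ordinal numeric covariate. Constant
    covariates are dropped with a warning (beta fixed at 0). Monotone partial
    likelihood (perfect separation) is reported as ``converged=False`` with no
    CI for the diverged term.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")
    df = _to_frame(records)
    if int(df["event"].sum()) < 1:
        raise ValueError("Cox fit requires at least one observed event")
    design = pd.DataFrame(index=df.index)
    for cov in covariates:
        if cov == "group":
            labels = sorted(df["group"].unique())
            rg = risk_group if risk_group is not None else labels[0]
            if rg not in labels:
                raise ValueError(f"risk_group {rg!r} not among group labels {labels}")
            design["group"] = (df["group"] == rg).astype(float)
        elif cov == "stage":
            design["stage"] = df["stage"].astype(float)
        else:
            raise ValueError(f"unknown covariate {cov!r}")
    dropped = [c for c in design.columns if design[c].nunique() <= 1]
    if dropped:
        warnings.warn(f"constant covariates dropped from Cox fit: {dropped}")
        design = design.drop(columns=dropped)
    terms = list(design.columns)
    if not terms:
        return CoxResult(
            [], {c: 0.0 for c in covariates}, {}, {}, {}, {}, converged=True, ties=ties
        )

    if ties == "efron":
        beta, se, n_iter, diverged = _fit_efron(df, design)
    else:
        beta, se, n_iter, diverged = _fit_breslow(df, design)

    hr = {t: float(np.exp(beta[t])) for t in terms}
    ci95: dict[str, tuple[float, float] | None] = {}
    wald_p: dict[str, float | None] = {}
    from scipy import stats

    for t in terms:
        if diverged or not np.isfinite(se[t]) or se[t] > _SE_DIVERGED:
            ci95[t] = None
            wald_p[t] = None
        else:
            lo, hi = beta[t] - 1.96 * se[t], beta[t] + 1.96 * se[t]
            ci95[t] = (float(np.exp(lo)), float(np.exp(hi)))
            z = beta[t] / se[t]
            wald_p[t] = float(2 * stats.norm.sf(abs(z)))
    for c in covariates:
        if c in dropped:
            beta[c] = 0.0
            hr[c] = 1.0
            se[c] = float("nan")
            ci95[c] = None
            wald_p[c] = None
    return CoxResult(
        terms, beta, se, hr, ci95, wald_p, converged=not diverged,
        n_iterations=n_iter, ties=ties,
    )


def _fit_efron(df: pd.DataFrame, design: pd.DataFrame):
    data = design.copy()
    data["time"] = df["time"].to_numpy()
    data["event"] = df["event"].to_numpy()
    fitter = CoxPHFitter()
    diverged = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            fitter.fit(data, duration_col="time", event_col="event")
        except ConvergenceError:
            diverged = True
    if diverged:
        # refit loosely to recover the direction of divergence
        fitter = CoxPHFitter(penalizer=1e-6)
        fitter.fit(data, duration_col="time", event_col="event")
    else:
        diverged = any("convergence" in str(w.message).lower() for w in caught) and bool(
            (fitter.standard_errors_ > _SE_DIVERGED).any()
        )
    beta = {t: float(fitter.params_[t]) for t in design.columns}
    se = {t: float(fitter.standard_errors_[t]) for t in design.columns}
    if any(s > _SE_DIVERGED for s in se.values()):
        diverged = True
    n_iter = getattr(fitter, "_n_iter", None)
    return beta, se, n_iter, diverged


def _fit_breslow(df: pd.DataFrame, design: pd.DataFrame):
    model = PHReg(
        df["time"].to_numpy(),
        design.to_numpy(dtype=float),
        status=df["event"].to_numpy(),
        ties="breslow",
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(disp=0)
    beta = {t: float(res.params[i]) for i, t in enumerate(design.columns)}
    se = {t: float(res.bse[i]) for i, t in enumerate(design.columns)}
    diverged = any(not np.isfinite(s) or s > _SE_DIVERGED for s in se.values())
    return beta, se, None, diverged


def genotype_strata(
    genotypes: Mapping[str, str], mode: str = "dominant", ref_allele: str | None = None
) -> dict[str, str]:
    """Map per-sample diploid genotype strings (e.g. ``"C/T"``) to strata.

    ``dominant`` (default) pools heterozygotes with alternate homozygotes:
    ``C/C`` vs ``C/T or T/T`` — the split used to validate the responder SNP.
    ``recessive`` isolates the alternate homozygote; ``additive`` keeps all
    three genotype classes. ``ref_allele`` names the genome reference allele;
    without it the more frequent allele is assumed reference (note the
    validated transporter SNP's reference C is the *minor* allele in Asian
    cohorts, so the pipeline passes it explicitly). The SNP must be biallelic.
    """
    alleles_per_sample = {}
    counts: dict[str, int] = {}
    for sample, g in genotypes.items():
        a = tuple(sorted(g.replace("|", "/").split("/")))
        if len(a) != 2:
            raise ValueError(f"{sample}: not a diploid genotype {g!r}")
        alleles_per_sample[sample] = a
        for al in a:
            counts[al] = counts.get(al, 0) + 1
    alleles = sorted(counts, key=lambda al: (-counts[al], al))
    if len(alleles) == 1:
        raise ValueError("monomorphic SNP: only one stratum")
    if len(alleles) > 2:
        raise ValueError(f"not biallelic: alleles {alleles}")
    if ref_allele is not None:
        if ref_allele not in alleles:
            raise ValueError(f"ref allele {ref_allele!r} not observed in {alleles}")
        ref = ref_allele
        alt = next(al for al in alleles if al != ref)
    else:
        ref, alt = alleles
    hom_ref = f"{ref}/{ref}"
    carrier = f"{ref}/{alt} or {alt}/{alt}"
    hom_alt = f"{alt}/{alt}"
    out = {}
    for sample, a in alleles_per_sample.items():
        n_alt = sum(1 for al in a if al == alt)
        if mode == "dominant":
            out[sample] = hom_ref if n_alt == 0 else carrier
        elif mode == "recessive":
            out[sample] = hom_alt if n_alt == 2 else f"{hom_ref} or {ref}/{alt}"
        elif mode == "additive":
            out[sample] = [hom_ref, f"{ref}/{alt}", hom_alt][n_alt]
        else:
            raise ValueError(f"unknown mode {mode!r}")
    return out


def genotype_allele_counts(
    genotypes: Mapping[str, str]
) -> tuple[dict[str, int], str, str]:
    """Alternate-allele counts from diploid genotype strings at a biallelic SNP.

    The more frequent allele is taken as reference. Returns
    ``(sample -> count, ref allele, alt allele)``.
    """
    counts: dict[str, int] = {}
    per_sample = {}
    for sample, g in genotypes.items():
        a = tuple(g.replace("|", "/").split("/"))
        if len(a) != 2:
            raise ValueError(f"{sample}: not a diploid genotype {g!r}")
        per_sample[sample] = a
        for al in a:
            counts[al] = counts.get(al, 0) + 1
    alleles = sorted(counts, key=lambda al: (-counts[al], al))
    if len(alleles) != 2:
        raise ValueError(f"SNP is not biallelic/polymorphic: alleles {alleles}")
    ref, alt = alleles
    return (
        {s: sum(1 for al in a if al == alt) for s, a in per_sample.items()},
        ref,
        alt,
    )


def ld_pairwise(
    g1: Sequence[int] | np.ndarray,
    g2: Sequence[int] | np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> LDResult:
    """Estimate D, D' and r² between two SNPs from unphased genotypes.

    Haplotype frequencies are maximum-likelihood under an EM that resolves the
    double-heterozygote phase ambiguity, initialized at linkage equilibrium
    (product of allele frequencies). D is the haplotype-frequency covariance
    p_AB − p_A·p_B on the alternate alleles; D' normalizes by its bound given
    the allele frequencies; r² divides by the allele-frequency variances.
    """
    g1 = np.asarray(g1, dtype=int)
    g2 = np.asarray(g2, dtype=int)
    keep = (g1 != MISSING) & (g2 != MISSING)
    g1, g2 = g1[keep], g2[keep]
    n = g1.size
    if n < 2:
        raise ValueError("need >= 2 samples with calls at both SNPs")
    pA = g1.sum() / (2 * n)
    pB = g2.sum() / (2 * n)
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        raise ValueError("monomorphic SNP: LD undefined")

    # counts of the 9 joint genotype classes
    joint = np.zeros((3, 3))
    for a, b in zip(g1, g2):
        joint[a, b] += 1

    # haplotype freq order: AB, Ab, aB, ab (uppercase = alternate allele)
    p = np.array([pA * pB, pA * (1 - pB), (1 - pA) * pB, (1 - pA) * (1 - pB)])
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        # expected haplotype counts; only 1/1 double hets are phase-ambiguous
        c = np.zeros(4)
        c[0] += 2 * joint[2, 2] + joint[2, 1] + joint[1, 2]
        c[1] += 2 * joint[2, 0] + joint[2, 1] + joint[1, 0]
        c[2] += 2 * joint[0, 2] + joint[0, 1] + joint[1, 2]
        c[3] += 2 * joint[0, 0] + joint[0, 1] + joint[1, 0]
        dh = joint[1, 1]
        if dh:
            cis = p[0] * p[3]
            trans = p[1] * p[2]
            w = 0.5 if cis + trans == 0 else cis / (cis + trans)
            c[0] += dh * w
            c[3] += dh * w
            c[1] += dh * (1 - w)
            c[2] += dh * (1 - w)
        p_new = c / (2 * n)
        if np.abs(p_new - p).max() < tol:
            p = p_new
            converged = True
            break
        p = p_new
    D = p[0] - pA * pB
    if D >= 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    dprime = 0.0 if dmax == 0 else abs(D) / dmax
    r2 = D * D / (pA * (1 - pA) * pB * (1 - pB))
    return LDResult(
        D=float(D),
        Dprime=float(min(dprime, 1.0)),
        r2=float(min(r2, 1.0)),
        haplotype_freqs={
            "AB": float(p[0]), "Ab": float(p[1]), "aB": float(p[2]), "ab": float(p[3])
        },
        converged=converged,
        n_iterations=n_iter,
    )


def concordance(calls1: GenotypeMatrix, calls2: GenotypeMatrix) -> dict[str, float]:
    """Per-sample genotype-class agreement rate between two platforms.

    Compared over the shared (site, sample) pairs; pairs where either call is
    MISSING leave the denominator. Rates are percentages.
    """
    shared_sites = [s.key for s in calls1.sites if s.key in {t.key for t in calls2.sites}]
    shared_samples = [s for s in calls1.samples if s in set(calls2.samples)]
    if not shared_sites or not shared_samples:
        raise ValueError("no shared (site, sample) pairs to compare")
    idx1 = {s.key: i for i, s in enumerate(calls1.sites)}
    idx2 = {s.key: i for i, s in enumerate(calls2.sites)}
    rates = {}
    any_compared = False
    for sample in shared_samples:
        j1 = calls1.samples.index(sample)
        j2 = calls2.samples.index(sample)
        agree = total = 0
        for key in shared_sites:
            a = int(calls1.g[idx1[key], j1])
            b = int(calls2.g[idx2[key], j2])
            if a == MISSING or b == MISSING:
                continue
            total += 1
            agree += a == b
        if total:
            rates[sample] = 100.0 * agree / total
            any_compared = True
    if not any_compared:
        raise ValueError("zero comparable genotype pairs (all MISSING)")
    return rates
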