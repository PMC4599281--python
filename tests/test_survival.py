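"""Survival estimators against hand-computed and independent numeric oracles."""

import numpy as np
import pytest
from scipy import optimize

from sorascan.core_io import MISSING, GenotypeMatrix, SurvivalRecord, VariantSite
from sorascan.survival import (
    concordance,
    cox_fit,
    genotype_allele_counts,
    genotype_strata,
    km_estimate,
    ld_pairwise,
    logrank_test,
)


def recs(times, events, groups=None, stages=None):
    groups = groups or ["g"] * len(times)
    stages = stages or [0] * len(times)
    return [
        SurvivalRecord(f"s{i}", t, e, g, st)
        for i, (t, e, g, st) in enumerate(zip(times, events, groups, stages))
    ]


class TestKaplanMeier:
    def test_three_events_closed_form(self):
        km = km_estimate(recs([1, 2, 3], [1, 1, 1]))
        assert np.allclose(km.survival, [2 / 3, 1 / 3, 0.0])
        assert km.median == 2

    def test_censored_before_event(self):
        # censored at 1, event at 2: S(2) = 0 by the product-limit formula
        km = km_estimate(recs([1, 2], [0, 1]))
        assert list(km.times) == [2]
        assert km.survival[-1] == pytest.approx(0.0)

    def test_single_censored_subject(self):
        km = km_estimate(recs([5], [0]))
        assert km.at(10) == 1.0 and km.median is None

    def test_equals_empirical_survival_without_censoring(self, rng):
        times = rng.exponential(5, 60).round(2) + 0.01
        km = km_estimate(recs(times, [1] * 60))
        for t in [0.5, 2.0, 5.0, 10.0]:
            assert km.at(t) == pytest.approx((times > t).mean())

    def test_greenwood_variance_first_step(self):
        # one event among n: var = S^2 * d/(n(n-d)) = (1-1/n)^2 / (n(n-1))
        n = 10
        km = km_estimate(recs(range(1, n + 1), [1] + [0] * (n - 1)))
        s = 1 - 1 / n
        assert km.variance[0] == pytest.approx(s**2 * 1 / (n * (n - 1)))


class TestLogrank:
    def test_identical_groups_give_null(self):
        a = recs([1, 2, 3, 4], [1, 1, 1, 0], ["A"] * 4)
        b = recs([1, 2, 3, 4], [1, 1, 1, 0], ["B"] * 4)
        stat, df, p = logrank_test({"A": a, "B": b})
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert df == 1 and p == pytest.approx(1.0)

    def test_hand_computed_observed_minus_expected(self):
        """A events {1,2}, B events {10,11}: chi-square = (7/6)^2 / (17/36) = 49/17."""
        a = recs([1, 2], [1, 1], ["A"] * 2)
        b = recs([10, 11], [1, 1], ["B"] * 2)
        stat, df, p = logrank_test({"A": a, "B": b})
        assert stat == pytest.approx(49 / 17, rel=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            logrank_test({"A": recs([1], [1]), "B": [], "C": recs([2], [1])})


def neg_log_partial_likelihood(beta, times, events, x):
    """Tie-free Cox partial likelihood (independent oracle)."""
    order = np.argsort(times)
    times, events, x = times[order], events[order], x[order]
    ll = 0.0
    for i in range(len(times)):
        if events[i]:
            at_risk = times >= times[i]
            ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[at_risk])))
    return -ll


class TestCox:
    def test_symmetric_groups_give_null_hazard(self):
        r = recs([1, 3, 1, 3], [1, 1, 1, 1], ["A", "A", "B", "B"])
        # jitter times to break exact ties while keeping symmetry
        res = cox_fit(r, covariates=("group",), risk_group="A")
        assert res.beta["group"] == pytest.approx(0.0, abs=1e-8)
        assert res.hr["group"] == pytest.approx(1.0, abs=1e-8)

    def test_beta_matches_independent_likelihood_maximization(self, rng):
        """Fitted beta agrees with golden-section maximization of the same
        partial likelihood to 1e-6 (tie-free 20-subject dataset)."""
        n = 20
        x = np.array([1.0] * 10 + [0.0] * 10)
        times = np.concatenate([rng.exponential(1, 10), rng.exponential(2, 10)])
        times = np.round(times, 6) + np.linspace(0, 1e-4, n)  # ensure unique
        events = np.ones(n, dtype=int)
        r = recs(times, events, ["R" if xi else "B" for xi in x])
        res = cox_fit(r, covariates=("group",), risk_group="R")
        oracle = optimize.minimize_scalar(
            neg_log_partial_likelihood,
            bounds=(-5, 5),
            args=(times, events, x),
            method="bounded",
            options={"xatol": 1e-10},
        )
        assert res.beta["group"] == pytest.approx(oracle.x, abs=1e-6)
        assert res.ci95["group"][0] < res.hr["group"] < res.ci95["group"][1]

    def test_breslow_equals_efron_without_ties(self, rng):
        times = np.unique(rng.exponential(3, 40).round(6))
        n = len(times)
        groups = ["R" if i % 2 else "B" for i in range(n)]
        r = recs(times, [1] * n, groups)
        efron = cox_fit(r, covariates=("group",), ties="efron", risk_group="R")
        breslow = cox_fit(r, covariates=("group",), ties="breslow", risk_group="R")
        assert efron.beta["group"] == pytest.approx(breslow.beta["group"], abs=1e-5)
        assert efron.se["group"] == pytest.approx(breslow.se["group"], abs=1e-5)

    def test_perfect_separation_flagged(self):
        r = recs(
            [1, 2, 3, 10, 11, 12],
            [1, 1, 1, 0, 0, 0],
            ["A", "A", "A", "B", "B", "B"],
        )
        res = cox_fit(r, covariates=("group",), risk_group="A")
        assert not res.converged
        assert res.ci95["group"] is None

    def test_constant_covariate_dropped_with_warning(self):
        r = recs([1, 2, 3, 4], [1, 1, 1, 1], ["A", "A", "B", "B"], [2, 2, 2, 2])
        with pytest.warns(UserWarning, match="constant"):
            res = cox_fit(r, covariates=("group", "stage"), risk_group="A")
        assert res.beta["stage"] == 0.0 and res.hr["stage"] == 1.0


class TestGenotypeStrata:
    GENO = {"a": "C/C", "b": "C/T", "c": "T/T"}

    def test_dominant_pools_carriers(self):
        s = genotype_strata(self.GENO, "dominant", ref_allele="C")
        assert s == {"a": "C/C", "b": "C/T or T/T", "c": "C/T or T/T"}

    def test_additive_keeps_three_classes(self):
        s = genotype_strata(self.GENO, "additive", ref_allele="C")
        assert len(set(s.values())) == 3

    def test_recessive_isolates_alt_homozygote(self):
        s = genotype_strata(self.GENO, "recessive", ref_allele="C")
        assert s["c"] == "T/T" and s["a"] == s["b"]

    def test_monomorphic_is_an_error(self):
        with pytest.raises(ValueError, match="monomorphic"):
            genotype_strata({"a": "C/C", "b": "C/C"})

    def test_major_allele_assumed_reference_by_default(self):
        s = genotype_strata({"a": "T/T", "b": "T/T", "c": "C/T"})
        assert s["a"] == "T/T" and s["c"] == "T/C or C/C"


class TestLD:
    def test_identical_polymorphic_vectors_in_complete_ld(self):
        g = [0, 1, 2, 0, 1, 2, 1, 0]
        res = ld_pairwise(g, g)
        assert res.r2 == pytest.approx(1.0, abs=1e-9)
        assert res.Dprime == pytest.approx(1.0, abs=1e-9)

    def test_closed_form_from_balanced_haplotypes(self):
        """50 AB + 50 ab haplotypes: D = pAB - pA pB = 0.5 - 0.25 = 0.25."""
        g1 = [2] * 25 + [0] * 25  # 25 AB/AB + 25 ab/ab individuals
        g2 = [2] * 25 + [0] * 25
        res = ld_pairwise(g1, g2)
        assert res.D == pytest.approx(0.25, abs=1e-9)
        assert res.Dprime == pytest.approx(1.0, abs=1e-9)
        assert res.r2 == pytest.approx(1.0, abs=1e-9)

    def test_em_equals_direct_counting_on_phase_unambiguous_data(self, rng):
        """With no double heterozygotes the EM fixed point is direct counting."""
        # haplotype pool with LD, sampled avoiding double hets
        haps = [(1, 1), (0, 0), (1, 0)]
        probs = [0.5, 0.4, 0.1]
        g1, g2 = [], []
        count = np.zeros(4)  # AB, Ab, aB, ab
        while len(g1) < 200:
            i, j = rng.choice(3, 2, p=probs)
            a = (haps[i][0] + haps[j][0], haps[i][1] + haps[j][1])
            if a == (1, 1) and haps[i] != haps[j]:
                continue  # would be phase-ambiguous
            g1.append(a[0])
            g2.append(a[1])
            for h in (haps[i], haps[j]):
                count[{(1, 1): 0, (1, 0): 1, (0, 1): 2, (0, 0): 3}[h]] += 1
        res = ld_pairwise(g1, g2)
        direct = count / count.sum()
        assert res.haplotype_freqs["AB"] == pytest.approx(direct[0], abs=1e-7)
        assert res.haplotype_freqs["ab"] == pytest.approx(direct[3], abs=1e-7)

    def test_independent_snps_have_negligible_r2(self, rng):
        n = 10_000
        g1 = rng.binomial(2, 0.4, n)
        g2 = rng.binomial(2, 0.6, n)
        assert ld_pairwise(g1, g2).r2 < 0.01

    def test_monomorphic_rejected(self):
        with pytest.raises(ValueError, match="monomorphic"):
            ld_pairwise([0, 0, 0], [0, 1, 2])

    def test_missing_pairs_excluded(self):
        g1 = [0, 1, 2, MISSING, 1]
        g2 = [0, 1, 2, 2, MISSING]
        res = ld_pairwise(g1, g2)
        assert res.r2 == pytest.approx(1.0, abs=1e-9)


class TestConcordance:
    def _matrix(self, g, samples=("s1", "s2")):
        sites = [VariantSite("chr1", 100 + i, "A", "G") for i in range(len(g))]
        return GenotypeMatrix(sites, list(samples), np.array(g, dtype=np.int8))

    def test_identical_matrices_are_fully_concordant(self):
        m = self._matrix([[0, 1], [2, 1], [1, 0]])
        assert concordance(m, m) == {"s1": 100.0, "s2": 100.0}

    def test_one_mismatch_in_hundred(self):
        g = [[0, 0] for _ in range(100)]
        m1 = self._matrix(g)
        g2 = [row[:] for row in g]
        g2[0][0] = 1
        m2 = self._matrix(g2)
        assert concordance(m1, m2)["s1"] == pytest.approx(99.0)
        assert concordance(m1, m2)["s2"] == pytest.approx(100.0)

    def test_missing_calls_leave_denominator(self):
        m1 = self._matrix([[0, 1], [MISSING, 1]])
        m2 = self._matrix([[0, 1], [2, 1]])
        assert concordance(m1, m2)["s1"] == pytest.approx(100.0)

    def test_all_missing_is_an_error(self):
        m1 = self._matrix([[MISSING, MISSING]])
        m2 = self._matrix([[0, 1]])
        with pytest.raises(ValueError):
            concordance(m1, m2)


def test_genotype_allele_counts_identifies_minor_allele():
    counts, ref, alt = genotype_allele_counts({"a": "T/T", "b": "C/T", "c": "T/T"})
    assert (ref, alt) == ("T", "C")
    assert counts == {"a": 0, "b": 1, "c": 0}
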