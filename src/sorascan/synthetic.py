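"""Synthetic cohort generators emulating the extreme-responder study design.

Two generators cover the whole pipeline without any download:

* :func:`make_discovery_cohort` — a 4 good / 3 poor responder whole-genome
  discovery cohort: a VCF with variants planted to segregate perfectly under
  each of the four inheritance subclasses, decoy variants guaranteed (by
  rejection sampling) to segregate under none, and — by default — the study's
  15 validated coding variants embedded in synthetic gene models whose codon
  context reproduces each printed amino-acid change. Gene models are emitted
  as BED12 + FASTA (region-named records back the genes at their hg19
  coordinates with kilobase-scale sequence windows), the phenotype sheet
  carries the discovery cohort's printed TTP/age/tumour-size values, and a
  truth table records every planted site with its subclass.

* :func:`make_validation_cohort` — an independent survival cohort (default
  n = 174) with genotypes drawn under Hardy–Weinberg at the Asian T-allele
  frequency of the validated transporter SNP, exponential event times whose
  hazard is multiplied by the design hazard ratio for homozygous-reference
  (C/C) subjects, independent exponential censoring calibrated to a target
  censoring fraction, and three candidate SNPs generated in complete linkage
  disequilibrium.

All randomness flows from one :class:`numpy.random.Generator` seeded once per
run; identical seed and design give byte-identical output files.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from .core_io import MISSING, GenotypeMatrix, VariantSite, write_vcf

__all__ = [
    "DiscoveryDesign",
    "ValidationDesign",
    "DiscoveryCohort",
    "CODING_VARIANT_PLAN",
    "make_discovery_cohort",
    "make_validation_cohort",
    "hardy_weinberg_genotypes",
    "linked_genotypes",
]


# ---------------------------------------------------------------------------
# The validated coding variants (hg19) and the genes that carry them
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlannedVariant:
    """One coding variant to embed: position, alleles and amino-acid change."""

    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    ref_aa: str
    var_aa: str
    id: str | None = None
    codon_index: int | None = None  # requested 1-based protein position


#: The 15 Sanger-validated coding variants of the sorafenib extreme-responder
#: discovery cohort, with their printed amino-acid changes. Six are
#: non-synonymous, in four genes; five sit in the SLC15A2 peptide transporter.
#: The three validated SLC15A2 missense SNPs carry their dbSNP IDs and
#: protein positions (L350F, P409S, R509K).
CODING_VARIANT_PLAN: tuple[PlannedVariant, ...] = (
    PlannedVariant("ABCB1", "chr7", 87160618, "A", "C", "S", "A"),
    PlannedVariant("ALDH3B1", "chr11", 67795299, "G", "A", "P", "P"),
    PlannedVariant("ALDH3B1", "chr11", 67795353, "G", "A", "L", "L"),
    PlannedVariant("CYP21A2", "chr6", 32006317, "C", "T", "L", "L"),
    PlannedVariant("DDR1", "chr6", 30865204, "A", "C", "P", "P"),
    PlannedVariant("FMO3", "chr1", 171076966, "G", "A", "E", "K"),
    PlannedVariant("MUSK", "chr9", 113538122, "G", "A", "M", "I"),
    PlannedVariant("SLC15A2", "chr3", 121641693, "G", "A", "A", "A"),
    PlannedVariant("SLC15A2", "chr3", 121643804, "C", "T", "L", "F",
                   id="rs2257212", codon_index=350),
    PlannedVariant("SLC15A2", "chr3", 121646641, "A", "G", "A", "A"),
    PlannedVariant("SLC15A2", "chr3", 121647286, "C", "T", "P", "S",
                   id="rs1143671", codon_index=409),
    PlannedVariant("SLC15A2", "chr3", 121648168, "G", "A", "R", "K",
                   id="rs1143672", codon_index=509),
    PlannedVariant("SLC22A15", "chr1", 116534852, "C", "T", "S", "S"),
    PlannedVariant("SLC7A7", "chr14", 23282449, "C", "T", "S", "S"),
    PlannedVariant("SLC7A7", "chr14", 23282110, "A", "G", "I", "I"),
)

#: Sorafenib-target vs ADME candidate assignment of the nine genes (the two
#: kinase-family genes are target candidates, the rest drug-disposition genes).
TARGET_GENES = frozenset({"MUSK", "DDR1"})
ADME_GENES = frozenset(
    {"ABCB1", "ALDH3B1", "CYP21A2", "FMO3", "SLC15A2", "SLC22A15", "SLC7A7"}
)

#: Discovery-cohort phenotype sheet: per-patient TTP (months), age (years) and
#: maximum tumour size (mm) as printed for the seven sequenced patients.
DISCOVERY_SAMPLE_SHEET = pd.DataFrame(
    {
        "sample": [f"P{i}" for i in range(1, 8)],
        "ttp_months": [55.5, 38.1, 9.3, 8.1, 4.7, 3.5, 4.3],
        "age": [54, 45, 47, 60, 61, 66, 68],
        "tumor_size_mm": [60, 45, 72, 13, 15, 83, 20],
    }
)

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_ALL_CODONS = ["".join(c) for c in itertools.product("ACGT", repeat=3)]
_SAFE_FILLERS = ("GCT", "GGA", "CTG", "AAC", "GAC", "TCC", "ATC", "GTG")
_MIN_INTRON = 12
_UTR_PAD = 60
_DEFAULT_CODON_GAP = 30


def _aa(codon: str) -> str:
    return "*" if codon in standard_dna_table.stop_codons else standard_dna_table.forward_table[codon]


def _codon_solutions(v: PlannedVariant, strand: str) -> list[tuple[str, int]]:
    """All (reference codon, within-codon offset) realizing v's amino-acid change."""
    ref_b = v.ref if strand == "+" else _COMPLEMENT[v.ref]
    alt_b = v.alt if strand == "+" else _COMPLEMENT[v.alt]
    out = []
    for codon in _ALL_CODONS:
        for k in range(3):
            if codon[k] != ref_b:
                continue
            mutated = codon[:k] + alt_b + codon[k + 1 :]
            if _aa(codon) == v.ref_aa and _aa(mutated) == v.var_aa and _aa(codon) != "*":
                out.append((codon, k))
    return out


@dataclass
class _GenePlan:
    gene: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]  # genomic order, 1-based inclusive
    thick: tuple[int, int]  # CDS extent
    cds_string: str  # strand-oriented coding sequence incl. terminal stop
    variant_codons: dict[int, int]  # genomic pos -> 1-based codon index

    @property
    def span(self) -> tuple[int, int]:
        return (self.exons[0][0], self.exons[-1][1])


def _plan_gene(variants: list[PlannedVariant], rng: np.random.Generator) -> _GenePlan:
    """Lay out a gene model whose codons realize each variant's amino-acid pair.

    Every target codon becomes its own 3-bp CDS exon, so its reading frame is
    controlled regardless of inter-variant spacing; intervening codons fill
    intermediate exons and introns absorb the genomic distance. The first exon
    carries a 5' UTR pad and the start codon, the last a terminal stop and a
    3' UTR pad.
    """
    gene = variants[0].gene
    by_pos = sorted(variants, key=lambda v: v.pos)
    strand = None
    solutions: dict[int, tuple[str, int]] = {}
    for cand in "+-":
        sols = {v.pos: _codon_solutions(v, cand) for v in by_pos}
        if all(sols[p] for p in sols):
            strand = cand
            solutions = {p: sorted(s)[0] for p, s in sols.items()}
            break
    if strand is None:
        raise ValueError(f"{gene}: no codon context realizes the amino-acid changes")

    coding_order = by_pos if strand == "+" else list(reversed(by_pos))
    # assign strictly increasing codon indices, honouring requested positions;
    # the genomic distance to the previous variant bounds how many intervening
    # codons (plus two introns) fit between their exons
    indices: list[int] = []
    for i, v in enumerate(coding_order):
        if not indices:
            lo, hi = 2, None
        else:
            dist = abs(v.pos - coding_order[i - 1].pos)
            if dist < 20:
                raise ValueError(f"{gene}: variants {dist} bp apart cannot be laid out")
            lo = indices[-1] + 1
            hi = indices[-1] + 1 + max(0, (dist - 32) // 3)
        if v.codon_index is not None:
            idx = v.codon_index
            if idx < lo or (hi is not None and idx > hi):
                raise ValueError(f"{gene}: requested codon index {idx} infeasible")
        else:
            idx = lo + _DEFAULT_CODON_GAP - 2
            if hi is not None:
                idx = min(idx, hi)
            idx = max(idx, lo)
        indices.append(idx)
    n_codons = indices[-1] + 10  # coding codons after the last variant
    total_codons = n_codons + 1  # + terminal stop

    # reference codons at the variant positions
    codon_at = {indices[i]: solutions[v.pos][0] for i, v in enumerate(coding_order)}
    fillers = rng.choice(_SAFE_FILLERS, size=total_codons)
    cds = ["ATG"] + [
        codon_at.get(i, fillers[i]) for i in range(2, n_codons + 1)
    ] + ["TAA"]
    cds_string = "".join(cds)

    # genomic exon layout (genomic order); prev_end tracks the last laid exon
    exon_codonspans: list[tuple[int, int]] = []  # codon index ranges per exon, coding order
    first = indices[0]
    exon_codonspans.append((1, first - 1))
    for a, b in zip(indices, indices[1:]):
        exon_codonspans.append((a, a))
        if b > a + 1:
            exon_codonspans.append((a + 1, b - 1))
    exon_codonspans.append((indices[-1], indices[-1]))
    exon_codonspans.append((indices[-1] + 1, total_codons))

    # genomic anchor: each variant exon is pinned by its genomic position
    variant_exon_pos = {}
    for i, v in enumerate(coding_order):
        codon, k = solutions[v.pos]
        if strand == "+":
            start = v.pos - k
        else:
            start = v.pos - (2 - k)
        variant_exon_pos[indices[i]] = (start, start + 2)

    genomic_spans = _place_exons(
        gene, strand, exon_codonspans, variant_exon_pos
    )
    # thick (CDS) extent across all exons
    thick = (genomic_spans[0][0], genomic_spans[-1][1])
    # prepend/append UTR pads to terminal exons
    exons = list(genomic_spans)
    exons[0] = (exons[0][0] - _UTR_PAD, exons[0][1])
    exons[-1] = (exons[-1][0], exons[-1][1] + _UTR_PAD)
    return _GenePlan(
        gene,
        variants[0].chrom,
        strand,
        exons,
        thick,
        cds_string,
        {v.pos: indices[i] for i, v in enumerate(coding_order)},
    )


def _place_exons(gene, strand, codonspans, variant_exon_pos):
    """Convert coding-order codon ranges into genomic-order exon intervals."""
    lengths = [3 * (b - a + 1) for a, b in codonspans]
    anchors = {
        i: variant_exon_pos[a]
        for i, (a, b) in enumerate(codonspans)
        if a == b and a in variant_exon_pos
    }
    n = len(codonspans)
    spans: list[tuple[int, int] | None] = [None] * n
    for i, pos in anchors.items():
        spans[i] = pos
    if strand == "+":
        # lay unanchored exons away from the nearest anchored neighbour
        first_anchor = sorted(anchors)[0]
        for i in range(first_anchor - 1, -1, -1):  # upstream in coding order
            nxt = spans[i + 1]
            end = nxt[0] - _MIN_INTRON - 1
            spans[i] = (end - lengths[i] + 1, end)
        for i in range(first_anchor + 1, n):
            if spans[i] is not None:
                continue
            prev = spans[i - 1]
            start = prev[1] + _MIN_INTRON + 1
            spans[i] = (start, start + lengths[i] - 1)
            # if the next exon is anchored, verify we fit before it
            if i + 1 < n and spans[i + 1] is not None and spans[i][1] + _MIN_INTRON >= spans[i + 1][0]:
                raise ValueError(f"{gene}: variants too close to lay out intervening codons")
        genomic = spans
    else:
        # coding order runs right-to-left genomically
        genomic = _mirror_minus(gene, codonspans, lengths, anchors, n)
    result = sorted(genomic)  # genomic order
    for (a1, b1), (a2, b2) in zip(result, result[1:]):
        if a2 <= b1 + _MIN_INTRON:
            raise ValueError(f"{gene}: exon layout collision")
    if result[0][0] < 1:
        raise ValueError(f"{gene}: layout extends below position 1")
    return result


def _mirror_minus(gene, codonspans, lengths, anchors, n):
    """Genomic intervals for a minus-strand gene (coding order right-to-left)."""
    spans: list[tuple[int, int] | None] = [None] * n
    for i, pos in anchors.items():
        spans[i] = pos
    first_anchor = sorted(anchors)[0]
    for i in range(first_anchor - 1, -1, -1):  # coding-upstream = genomic right
        nxt = spans[i + 1]
        start = nxt[1] + _MIN_INTRON + 1
        spans[i] = (start, start + lengths[i] - 1)
    for i in range(first_anchor + 1, n):
        if spans[i] is not None:
            continue
        prev = spans[i - 1]
        end = prev[0] - _MIN_INTRON - 1
        spans[i] = (end - lengths[i] + 1, end)
        if i + 1 < n and spans[i + 1] is not None and spans[i + 1][1] + _MIN_INTRON >= spans[i][0]:
            raise ValueError(f"{gene}: variants too close to lay out intervening codons")
    return spans


def _gene_window_sequence(plan: _GenePlan, rng: np.random.Generator, margin: int = 40):
    """Random intron/flank bases with coding chunks written onto the exons."""
    w_start = plan.span[0] - margin
    w_end = plan.span[1] + margin
    seq = rng.choice(list("ACGT"), size=w_end - w_start + 1)
    # distribute the coding string over the CDS exon parts (coding order)
    cds_exons = []
    for a, b in plan.exons:
        lo, hi = max(a, plan.thick[0]), min(b, plan.thick[1])
        if lo <= hi:
            cds_exons.append((lo, hi))
    order = cds_exons if plan.strand == "+" else list(reversed(cds_exons))
    off = 0
    for a, b in order:
        chunk = plan.cds_string[off : off + (b - a + 1)]
        off += b - a + 1
        if plan.strand == "-":
            chunk = str(Seq(chunk).reverse_complement())
        seq[a - w_start : b - w_start + 1] = list(chunk)
    return w_start, w_end, "".join(seq)


# ---------------------------------------------------------------------------
# Designs
# ---------------------------------------------------------------------------

@dataclass
class DiscoveryDesign:
    """Discovery-cohort simulation design (defaults = the study's conditions)."""

    n_good: int = 4
    n_poor: int = 3
    n_planted_per_subclass: int = 1
    n_decoys: int = 96
    missing_rate: float = 0.0
    embed_coding_variants: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_good < 1 or self.n_poor < 1:
            raise ValueError("both responder classes must be non-empty")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must be in [0,1]")


@dataclass
class ValidationDesign:
    """Validation-cohort simulation design (defaults = the study's conditions)."""

    n: int = 174
    alt_allele_freq: float = 0.75  # protective T allele, Asian frequency range
    hr: float = 2.18  # hazard of C/C (ref-hom) vs carriers
    baseline_hazard: float = float(np.log(2) / 4.4)  # per month; carrier median PFS 4.4 mo
    censoring_rate: float = 0.2  # expected fraction censored
    stage_probs: tuple[float, ...] = (0.012, 0.201, 0.787)  # BCLC A/B/C -> 0/1/2
    stage_log_hr: float = 0.0  # optional hazard link per stage step
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hr <= 0 or self.baseline_hazard <= 0:
            raise ValueError("hazards must be positive")
        if not 0.0 < self.alt_allele_freq < 1.0:
            raise ValueError("alt_allele_freq must be in (0,1)")
        if not 0.0 <= self.censoring_rate < 1.0:
            raise ValueError("censoring_rate must be in [0,1); 1 is degenerate")
        if abs(sum(self.stage_probs) - 1.0) > 1e-9:
            raise ValueError("stage_probs must sum to 1")


@dataclass
class DiscoveryCohort:
    """Paths of a generated discovery cohort (all plain-text formats)."""

    vcf: Path
    sample_sheet: Path
    gene_models: Path
    fasta: Path
    targets: Path
    adme: Path
    truth: Path


# ---------------------------------------------------------------------------
# Discovery cohort
# ---------------------------------------------------------------------------

_SUBCLASS_PATTERNS = {
    1: (lambda rng, ng, np_: (rng.integers(1, 3, ng), np.zeros(np_, int))),
    2: (lambda rng, ng, np_: (np.full(ng, 2), rng.integers(0, 2, np_))),
    3: (lambda rng, ng, np_: (np.zeros(ng, int), rng.integers(1, 3, np_))),
    4: (lambda rng, ng, np_: (rng.integers(0, 2, ng), np.full(np_, 2))),
}


def _matches_any_subclass(good: np.ndarray, poor: np.ndarray) -> bool:
    return (
        ((good >= 1).all() and (poor == 0).all())
        or ((good == 2).all() and (poor <= 1).all())
        or ((good == 0).all() and (poor >= 1).all())
        or ((good <= 1).all() and (poor == 2).all())
    )


def make_discovery_cohort(
    design: DiscoveryDesign, out_dir: str | Path
) -> DiscoveryCohort:
    """Generate VCF, sample sheet, gene models + FASTA, candidate lists, truth table.

    Planted variants satisfy their designated subclass exactly; decoys are
    rejection-sampled until they satisfy none (bounded retries) and placed
    outside every candidate gene span. With ``embed_coding_variants`` the 15
    validated coding variants are planted inside synthetic gene models whose
    codons reproduce the printed amino-acid pairs; four additional intronic
    planted sites (one per subclass times ``n_planted_per_subclass``) sit in
    candidate-gene introns.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(design.seed)
    ng, np_ = design.n_good, design.n_poor

    # --- sample sheet ------------------------------------------------------
    if (ng, np_) == (4, 3):
        sheet = DISCOVERY_SAMPLE_SHEET.copy()
    else:  # non-default cohort sizes get synthetic TTPs around the threshold
        ttp_good = np.round(rng.uniform(8.0, 60.0, ng), 1)
        ttp_poor = np.round(rng.uniform(1.0, 4.9, np_), 1)
        sheet = pd.DataFrame(
            {
                "sample": [f"P{i}" for i in range(1, ng + np_ + 1)],
                "ttp_months": np.concatenate([ttp_good, ttp_poor]),
                "age": rng.integers(40, 75, ng + np_),
                "tumor_size_mm": rng.integers(10, 90, ng + np_),
            }
        )
    samples = list(sheet["sample"])

    # --- gene models -------------------------------------------------------
    plans: list[_GenePlan] = []
    gene_rows: dict[str, list[PlannedVariant]] = {}
    if design.embed_coding_variants:
        for v in CODING_VARIANT_PLAN:
            gene_rows.setdefault(v.gene, []).append(v)
        plans = [_plan_gene(rows, rng) for rows in gene_rows.values()]

    windows = [(_gene_window_sequence(p, rng), p) for p in plans]

    fasta_path = out / "reference.fa"
    with open(fasta_path, "w") as fh:
        for (w_start, w_end, seq), p in windows:
            fh.write(f">{p.chrom}:{w_start}-{w_end}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")

    bed_path = out / "gene_models.bed"
    with open(bed_path, "w") as fh:
        for (_, _, _), p in windows:
            span = p.span
            sizes = ",".join(str(b - a + 1) for a, b in p.exons)
            starts = ",".join(str(a - span[0]) for a, _ in p.exons)
            fh.write(
                "\t".join(
                    map(
                        str,
                        [
                            p.chrom, span[0] - 1, span[1], p.gene, 0, p.strand,
                            p.thick[0] - 1, p.thick[1], "0", len(p.exons),
                            sizes + ",", starts + ",",
                        ],
                    )
                )
                + "\n"
            )

    targets_path = out / "target_genes.txt"
    adme_path = out / "adme_genes.txt"
    targets_path.write_text("\n".join(sorted(TARGET_GENES)) + "\n")
    adme_path.write_text("\n".join(sorted(ADME_GENES)) + "\n")

    # --- planted variants --------------------------------------------------
    sites: list[VariantSite] = []
    geno: list[np.ndarray] = []
    truth_rows = []

    def plant(site: VariantSite, subclass: int, kind: str) -> None:
        good, poor = _SUBCLASS_PATTERNS[subclass](rng, ng, np_)
        sites.append(site)
        geno.append(np.concatenate([good, poor]).astype(np.int8))
        truth_rows.append(
            {
                "chrom": site.chrom, "pos": site.pos, "ref": site.ref,
                "alt": site.alt, "subclass": subclass, "kind": kind,
            }
        )

    window_seq = {p.gene: w for w, p in windows}
    subclass_cycle = itertools.cycle([1, 2, 3, 4])
    if design.embed_coding_variants:
        for gene, rows in gene_rows.items():
            for v in rows:
                plant(
                    VariantSite(v.chrom, v.pos, v.ref, v.alt, v.id),
                    next(subclass_cycle),
                    "coding",
                )

    # intronic planted sites, one per subclass per replicate
    for rep in range(design.n_planted_per_subclass):
        for sc in (1, 2, 3, 4):
            if plans:
                p = plans[(rep * 4 + sc) % len(plans)]
                w_start, w_end, seq = window_seq[p.gene]
                pos = _intron_position(p, rng)
                ref = seq[pos - w_start]
                alt = rng.choice([b for b in "ACGT" if b != ref])
                site = VariantSite(p.chrom, int(pos), ref, str(alt))
            else:
                pos = 1_000_000 + (rep * 4 + sc) * 97
                ref, alt = "A", "G"
                site = VariantSite("chr21", pos, ref, alt)
            if any(s.key == site.key for s in sites):
                continue
            plant(site, sc, "intronic" if plans else "standalone")

    # --- decoys (outside candidate spans, matching no subclass) ------------
    for i in range(design.n_decoys):
        pos = 5_000_000 + i * 211
        ref, alt_b = rng.choice(list("ACGT"), size=2, replace=False)
        for _ in range(1000):
            p_alt = rng.uniform(0.15, 0.85)
            g = rng.binomial(2, p_alt, ng + np_)
            if not _matches_any_subclass(g[:ng], g[ng:]):
                break
        else:
            raise RuntimeError("decoy rejection sampling failed after 1000 tries")
        sites.append(VariantSite("chr22", pos, str(ref), str(alt_b)))
        geno.append(g.astype(np.int8))

    g = np.vstack(geno) if geno else np.empty((0, len(samples)), dtype=np.int8)
    if design.missing_rate > 0:
        mask = rng.random(g.shape) < design.missing_rate
        g = np.where(mask, np.int8(MISSING), g)

    matrix = GenotypeMatrix(sites, samples, g)
    vcf_path = out / "discovery.vcf"
    write_vcf(matrix, vcf_path)

    sheet_path = out / "sample_sheet.tsv"
    sheet.to_csv(sheet_path, sep="\t", index=False)

    truth_path = out / "truth.tsv"
    pd.DataFrame(
        truth_rows, columns=["chrom", "pos", "ref", "alt", "subclass", "kind"]
    ).to_csv(truth_path, sep="\t", index=False)

    return DiscoveryCohort(
        vcf=vcf_path,
        sample_sheet=sheet_path,
        gene_models=bed_path,
        fasta=fasta_path,
        targets=targets_path,
        adme=adme_path,
        truth=truth_path,
    )


def _intron_position(plan: _GenePlan, rng: np.random.Generator) -> int:
    gaps = [
        (b1 + 1, a2 - 1)
        for (a1, b1), (a2, b2) in zip(plan.exons, plan.exons[1:])
        if a2 - b1 > 2
    ]
    lo, hi = gaps[rng.integers(len(gaps))]
    return int(rng.integers(lo, hi + 1))


# ---------------------------------------------------------------------------
# Validation cohort
# ---------------------------------------------------------------------------

def hardy_weinberg_genotypes(
    rng: np.random.Generator, n: int, alt_freq: float
) -> np.ndarray:
    """Alt-allele counts for n diploid subjects under Hardy–Weinberg."""
    return rng.binomial(2, alt_freq, size=n)


def linked_genotypes(
    rng: np.random.Generator, n: int, alt_freq: float, n_snps: int
) -> np.ndarray:
    """Genotypes at ``n_snps`` SNPs in complete LD (shared haplotypes): n x k."""
    g = hardy_weinberg_genotypes(rng, n, alt_freq)
    return np.tile(g[:, None], (1, n_snps))


#: SNP id -> (ref allele, alt allele) for the three validated transporter SNPs.
VALIDATION_SNPS = {
    "rs2257212": ("C", "T"),  # L350F
    "rs1143671": ("C", "T"),  # P409S
    "rs1143672": ("G", "A"),  # R509K
}


def make_validation_cohort(
    design: ValidationDesign, out_dir: str | Path | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the independent survival cohort; optionally write TSVs.

    Returns ``(survival, genotypes)`` data frames. Survival columns: sample,
    time_months, event, genotype (of the lead SNP), stage. Genotype columns:
    sample plus one diploid genotype string per validated SNP (all three in
    complete LD by construction).

    Event times are exponential with hazard
    ``baseline * hr^{1[C/C]} * exp(stage_log_hr * stage)``; censoring is an
    independent exponential whose rate is calibrated so the expected censored
    fraction equals ``censoring_rate`` under the genotype mixture.
    """
    rng = np.random.default_rng(design.seed)
    n = design.n
    g = linked_genotypes(rng, n, design.alt_allele_freq, len(VALIDATION_SNPS))
    lead = g[:, 0]
    ref_hom = lead == 0  # C/C risk genotype

    stage = rng.choice(len(design.stage_probs), size=n, p=design.stage_probs)
    hazard = design.baseline_hazard * np.where(ref_hom, design.hr, 1.0)
    hazard = hazard * np.exp(design.stage_log_hr * stage)
    event_time = rng.exponential(1.0 / hazard)

    if design.censoring_rate > 0:
        mean_hazard = float(np.mean(hazard))
        c_rate = mean_hazard * design.censoring_rate / (1.0 - design.censoring_rate)
        censor_time = rng.exponential(1.0 / c_rate, size=n)
    else:
        censor_time = np.full(n, np.inf)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    time = np.maximum(np.round(time, 3), 0.001)  # keep times strictly positive

    def geno_string(count: int, ref: str, alt: str) -> str:
        return [f"{ref}/{ref}", f"{ref}/{alt}", f"{alt}/{alt}"][count]

    samples = [f"V{i:04d}" for i in range(1, n + 1)]
    lead_ref, lead_alt = VALIDATION_SNPS["rs2257212"]
    survival = pd.DataFrame(
        {
            "sample": samples,
            "time_months": time,
            "event": event,
            "genotype": [geno_string(c, lead_ref, lead_alt) for c in lead],
            "stage": stage,
        }
    )
    genotypes = pd.DataFrame({"sample": samples})
    for j, (snp, (ref, alt)) in enumerate(VALIDATION_SNPS.items()):
        genotypes[snp] = [geno_string(c, ref, alt) for c in g[:, j]]

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        survival.to_csv(out / "survival.tsv", sep="\t", index=False)
        genotypes.to_csv(out / "validation_genotypes.tsv", sep="\t", index=False)
    return survival, genotypes
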