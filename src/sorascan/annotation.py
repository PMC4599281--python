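"""Candidate-gene filtering and codon-level variant effect annotation.

The cascade mirrors the discovery analysis of the extreme-responder study:
perfectly segregating variants are first restricted to candidate gene bodies
(drug-target and ADME genes, introns included), then classified by genomic
feature, and coding SNVs are called synonymous/missense/nonsense by translating
the reference and variant codons in the CDS-concatenated reading frame.

Variant alleles are always expressed on the plus strand of the reference (the
VCF convention); gene strand is applied only when codons are read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from .core_io import CandidateGeneSet, GeneModel, VariantSite

__all__ = [
    "EffectCall",
    "CascadeReport",
    "filter_candidate_regions",
    "classify_feature",
    "translate_codon",
    "annotate_effect",
    "run_cascade",
]

logger = logging.getLogger(__name__)

CODING_CATEGORIES = (
    "coding_synonymous",
    "coding_missense",
    "coding_nonsense",
    "coding_frameshift",
    "coding_inframe_indel",
)


class ReferenceMismatchError(ValueError):
    """The gene model's sequence disagrees with a variant's stated ref allele."""


@dataclass
class EffectCall:
    site: VariantSite
    gene: str | None
    category: str
    ref_aa: str | None = None
    var_aa: str | None = None
    aa_pos: int | None = None  # 1-based codon index in the protein

    @property
    def is_nonsynonymous(self) -> bool:
        return self.category in ("coding_missense", "coding_nonsense")


@dataclass
class CascadeReport:
    """Stage-by-stage accounting of the candidate filtering cascade."""

    n_associated: int
    n_in_candidate_genes: int
    n_coding: int
    n_nonsynonymous: int
    associated: list[VariantSite] = field(default_factory=list)
    in_candidate_genes: list[tuple[VariantSite, list[str]]] = field(default_factory=list)
    coding: list[EffectCall] = field(default_factory=list)
    nonsynonymous: list[EffectCall] = field(default_factory=list)

    def __post_init__(self) -> None:
        counts = (
            self.n_associated,
            self.n_in_candidate_genes,
            self.n_coding,
            self.n_nonsynonymous,
        )
        if any(a < b for a, b in zip(counts, counts[1:])):
            raise ValueError(f"cascade counts must be non-increasing, got {counts}")


def filter_candidate_regions(
    sites: list[VariantSite],
    genes: list[GeneModel],
    candidates: CandidateGeneSet,
    flank: int = 0,
) -> list[tuple[VariantSite, list[str]]]:
    """Keep sites within ``flank`` bp of a candidate gene body.

    A site overlapping several candidate genes is kept once with every
    overlapping gene recorded. Candidate symbols without a gene model are
    warned about and ignored.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    by_symbol = {g.gene: g for g in genes}
    absent = candidates.all - set(by_symbol)
    if absent:
        logger.warning("candidate genes without models, ignored: %s", sorted(absent))
    candidate_models = [by_symbol[s] for s in sorted(candidates.all & set(by_symbol))]
    kept = []
    for site in sites:
        overlapping = [
            g.gene
            for g in candidate_models
            if g.chrom == site.chrom
            and g.span[0] - flank <= site.pos <= g.span[1] + flank
        ]
        if overlapping:
            kept.append((site, overlapping))
    return kept


def classify_feature(site: VariantSite, gene: GeneModel) -> str:
    """Classify a position within a gene span as coding, utr or intronic.

    CDS positions are coding. Outside the CDS, exonic positions are UTR and
    intron gaps intronic when exon structure is known; without exons, in-span
    positions beyond the CDS extent are called UTR and gap positions intronic.
    """
    if not gene.contains(site.pos):
        raise ValueError(
            f"{site.chrom}:{site.pos} outside span of {gene.gene}; pre-filter first"
        )
    if gene.in_cds(site.pos):
        return "coding"
    in_exon = gene.in_exon(site.pos)
    if in_exon is not None:
        return "utr" if in_exon else "intronic"
    if not gene.cds:
        return "utr"
    cds_lo, cds_hi = gene.cds[0][0], gene.cds[-1][1]
    return "intronic" if cds_lo < site.pos < cds_hi else "utr"


def translate_codon(codon: str) -> str:
    """Translate a codon under the standard genetic code; stop codons give ``*``."""
    codon = codon.upper()
    if len(codon) != 3 or any(b not in "ACGT" for b in codon):
        raise ValueError(f"not an ACGT codon: {codon!r}")
    if codon in standard_dna_table.stop_codons:
        return "*"
    return standard_dna_table.forward_table[codon]


def annotate_effect(site: VariantSite, gene: GeneModel) -> EffectCall:
    """Call the coding effect of a variant inside a gene model.

    SNVs in the CDS are translated: the affected codon is located by CDS
    offset (minus-strand genes read the reverse complement, codon index from
    the strand-correct 5' end) and the reference vs variant amino acids
    compared. CDS indels are frameshift when the length difference is not a
    multiple of 3, in-frame otherwise. Non-CDS positions get their feature
    category with no amino-acid fields.
    """
    category = classify_feature(site, gene)
    if category != "coding":
        return EffectCall(site, gene.gene, category)
    ref_here = gene.sequence[site.pos - gene.span[0] : site.pos - gene.span[0] + len(site.ref)]
    if ref_here != site.ref:
        raise ReferenceMismatchError(
            f"{gene.gene} {site.chrom}:{site.pos}: reference sequence has "
            f"{ref_here!r}, variant states ref {site.ref!r}"
        )
    if not site.is_snv:
        shift = abs(len(site.ref) - len(site.alt)) % 3 != 0
        return EffectCall(
            site, gene.gene, "coding_frameshift" if shift else "coding_inframe_indel"
        )
    cds_seq = gene.coding_sequence()
    off = gene.cds_offset(site.pos)
    codon_idx, within = divmod(off, 3)
    ref_codon = cds_seq[codon_idx * 3 : codon_idx * 3 + 3]
    ref_base = site.ref if gene.strand == "+" else str(Seq(site.ref).complement())
    alt_base = site.alt if gene.strand == "+" else str(Seq(site.alt).complement())
    if ref_codon[within] != ref_base:
        raise ReferenceMismatchError(
            f"{gene.gene} {site.chrom}:{site.pos}: codon/ref inconsistency"
        )
    var_codon = ref_codon[:within] + alt_base + ref_codon[within + 1 :]
    ref_aa = translate_codon(ref_codon)
    var_aa = translate_codon(var_codon)
    if var_aa == "*":
        category = "coding_nonsense"
    elif ref_aa == var_aa:
        category = "coding_synonymous"
    else:
        category = "coding_missense"
    return EffectCall(site, gene.gene, category, ref_aa, var_aa, codon_idx + 1)


def run_cascade(
    matches,
    genes: list[GeneModel],
    candidates: CandidateGeneSet,
    flank: int = 0,
) -> CascadeReport:
    """Run associated -> candidate-gene -> coding -> non-synonymous filtering.

    ``matches`` are :class:`~sorascan.segregation.SubclassMatch` objects (or
    any objects with a ``site`` attribute). Counts are per-site; a site inside
    two overlapping candidate genes counts once, its effect taken from the
    first gene in which it is coding (or the first overlapping gene otherwise).
    """
    sites = [m.site for m in matches]
    kept = filter_candidate_regions(sites, genes, candidates, flank)
    by_symbol = {g.gene: g for g in genes}
    coding_calls: list[EffectCall] = []
    for site, symbols in kept:
        call = None
        for sym in symbols:
            c = annotate_effect(site, by_symbol[sym])
            if c.category.startswith("coding"):
                call = c
                break
            call = call or c
        if call is not None and call.category.startswith("coding"):
            coding_calls.append(call)
    nonsyn = [c for c in coding_calls if c.is_nonsynonymous]
    return CascadeReport(
        n_associated=len(sites),
        n_in_candidate_genes=len(kept),
        n_coding=len(coding_calls),
        n_nonsynonymous=len(nonsyn),
        associated=sites,
        in_candidate_genes=kept,
        coding=coding_calls,
        nonsynonymous=nonsyn,
    )
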