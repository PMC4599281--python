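"""Candidate-region filtering, feature classification and codon-effect calls."""

import numpy as np
import pytest
from Bio.Seq import Seq

from sorascan.annotation import (
    ReferenceMismatchError,
    annotate_effect,
    classify_feature,
    filter_candidate_regions,
    run_cascade,
    translate_codon,
)
from sorascan.core_io import (
    CandidateGeneSet,
    GeneModel,
    VariantSite,
    read_gene_list,
    read_gene_models,
)
from sorascan.segregation import SubclassMatch
from sorascan.synthetic import CODING_VARIANT_PLAN


def simple_gene(seq="ATGCTCTACCCGTAA", strand="+", chrom="chr1", offset=0):
    """Single-exon gene: M L Y P stop (CDS = whole span)."""
    n = len(seq)
    return GeneModel("G1", chrom, strand, (1 + offset, n + offset),
                     [(1 + offset, n + offset)], seq)


class TestCandidateFilter:
    def _gene(self, start, end, name="SLC15A2"):
        length = end - start + 1
        pad = (3 - length % 3) % 3
        end += pad
        seq = "ATG" + "GCA" * ((end - start + 1 - 6) // 3) + "TAA"
        return GeneModel(name, "chr3", "+", (start, end), [(start, end)], seq)

    def test_site_in_candidate_gene_kept_with_assignment(self):
        g = self._gene(121640000, 121650000)
        cands = CandidateGeneSet(set(), {"SLC15A2"})
        site = VariantSite("chr3", 121643804, "C", "T")
        kept = filter_candidate_regions([site], [g], cands, flank=0)
        assert kept == [(site, ["SLC15A2"])]

    @pytest.mark.parametrize("flank,expect_kept", [(0, False), (1, True)])
    def test_flank_boundary(self, flank, expect_kept):
        g = self._gene(1000, 2000)
        cands = CandidateGeneSet(set(), {"SLC15A2"})
        site = VariantSite("chr3", g.span[1] + 1, "A", "G")  # 1 bp past the span
        kept = filter_candidate_regions([site], [g], cands, flank=flank)
        assert bool(kept) is expect_kept

    def test_non_candidate_gene_does_not_keep(self):
        g = self._gene(1000, 2000, name="NOTCAND")
        cands = CandidateGeneSet(set(), {"SLC15A2"})
        site = VariantSite("chr3", 1500, "A", "G")
        assert filter_candidate_regions([site], [g], cands) == []

    def test_absent_candidate_symbol_warned_and_ignored(self, caplog):
        g = self._gene(1000, 2000)
        cands = CandidateGeneSet({"GHOST"}, {"SLC15A2"})
        site = VariantSite("chr3", 1500, "A", "G")
        with caplog.at_level("WARNING"):
            kept = filter_candidate_regions([site], [g], cands)
        assert kept == [(site, ["SLC15A2"])]
        assert "GHOST" in caplog.text


class TestClassifyFeature:
    @pytest.fixture
    def gene(self):
        # span 1..60; exons (1,21) and (40,60); CDS (10,21)+(40,51)
        cds_seq = "ATG" + "GCT" * 6 + "TAA"  # 24 nt over two CDS chunks
        seq = ["T"] * 60
        seq[9:21] = list(cds_seq[:12])
        seq[39:51] = list(cds_seq[12:])
        return GeneModel(
            "G1", "chr1", "+", (1, 60), [(10, 21), (40, 51)], "".join(seq),
            exons=[(1, 21), (40, 60)],
        )

    def test_cds_position_is_coding(self, gene):
        assert classify_feature(VariantSite("chr1", 15, "A", "G"), gene) == "coding"

    def test_gap_between_cds_is_intronic(self, gene):
        assert classify_feature(VariantSite("chr1", 30, "A", "G"), gene) == "intronic"

    def test_exonic_upstream_of_cds_is_utr(self, gene):
        assert classify_feature(VariantSite("chr1", 5, "A", "G"), gene) == "utr"

    def test_outside_span_is_an_error(self, gene):
        with pytest.raises(ValueError, match="outside span"):
            classify_feature(VariantSite("chr1", 61, "A", "G"), gene)


class TestTranslateCodon:
    @pytest.mark.parametrize(
        "codon,aa", [("ATG", "M"), ("TAA", "*"), ("CTC", "L"), ("TTC", "F")]
    )
    def test_standard_code(self, codon, aa):
        assert translate_codon(codon) == aa

    def test_non_acgt_rejected(self):
        with pytest.raises(ValueError):
            translate_codon("ANG")


class TestAnnotateEffect:
    def test_missense_leucine_to_phenylalanine(self):
        # codon 2 = CTC (L); C->T at its first base gives TTC (F)
        g = simple_gene()
        call = annotate_effect(VariantSite("chr1", 4, "C", "T"), g)
        assert (call.category, call.ref_aa, call.var_aa, call.aa_pos) == (
            "coding_missense", "L", "F", 2,
        )

    def test_synonymous_third_position(self):
        # codon 4 = CCG (P); G->A gives CCA (P)
        g = simple_gene()
        call = annotate_effect(VariantSite("chr1", 12, "G", "A"), g)
        assert call.category == "coding_synonymous"
        assert call.ref_aa == call.var_aa == "P"

    def test_nonsense_stop_gain(self):
        # codon 3 = TAC (Y); C->A gives TAA (stop)
        g = simple_gene()
        call = annotate_effect(VariantSite("chr1", 9, "C", "A"), g)
        assert call.category == "coding_nonsense"
        assert (call.ref_aa, call.var_aa) == ("Y", "*")

    def test_frameshift_and_inframe_indels(self):
        g = simple_gene()
        fs = annotate_effect(VariantSite("chr1", 4, "CTC", "C"), g)
        assert fs.category == "coding_frameshift"
        inframe = annotate_effect(VariantSite("chr1", 4, "CTCT", "C"), g)
        assert inframe.category == "coding_inframe_indel"

    def test_reference_mismatch_detected(self):
        g = simple_gene()
        with pytest.raises(ReferenceMismatchError):
            annotate_effect(VariantSite("chr1", 4, "G", "T"), g)

    @pytest.mark.parametrize("seed", range(5))
    def test_minus_strand_equals_mirrored_plus_construction(self, seed):
        """Effect calls on a minus-strand gene match the reverse-complemented
        plus-strand construction of the same locus."""
        rng = np.random.default_rng(seed)
        n_codons = int(rng.integers(4, 30))
        body = "".join(rng.choice(["GCT", "CTC", "TAC", "CCG", "AAA", "TGG"], n_codons))
        cds = "ATG" + body + "TAA"
        span_len = len(cds)
        # minus-strand gene: plus-strand sequence is revcomp of the CDS
        minus = GeneModel(
            "M", "chr1", "-", (1, span_len), [(1, span_len)],
            str(Seq(cds).reverse_complement()),
        )
        plus = GeneModel("P", "chr1", "+", (1, span_len), [(1, span_len)], cds)
        # pick a CDS position on the plus construction and mirror it
        pos_plus = int(rng.integers(4, span_len - 3))
        ref_plus = cds[pos_plus - 1]
        alt_plus = rng.choice([b for b in "ACGT" if b != ref_plus])
        pos_minus = span_len - pos_plus + 1
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        call_plus = annotate_effect(VariantSite("chr1", pos_plus, ref_plus, str(alt_plus)), plus)
        call_minus = annotate_effect(
            VariantSite("chr1", pos_minus, comp[ref_plus], comp[str(alt_plus)]), minus
        )
        assert call_plus.category == call_minus.category
        assert call_plus.ref_aa == call_minus.ref_aa
        assert call_plus.var_aa == call_minus.var_aa
        assert call_plus.aa_pos == call_minus.aa_pos


class TestCascade:
    def _load(self, cohort):
        genes = read_gene_models(cohort.gene_models, cohort.fasta)
        cands = CandidateGeneSet(
            read_gene_list(cohort.targets), read_gene_list(cohort.adme)
        )
        return genes, cands

    def test_embedded_coding_variants_reproduce_printed_aa_pairs(self, discovery_cohort):
        """Every embedded coding variant translates to its printed amino-acid pair:
        9 synonymous rows, 6 missense rows across 4 genes."""
        genes, _ = self._load(discovery_cohort)
        by_symbol = {g.gene: g for g in genes}
        n_syn = n_mis = 0
        for v in CODING_VARIANT_PLAN:
            call = annotate_effect(
                VariantSite(v.chrom, v.pos, v.ref, v.alt), by_symbol[v.gene]
            )
            assert (call.ref_aa, call.var_aa) == (v.ref_aa, v.var_aa), v
            if v.ref_aa == v.var_aa:
                assert call.category == "coding_synonymous"
                n_syn += 1
            else:
                assert call.category == "coding_missense"
                n_mis += 1
        assert n_syn == 9 and n_mis == 6

    def test_cascade_counts_on_embedded_cohort(self, discovery_cohort):
        """15 coding variants in 9 genes; 6 non-synonymous in 4; 5 in SLC15A2."""
        genes, cands = self._load(discovery_cohort)
        matches = [
            SubclassMatch(VariantSite(v.chrom, v.pos, v.ref, v.alt), frozenset({1}), True)
            for v in CODING_VARIANT_PLAN
        ]
        rep = run_cascade(matches, genes, cands)
        assert rep.n_coding == 15 and rep.n_nonsynonymous == 6
        assert len({c.gene for c in rep.coding}) == 9
        assert len({c.gene for c in rep.nonsynonymous}) == 4
        assert sum(1 for c in rep.coding if c.gene == "SLC15A2") == 5
        counts = (
            rep.n_associated, rep.n_in_candidate_genes, rep.n_coding, rep.n_nonsynonymous
        )
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_decoys_outside_candidate_spans_drop_to_zero(self, discovery_cohort):
        genes, cands = self._load(discovery_cohort)
        decoys = [
            SubclassMatch(VariantSite("chr22", 5_000_000 + i, "A", "G"), frozenset({1}), True)
            for i in range(10)
        ]
        rep = run_cascade(decoys, genes, cands)
        assert rep.n_in_candidate_genes == 0
        assert rep.n_coding == 0 and rep.n_nonsynonymous == 0
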