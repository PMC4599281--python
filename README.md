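# sorascan

Extreme-responder pharmacogenomics for small cohorts: **sorascan** implements,
as a tested and reusable pipeline, the analysis used to find germline variants
associated with the response of hepatocellular-carcinoma (HCC) patients to the
multikinase inhibitor sorafenib — perfect-segregation scanning of genotypes
against responder status, a candidate-gene → coding → non-synonymous annotation
cascade, and genotype-stratified survival validation in an independent cohort.
It is aimed at researchers who want to reproduce, stress-test or adapt the
extreme-phenotype segregation design without access to patient-level data:
every input the pipeline needs can be simulated by the built-in generators.

## The method

**Segregation scan.** Each diploid genotype is coded as the count
*g* ∈ {0, 1, 2} of alleles differing from the reference genome ("A" alleles;
reference-matching alleles are "B"). With the cohort split into good and poor
responders by a time-to-progression (TTP) threshold (default 5 months), a
variant is *100% associated* with response when its genotype vector satisfies
one of four inheritance subclasses:

| subclass | model        | good responders | poor responders |
|----------|--------------|-----------------|-----------------|
| 1        | A-dominant   | g ≥ 1           | g = 0           |
| 2        | A-recessive  | g = 2           | g ≤ 1           |
| 3        | B-recessive  | g = 0           | g ≥ 1           |
| 4        | B-dominant   | g ≤ 1           | g = 2           |

Because the filter is an exact match rather than a test statistic, the package
also reports its implied null calibration: for *n_g* good and *n_p* poor
responders, the number of complete genotype vectors matching any subclass is
2·2^*n_g*​ + 2·2^*n_p*​ − 2 (46 of the 3⁷ = 2187 vectors for the 4/3 design),
verified against brute-force enumeration.

**Annotation cascade.** Associated variants are filtered to candidate gene
bodies (sorafenib-target and ADME genes, introns included), classified by
genomic feature, and coding SNVs are called synonymous/missense/nonsense by
locating the affected codon in the CDS-concatenated reading frame (minus-strand
genes are reverse-complemented; indels are frameshift/in-frame by length).

**Survival validation.** Candidate SNPs are validated in an independent cohort
with pairwise linkage disequilibrium (EM haplotype frequencies → D, D′, r²),
Kaplan–Meier curves per genotype stratum (homozygous-reference vs carrier by
default, e.g. C/C vs C/T-or-T/T), the log-rank test, and a Cox
proportional-hazards model adjusted for tumour stage, reporting
HR = exp(β) with a Wald 95% CI. NGS-vs-array genotype concordance is available
as a QC step.

**Synthetic cohorts.** `sorascan.synthetic` generates a 4-good/3-poor discovery
cohort (planted subclass variants, rejection-sampled decoys, and gene models
whose codon context reproduces the 15 validated coding variants, including
SLC15A2 L350F/P409S/R509K) and an independent survival cohort with
Hardy–Weinberg genotypes, exponential event times whose hazard depends on
genotype (default HR 2.18 for C/C), and independent censoring.

## Worked example

```python
from sorascan import *
from sorascan.synthetic import (DiscoveryDesign, ValidationDesign,
                                make_discovery_cohort, make_validation_cohort)
from sorascan.core_io import read_survival_table

c = make_discovery_cohort(DiscoveryDesign(seed=7), "demo/discovery")
matrix = read_vcf(c.vcf)
rows = read_sample_sheet(c.sample_sheet)
labels = classify_responders(rows, ttp_threshold=5.0)
hits = scan(matrix, labels)
genes = read_gene_models(c.gene_models, c.fasta)
cands = CandidateGeneSet(read_gene_list(c.targets), read_gene_list(c.adme))
rep = run_cascade(hits, genes, cands)
print(f"cascade: {rep.n_associated} -> {rep.n_in_candidate_genes} in candidate genes "
      f"-> {rep.n_coding} coding -> {rep.n_nonsynonymous} non-synonymous")
for call in rep.nonsynonymous:
    print(f"  {call.gene:8s} {call.site.chrom}:{call.site.pos} "
          f"{call.site.ref}>{call.site.alt}  {call.ref_aa}{call.aa_pos}{call.var_aa}")

surv, geno = make_validation_cohort(ValidationDesign(n=2000, seed=1), "demo/validation")
records = read_survival_table("demo/validation/survival.tsv")
strata = genotype_strata({r.sample: r.group for r in records}, "dominant", ref_allele="C")
for r in records:
    r.group = strata[r.sample]
res = cox_fit(records, covariates=("group", "stage"), risk_group="C/C")
lo, hi = res.ci95["group"]
print(f"Cox (stage-adjusted): HR={res.hr['group']:.2f} (95% CI {lo:.2f}-{hi:.2f}), "
      f"Wald p={res.wald_p['group']:.4f}")
```

prints

```
cascade: 19 -> 19 in candidate genes -> 15 coding -> 6 non-synonymous
  FMO3     chr1:171076966 G>A  E30K
  SLC15A2  chr3:121643804 C>T  L350F
  SLC15A2  chr3:121647286 C>T  P409S
  SLC15A2  chr3:121648168 G>A  R509K
  ABCB1    chr7:87160618 A>C  S30A
  MUSK     chr9:113538122 G>A  M30I
Cox (stage-adjusted): HR=2.23 (95% CI 1.84-2.70), Wald p=0.0000
```

The 19 perfectly segregating variants are the 15 embedded coding variants plus
4 planted intronic ones; the cascade narrows them to 15 coding calls in 9 genes
and 6 amino-acid-changing calls in 4 genes (5 of the coding variants sit in the
peptide transporter SLC15A2). The Cox fit on a 2000-patient simulated
validation cohort recovers a hazard ratio close to the generating value of 2.18
for C/C patients relative to T-allele carriers of the lead SNP rs2257212
(L350F); at the realistic cohort size of 174 the point estimate is noisier, as
expected.

The same chain is available from the shell:

```sh
sorascan run-all --out results_dir --seed 7
sorascan simulate discovery --seed 7 --out sim/
sorascan scan --vcf sim/discovery.vcf --samples sim/sample_sheet.tsv --out scan.tsv
```

`run-all` writes TSV tables for every stage plus a `manifest.json` recording
inputs, seed, and stage counts; reruns with the same seed are byte-identical.

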