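# Methods

## Scope and model

sorascan reproduces, at desk scale, the analysis design of an extreme-responder
pharmacogenomic study in hepatocellular carcinoma: a tiny discovery cohort
(4 good / 3 poor responders to sorafenib by time-to-progression) is scanned for
germline variants whose genotypes segregate *perfectly* with responder status,
the survivors are narrowed through a candidate-gene annotation cascade, and the
resulting candidate SNPs are validated by genotype-stratified survival analysis
in an independent cohort. The package implements the statistics and the data
plumbing; it does not perform read alignment, variant calling, array
processing, pathway enrichment or any wet-lab step.

## Responder classification

Samples carry either an explicit good/poor label or a TTP in months; an
explicit label wins. Without one, a sample is a good responder iff
TTP > `ttp_threshold`. The threshold defaults to 5 months — the study's cutoff
for its poor responders — and is overridable because the original split was an
explicit judgement call, not an estimated quantity. Classification fails loudly
if either class ends up empty, since perfect segregation is then undefined.

## The segregation scan

Genotypes are counts g ∈ {0,1,2} of the allele differing from the reference
genome ("A"); "B" is the reference-matching allele. The four subclasses are the
unique dominant/recessive readings of an A/B coding:

* subclass 1 (A-dominant): every good responder carries A (g ≥ 1), every poor
  responder none (g = 0);
* subclass 2 (A-recessive): every good responder is A-homozygous (g = 2),
  every poor responder is not (g ≤ 1);
* subclass 3 (B-recessive): mirror of 2 — good g = 0, poor g ≥ 1;
* subclass 4 (B-dominant): mirror of 1 — good g ≤ 1, poor g = 2.

The defining supplementary figure of the source study is not available, so the
definitions were fixed by two consistency requirements: (i) subclasses 1/4 are
dominant and 2/3 recessive with respect to the good-responder class, and
(ii) exchanging the A/B allele labels (g → 2−g) must map 1↔4 and 2↔3. The
second requirement is asserted as a property test on random genotype vectors.
All satisfied subclasses are reported per site (the downstream cascade only
needs non-emptiness). Note that relabelling good↔poor does *not* map 1↔3; only
the allele flip is a symmetry of the rule set.

Sites with any missing genotype are excluded from "100% associated" by default
(a perfect match cannot be asserted on incomplete data); a `tolerate` policy
instead drops missing samples from the rule check, refusing to match if a
responder class loses all definite calls. Calls with one undetermined allele
("./1") are treated as missing for the same reason.

Because the filter is an exact match, no multiple-testing correction applies;
instead `null_match_count` documents the implied false-positive calibration.
For n_g good and n_p poor responders the per-subclass counts of matching
complete vectors are 2^n_g, 2^n_p, 2^n_p, 2^n_g, and inclusion–exclusion
leaves union = 2·2^n_g + 2·2^n_p − 2 (the only non-empty pairwise
intersections are 1∩2 and 3∩4, one vector each). The closed form is tested
against brute-force enumeration for all cohort sizes up to 4+4.

## Annotation cascade

"Located within regions for candidate genes" is interpreted as the gene body
(transcription start–end, introns included) with a configurable flank
defaulting to 0 bp: in the source analysis 708 of 1813 associated variants fell
in candidate genes while only a handful were exonic, so the region filter must
include introns. A site overlapping several candidate genes counts once in the
cascade but keeps every gene assignment.

Feature classification is coarse by design (coding / UTR / intronic): CDS
positions are coding; outside the CDS, exonic positions are UTR and intron gaps
intronic when exon structure is known (BED12 blocks, GFF3 exon features). When
only CDS intervals are available, in-span positions outside the CDS extent are
called UTR and gap positions intronic — an approximation that reproduces the
coarse categories without a transcript database. There is no splice-site
category.

Coding SNVs are translated in the CDS-concatenated frame: the affected codon is
located by CDS offset (for minus-strand genes the concatenation is
reverse-complemented and the offset measured from the strand-correct 5′ end),
and the reference vs variant codons are translated under the standard genetic
code (Biopython's table). Synonymous/missense/nonsense are exhaustive and
mutually exclusive for SNVs; CDS indels are frameshift iff the length
difference is not a multiple of 3, in-frame otherwise. Variant alleles are
always expressed on the plus strand (VCF convention); strand is applied only at
translation. A disagreement between the gene model's sequence and a variant's
stated reference allele raises a reference-mismatch error rather than guessing.

## Survival validation

* **Strata.** The default stratification is dominant: homozygous-reference vs
  carrier (e.g. C/C vs C/T-or-T/T), matching the validation analysis that
  pooled heterozygotes with alternate homozygotes. Recessive and additive modes
  exist. The reference allele can be passed explicitly; this matters for the
  lead transporter SNP rs2257212, whose reference allele C is the *minor*
  allele in East-Asian cohorts, so frequency-based inference would invert the
  strata.
* **Kaplan–Meier.** Product-limit estimator with Greenwood variance
  (statsmodels `SurvfuncRight`); subjects censored at an event time count as at
  risk for that time. The reported median is the smallest event time with
  S(t) ≤ 0.5, undefined if S never reaches it.
* **Log-rank.** k-sample observed-minus-expected over pooled risk sets with
  hypergeometric variance (lifelines), χ² with k−1 df.
* **Cox PH.** Partial-likelihood maximization with Efron tie handling by
  default (lifelines; the source study does not state its tie method, and
  Efron is the default of the era's standard packages), Breslow available for
  cross-checking (statsmodels PHReg). Stage enters as an ordinal numeric
  covariate (BCLC A/B/C → 0/1/2 by default). Inference is Wald on the log-HR
  scale: CI = exp(β ± 1.96·se), two-sided p. Constant covariates are dropped
  with a warning (β = 0 reported); monotone likelihood (perfect separation) is
  flagged `converged=False` with no CI. The test suite cross-checks the fitted
  β against an independent golden-section maximization of a hand-written
  partial likelihood (agreement to 1e-6) and checks Efron = Breslow on
  tie-free data.
* **Linkage disequilibrium.** Haplotype frequencies for two biallelic SNPs are
  estimated from unphased genotypes by EM over the double-heterozygote phase
  ambiguity, initialized at linkage equilibrium (deterministic, no restarts),
  tolerance 1e-8, ≤ 100 iterations. D = p_AB − p_A·p_B, D′ normalizes by the
  allele-frequency bound, r² by the allele-frequency variances. Monomorphic
  input is an error (D′ undefined). On phase-unambiguous data the EM fixed
  point equals direct haplotype counting, which the tests assert.
* **Concordance QC.** Per-sample genotype-class agreement between two
  platforms' call matrices over shared (site, sample) pairs, missing pairs
  excluded from the denominator; reported as a percentage.

## Synthetic data

The generators define the study conditions; their defaults are the study's.

**Discovery cohort** (default 4 good / 3 poor, seven samples): the sample
sheet carries the printed per-patient TTPs {55.5, 38.1, 9.3, 8.1, 4.7, 3.5,
4.3} months, ages and maximum tumour sizes, so responder classification and
cohort summaries recompute the published 4/3 split and medians (60 y, 45 mm)
from generated files. The 15 validated coding variants are embedded by default:
for each of the nine genes a synthetic gene model is laid out at the real hg19
coordinates such that each variant's codon reproduces its printed amino-acid
pair. The layout solver enumerates (codon, within-codon offset, strand)
solutions per variant, picks a strand admitting all of a gene's variants, and
gives every target codon its own 3-bp CDS exon so its reading frame is exact
regardless of inter-variant spacing; intervening codons fill intermediate exons
and introns absorb the genomic distance (minimum intron 12 bp). The three
validated SLC15A2 missense SNPs are pinned to protein positions 350, 409 and
509 (L350F, P409S, R509K). Each gene's FASTA record is a kilobase-scale window
named in samtools-faidx region syntax (`chr3:121641430-121649781`), a
convention the FASTA reader understands, so genome-scale coordinates work
without genome-scale files. Every generated ORF starts with ATG and contains no
internal stop, which the readers verify.

Planted segregating variants (one per subclass by default) are placed in
candidate-gene introns with genotypes drawn to satisfy their subclass exactly;
decoy variants (default 96, on a gene-free chromosome) draw
genotypes from per-site binomial allele frequencies and are rejection-sampled
(≤ 1000 tries) until they satisfy no subclass. A truth table records every
planted (site, subclass). Missingness is applied uniformly at a configurable
rate (default 0).

**Validation cohort** (default n = 174, the study's size): genotypes at the
lead SNP are Hardy–Weinberg draws with T-allele frequency 0.75 (the reported
East-Asian range is 0.744–0.800); two further SNPs are generated in complete LD
by sharing haplotypes, mirroring the reported complete LD among the three
validated SLC15A2 SNPs. Event times are exponential with hazard
λ₀ · HR^{1[C/C]} · exp(stage_log_hr · stage); λ₀ defaults to ln 2 / 4.4 per
month so the carrier-dominated cohort reproduces the validation cohort's
median PFS of 4.4 months, and HR defaults to the reported 2.18. Censoring is an
independent exponential whose rate is calibrated so the expected censored
fraction (default 20%) holds under the genotype-mixture average hazard; a
censoring rate of 1 is rejected as degenerate. Stage is drawn from the
validation cohort's BCLC distribution (A/B/C = 1.2/20.1/78.7%), hazard-linked
only if requested (default off, so the stage adjustment is exercised without
confounding). All draws flow from one `numpy` generator seeded per run;
identical seed and design give byte-identical files.

What the generators do **not** emulate: read-level error, realistic LD beyond
the planted SNPs, population stratification, genotype-calling bias, and
non-exponential baseline hazards. Passing tests therefore demonstrate the
correctness of the *algorithms* under the study's design, not robustness to
real-data artefacts.

## Numerical and interface choices

* Internal coordinates are 1-based inclusive throughout (the convention of the
  printed variant table); the BED12 reader owns all 0-based half-open
  arithmetic, and the conversion is covered by an involution test.
* Multi-allelic VCF records are rejected by default (the analysis concerns
  biallelic SNVs) with an explicit split option.
* Chromosome names normalize to the `chrN` dialect via a single style switch.
* Problem sizes for the stochastic checks were chosen for stable verdicts at
  interactive cost: 200 replicates of n = 2000 for hazard-ratio recovery and
  CI coverage (MLE noise at n = 174 would swamp a 3% band), 50 seeds for
  planted-variant round trips, n = 10⁴ for the LD-null and Hardy–Weinberg
  checks.
* The Wald p-value is reported for the Cox genotype term; score and
  likelihood-ratio tests are not implemented (the source study does not state
  which it used).
* Multi-covariate Cox fits (e.g. genotype + stage) are supported; the
  pipeline's default model is the genotype indicator plus stage whenever stage
  varies.

## Known limitations

* UTR vs intron calls degrade gracefully but approximately when exon structure
  is absent (see above).
* The Cox fitter's separation diagnostic is heuristic (standard-error blowup),
  adequate for the cohort sizes here but not a substitute for exact logistic-
  style separation detection.
* The EM LD estimator assumes Hardy–Weinberg within the double-heterozygote
  resolution step, as the classical genotype-EM does.
* `null_match_count` describes the per-site null; it does not model linkage
  between sites, so it bounds rather than equals the genome-wide false-positive
  count under LD.
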