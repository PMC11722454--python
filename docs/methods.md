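# Methods

This note documents the models behind each stage of the pipeline, the
parameters that matter, and the design decisions taken where the design
was genuinely open.

## The locus model

The package models a biallelic VNTR with a 38-bp consensus unit
(`GGTGGGGATCTGTGGGATTGGTTTTCATGTGTGGGGTA`). Observed alleles cluster into
Short {24, 25.5, 27} and Long {40.5, 66.5} copy classes; no alleles occur
between 27 and 40.5. Copy numbers are carried at 0.5-copy granularity; a
half copy is represented as the first 19 bases of the consensus (the
partial unit is not defined by the observations, so half of the unit is
the natural choice). Classification uses Short ⇔ copies ≤ 30 and Long ⇔
copies ≥ 34: any cut inside the empty (27, 40.5) interval separates the
observed clusters, and an explicit INDETERMINATE gap surfaces
out-of-distribution alleles rather than silently assigning them. A
diploid sample is `LONG_ANY` iff at least one allele is Long — carriers,
not genotypic dosage, are what the depth signal can resolve.

All internal coordinates are 0-based half-open; SAM and VCF positions are
converted at the I/O boundary. Under this convention the profiled
interval chr5:1,275,210–1,277,500 spans 2,290 bp, consistent with the
printed width, and the reference amplicon arithmetic (2,241 bp minus a
1,267-bp internal deletion = 974 bp) is exact.

## Copy counting

`locate_flanks` finds each anchor by its best semi-global alignment
(edlib, edit distance ≤ 2 by default) and returns the interval strictly
between the hits. `count_repeat_copies` tiles the consensus greedily left
to right, mismatch-only (≤ 6 mismatches per 38-bp tile); a rejected
position advances the cursor one base. A terminal residual of length L
matching the consensus prefix with ≤ ceil(0.16·L) mismatches contributes
the nearest half copy, `round(L/38·2)/2`. Mismatch-only tiling is
adequate because substitutions dominate within-unit variation at the
scales modelled here; the test suite checks the greedy tiler against a
dynamic-programming segmentation oracle that allows indels, and exactness
on all five allele classes. Recovery stays within ±0.5 copies up to a 3%
per-base mutation rate.

## Depth classification

Per-base depth over the repeat interval is summarised as the median in
consecutive 50-bp windows (46 windows; the last covers 40 bp). Windows
are normalized by the sample's median flank depth — the observable signal
is *relative* pileup, so per-sample sequencing depth must be removed; the
features of a reference-like Short/Short sample sit near 1. The
classifier is elastic-net logistic regression (mixing 0.5, saga solver)
with the inverse penalty chosen on a 10⁻¹…10⁴ grid by 5-fold stratified
cross-validated AUC. `train_classifier` holds out a stratified 40% of
samples untouched and reports sensitivity, specificity, F1 and rank-based
AUC there, with `LONG_ANY` as the positive class and ties at probability
0.5 resolved positive. Under the default synthetic cohort (below) the
held-out AUC is ≥ 0.98; with the depth slope set to zero the same
protocol stays at chance, confirming the evaluation is honest.

## Tag-SNP discovery

SNPs are screened by MAF > 5% (allele-count frequency) and a 2×2
allele-count chi-square against the sample labels at p < 0.05 —
allele-level rather than genotype-level tables, matching the biallelic
framing (each sample contributes two chromosomes). Passing SNPs are
ranked by random-forest mean decrease in Gini impurity on 0/1/2 dosages
(500 trees, seeded) and the top 10% (≥ 1) retained. Because "combined
predictive strength" of a pair is not a standard forest output, the rule
pair is chosen directly: among the retained SNPs, the pair whose induced
haplotype rule maximizes sample-level agreement with the labels.
`induce_rule` maps a phased two-SNP haplotype to Long iff
P(Long | haplotype) > 0.5 in training; ties and unobserved haplotypes map
to Short (the majority class) with a warning. Rule induction needs
chromosome-level classes; when only sample labels exist, chromosomes
inherit their sample's label, which is conservative and adequate while
Long carriers are a minority. Unphased samples are called by evaluating
both allele orderings and flagging the sample ambiguous if the orderings
disagree on the diplotype class.

Validation statistics: Cohen's kappa with percent agreement (kappa
undefined when chance agreement is 1), complete-linkage hierarchical
clustering of coverage profiles on Euclidean distances (scipy linkage,
cut at 2 clusters; checked against a naive O(n³) agglomeration oracle),
and LD r² as the squared Pearson correlation of 0/1 chromosome-level
allele indicators.

## Splice-event classification

The gene model carries three contiguous half-open intervals
(exon4–intron4–exon5) and three constants: the INS1 offset (38 bp), the
INS1b offset (480 bp) and the minimum unspliced extension (20 bp). A read
is CANONICAL if a skip block spans exactly the intron; INS1/INS1b if a
skip starts at the corresponding offset inside the intron and ends at the
intron end (junction-level evidence — unambiguous per read, unlike
coverage-based support); UNSPLICED if a match block crosses the
exon4/intron4 boundary by ≥ 20 bp with no skip inside the intron; and
EXCLUDED otherwise, including 1–19-bp extensions. The fraction
denominator is canonical + INS1 + INS1b + unspliced; EXCLUDED reads never
enter any fraction. The retention fraction is the non-canonical share of
that denominator. Genotype trends are OLS of per-sample fractions on
additive dosage with optional sex/age covariates; constant covariates are
dropped with a warning.

## Quadruplex scanning

Bases score +min(k, 4) inside a run of k consecutive G, −min(k, 4) inside
a C run, 0 otherwise; sliding 25-nt means are thresholded at |mean| ≥ 1.2
(the published defaults of this scoring scheme, since no parameters are
stated for this locus). Window sums are computed exactly and divided
once, so threshold decisions do not depend on floating-point accumulation
order. `find_g4` merges overlapping or abutting same-sign windows into
maximal hits (score = max |window mean|; negative sign = quadruplex on
the reverse strand). For per-allele counting a merged-hit count is
uninformative: in a G-rich tandem array every window exceeds the
threshold and the entire array fuses into a single hit.
`count_g4_per_allele` therefore tiles thresholded windows greedily
without overlap, counting distinct quadruplex-forming stretches; a
mutation-free 24-copy array yields 36 and a 66.5-copy array 99, growing
linearly with copy number and consistent with the scale of per-allele
counts reported for alleles in this size range (tens to ~110).

## Association models

The composite marker codes each chromosome as (VNTR class, intron-4 SNP
allele), giving per-sample dosages over {Short-C, Short-T, Long-C,
Long-T} that sum to 2. Short-C — the most common haplotype — is the
omitted reference. Quantitative traits use OLS with two-sided Wald tests
per term; case/control outcomes use maximum-likelihood logit with odds
ratios and 95% CIs, flagging perfect or quasi-separation (|beta| > 15)
instead of reporting meaningless estimates. The age interaction is tested
by a likelihood-ratio test of dosage × age-group (5-year bins anchored at
the cohort minimum — wide enough to avoid age heaping) against the
main-effects model. No multiple-testing correction is applied inside
these functions; callers screening many markers should add their own.
Copy-number group comparisons use the two-sided Wilcoxon–Mann–Whitney
test, exact when both groups have ≤ 8 observations (matching exhaustive
enumeration) and tie-corrected normal approximation otherwise.

## Synthetic cohorts

`SimConfig` defaults define the study conditions:

| parameter | default | rationale |
|---|---|---|
| `n_samples` | 605 | size of the labelled training cohort in the emulated protocol |
| `long_freq` | 0.20 | Long-allele frequency; carrier fraction 1 − 0.8² = 0.36 |
| `short_copy_probs` | 24: 0.25, 25.5: 0.25, 27: 0.50 | mean 25.9 copies, matching the reported Short-allele mean |
| `long_copy_probs` | 40.5: 0.875, 66.5: 0.125 | 66.5 is the rare Long allele |
| `baseline_depth` | 30 | 30× whole-genome coverage |
| `depth_dispersion` | 10 | negative-binomial size; overdispersed depth |
| `depth_alpha` | 1.0 | slope of repeat-interval depth on total copies |
| `tag_fidelity` / `tag_background` | 0.97 / 0.03 | tagging-haplotype rates on Long/Short chromosomes; the background rate puts synthetic kappa in the upper part of the 0.78–0.95 band seen on real data |
| `n_noise_snps` | 58 | panel size 61 with the two tag SNPs and the intron-4 SNP |
| `snp_t_given_long` / `short` | 0.90 / 0.10 | gives r² ≈ 0.5 between the intron-4 SNP and the Long allele, near the reported European-population value |
| `event_probs` | per genotype | canonical 68.3/63.8/57.3% and INS1b 0/3.8/7.0% for CC/CT/TT; INS1 fixed at 2%, the remainder unspliced (unspliced > INS1, matching the reported ordering) |
| `pheno_effects` | −12.2 (Short-T), −15.92 (Long-C), −24.18 (Long-T) | additive haplotype effects on the quantitative trait, relative to Short-C |
| `pheno_sd` | 30 | residual scale relative to an intercept of 59.7 |

Depth is drawn per base as NB(mean, size) with mean
`baseline × (1 + alpha·(C − 54)/54)` inside the repeat interval (C =
total diploid copies; 54 = 2 × 27 reference copies) and `baseline` in the
flanks, so reference-like samples are flat in expectation. The linear
slope is an assumption — the emulated observations are qualitative
pileups only — and is exposed as `depth_alpha`.

The tag panel places the designated 1-1 haplotype on Long chromosomes
with probability 0.97 and on Short chromosomes with probability 0.03;
untagged chromosomes draw one of the three Short-associated haplotypes
with probabilities 0.8/0.1/0.1. The skew makes each tag SNP individually
the strongest marginal predictor while only their joint haplotype
separates the classes — the discovery structure the pipeline is designed
to recover. Noise SNPs draw MAF ~ U(0.01, 0.5) and fidelity
f ~ U(0.5, 0.85); each chromosome copies the VNTR class indicator with
probability 2f − 1 and otherwise draws Bernoulli(MAF), so f = 0.5 is
exact independence and the maximum induced allele-class correlation is
0.7.

Spliced reads draw an event class per read from the genotype's mixture
and place start positions uniformly subject to the class-defining feature
lying strictly inside the read, so classification recovers the generating
class for every read (verified exhaustively at 10⁵ reads). Generators use
independent, named random streams derived from the single seed; outputs
are byte-identical across runs of the same configuration.

**What the generators do not emulate:** sequencing errors and mapping
bias in reads, realistic LD decay (noise-SNP LD is exchangeable, not
positional), depth waviness from GC or mappability, allele-length
mosaicism, or cohort structure/relatedness. Passing tests therefore
demonstrate correctness of the algorithms under the stated statistical
model, not robustness to real-data artefacts.

## Numerical choices and degenerate inputs

- Window medians use numpy's interpolated median; the last partial window
  is kept.
- Classifier probability ties at 0.5 call the positive class; the
  positive class for sensitivity/specificity is always `LONG_ANY`.
- Chi-square tests use no continuity correction (calibration at the
  nominal level is verified by simulation over 1,000 null SNPs).
- Monomorphic SNPs are excluded from screening (MAF 0); monomorphic
  vectors make LD r² undefined and raise.
- Empty-denominator splice fractions are NaN and the retention fraction
  raises; `EXCLUDED` reads never enter denominators.
- Identical profiles in clustering produce an arbitrary but deterministic
  split with a warning.
- Problem sizes in tests and in `scripts/acceptance.py` follow the
  documented cohort defaults (605 samples for the classifier; 100 samples
  × 5,000 reads per fixed-genotype splice cohort), which resolve the
  target quantities to well within their stated tolerances.

## Known limitations

- The copy counter's greedy tiler assumes substitution-dominated units;
  high indel rates would require the DP segmentation (used here only as a
  test oracle).
- The haplotype caller assumes biallelic SNPs and diploid samples; no
  imputation or phasing is performed — phased input is consumed as given.
- The per-allele quadruplex count depends on the window/threshold choice;
  counts are comparable within a parameter setting, not across settings.
- Association models are complete-case: samples with missing genotypes
  are the caller's responsibility to drop (missing calls are explicit
  sentinels/`None`, never silently imputed).
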