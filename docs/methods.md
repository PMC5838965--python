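# Methods

This note documents the statistical models implemented in `becseq`, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical conventions that matter for
reproducing results.

## Internal-standard quantification

A competitive internal standard (IS) is a synthetic template co-amplified
with the native target by the same primers in the same reaction. Because
both templates see the same amplification factor, that factor cancels in
the read ratio and

    molecules = spike · native_reads / is_reads

estimates the number of native molecules loaded, with noise limited to
counting (Poisson) error. Abundance is reported as target molecules per
10⁶ ACTB molecules, which removes between-sample differences in cDNA
input. ACTB is quantified from its own IS first; a sample whose ACTB assay
fails the read filter fails QC as a whole (`sample_fail`).

Filters and defaults:

* **Stochastic-sampling filter**: both native and IS counts must reach
  `min_reads = 20`. At 20 reads the Poisson CV of a single count is ≈ 22 %,
  so below this the ratio is sampling-noise dominated. The threshold is
  configurable and recorded in the QC report; missing cells carry typed
  reason codes (`native_low`, `IS_low`, `sample_fail`) because low
  expression and assay failure are different facts.
* **Representation filter**: an assay is retained when measured in at least
  70 % of subjects (boundary inclusive: 42/60 passes).
* **Imputation**: missing cells of retained assays get the full-cohort
  per-assay mean, the convention of the classifier workflow this package
  follows. This leaks information across CV folds; the library keeps
  imputation a separate, explicit step so a leak-free variant (impute
  within training folds) can be substituted by the caller.
* **RNA integrity**: with oligo-dT priming, degraded RNA depresses signal
  at 5′-distal assays, so the per-subject 5′/3′ abundance ratio of a
  control gene (ACTB) is a degradation score; subjects under a
  configurable threshold (default 0.2) are flagged.

## Differential allelic expression

In a heterozygote, gDNA contains the two alleles 1:1, so the distribution
of log2(count_A/count_B) across gDNA heterozygotes measures analytic noise
only. A linked cis-regulatory variant shifts the cDNA allelic balance of a
heterozygous subject in a direction set by phase; across subjects this
inflates the variance of the cDNA log ratio without necessarily moving its
mean. The test is therefore a variance comparison:

    F = s²(cDNA log2 ratios) / s²(gDNA log2 ratios),  df = (n₁−1, n₂−1)

with unbiased (n−1) sample variances. The default alternative is the upper
tail (cDNA variance exceeding gDNA is the biological signal); a two-sided
option exists. Bonferroni adjustment uses the number of sites in the
analysis batch.

Genotypes are called from gDNA minor-allele read fractions: heterozygote
in [0.25, 0.75], homozygote ≤ 0.05, otherwise ambiguous and excluded.
cDNA samples without a matched gDNA call can be self-called with a wider
band [0.10, 0.90] and are flagged lower-confidence; by default all gDNA
heterozygote ratios are pooled as the control group (a matched-only mode
exists). Hardy-Weinberg goodness of fit is the 1-df chi-squared against
p², 2pq, q² with allele frequencies estimated from the counts.

## Correlation networks

Edges join assays whose log10 abundances correlate at two-sided p < 0.05
within a cohort (`t = r·sqrt((n−2)/(1−r²))`, n−2 df), using
pairwise-complete observations on the *pre-imputation* matrix — imputing
with column means before correlating would bias r toward 0 for exactly
the assays with most missingness. No multiple-testing correction is
applied to the edge filter; the network is a descriptive summary.
Non-positive abundances are treated as missing under the log transform
(zero means undetected). Constant columns leave their node isolated with
a warning.

Node metrics: degree; shortest-path betweenness normalized by
(n−1)(n−2)/2; harmonic closeness (mean of 1/d) normalized by n−1 — chosen
because thresholded correlation graphs are routinely disconnected, where
classic closeness is undefined. The correlation graph is undirected
(Pearson r is symmetric), so "in/out degree" distinctions collapse to
total degree. Cohorts are compared by two-sided Wilcoxon rank-sum tests on
the per-node metric vectors: exact null distribution when the pooled
sample is ≤ 20 without ties, otherwise the normal approximation with tie
and continuity corrections. Individual gene-pair correlations are compared
with the Fisher r-to-z statistic
`z = (atanh r₁ − atanh r₂)/sqrt(1/(n₁−3) + 1/(n₂−3))`.

## Shrinkage LDA and CAT scores

With p ≈ 35–50 features and n = 60 subjects, the pooled covariance is
near-singular, so both of its factors are regularized:

* variances: `v_k = λ_v · median(s²) + (1−λ_v) · s²_k` with the analytic
  James-Stein intensity `λ_v = Σ Var̂(s²_k) / Σ (s²_k − median)²`, clipped
  to [0, 1];
* correlations: `R* = (1−λ)R + λI` with the variance-minimizing intensity
  `λ = Σ_{k<l} Var̂(r_kl) / Σ_{k<l} r²_kl`, clipped to [0, 1].

The CAT (correlation-adjusted t) score is `τ = (R*)^{−1/2} t`, the
shrunken two-sample t-score vector decorrelated by the symmetric inverse
square root (eigendecomposition) of R*; features are ranked by |τ|, ties
broken by feature name for determinism. The discriminant uses
`Σ = D^{1/2} R* D^{1/2}` with empirical class priors; posteriors come from
the two-class linear rule. Forcing λ = λ_v = 0 reproduces textbook LDA
exactly (a tested identity); λ = 1 gives diagonal discriminant analysis.

Model size is selected by pooled k-fold (default 10, stratified) CV:
within each training fold features are re-ranked and the top-s model fit
for every candidate size s ∈ {1..15}; out-of-fold posteriors are pooled
and the AUC computed once per size by the rank statistic (ties get half
credit); the smallest size maximizing pooled AUC wins. Note that the
selected size's AUC is a maximum over candidates and is therefore
optimistically biased under the null — the test suite checks CV
calibration at a fixed size, where the pooled AUC is correctly centred at
0.5 under label permutation. Demographic covariates (sex as 0/1, age,
pack-years) enter as ordinary features on their natural scales; LDA with a
full covariance is affine-equivariant, so standardization is unnecessary.

The report adds a stratified percentile-bootstrap 95 % CI for the AUC
(2000 resamples; the CI method for such studies is often unstated, and the
percentile bootstrap is assumption-light at n = 60), the Youden cut-point
(threshold over observed posteriors maximizing sensitivity + specificity
− 1; under repeated CV, the median of per-repeat optima; rule: positive if
score ≥ threshold, smallest maximizing threshold on ties), and the
diagnostic odds ratio with Woolf logit CI and Haldane-Anscombe 0.5
correction when a cell is zero.

## Cohort statistics

Fisher's exact test (probability-mass two-sided rule, the R convention)
for categorical demographics; pooled-variance Student t (Welch by flag)
for continuous ones. ANCOVA is the least-squares fit
`y ~ intercept + group + covariate` on log10 abundance, one covariate at a
time; the adjusted difference is the group coefficient and its partial F
(= t²) tests the group term. With no covariate this reduces exactly to the
pooled t test. A covariate collinear with group cannot be adjusted for;
the unadjusted result is returned with a flag. The DAE-enrichment
comparison of two proportions uses the N−1 chi-squared (Pearson's
chi-squared scaled by (N−1)/N, the recommended small-sample form); both
published background proportions (lung 5884/19725 and lymphoblastoid
2935/9751) are computed since either is a defensible reference.

## GWAS integration

Intervals are 0-based half-open (BED) internally; SNP positions are
1-based (VCF) on input and converted on ingestion, so a SNP at 1-based
position P overlaps [start, end) iff start ≤ P−1 < end. Lookup is a
per-chromosome sorted sweep with binary search. Gene intersection pads
spans by a configurable flank (default 10 kb, a conventional
cis-regulatory window). Chromosome-naming mismatches ("chr1" vs "1")
raise rather than silently returning the empty set. D′ is computed from
two-site haplotype counts as |D|/D_max with the standard D_max cases;
monomorphic sites are an error, not a 0.

## The synthetic-data generator

The generator emulates the study design the pipeline assumes, with every
parameter overridable:

* 30 COPD / 30 control subjects; demographics drawn to mirror the
  published margins (male fraction 22/30 vs 11/30, ages ≈ N(64, 5),
  pack-years ≥ 20, current-smoker fractions ≈ 1/3); spirometry is drawn
  consistently with the cohort label (COPD ⇔ FEV1/FVC < 0.7 and
  FEV1% < 80).
* 68 assays on 35 genes (ACTB 5′/3′ pair plus 1–2 assays per target
  gene). Latent per-subject log2 abundance is multivariate normal:
  biological SD 0.8 log2 units; within-gene assay correlation 0.40; a
  per-subject input-scale factor (SD 0.5) multiplying every assay, which
  cancels on ACTB normalization; ACTB itself nearly constant (SD 0.1) as
  a housekeeping normalizer.
* COPD group shifts of +0.38 log2 on one assay of each of six classifier
  genes — calibrated once so the pooled-CV AUC of the default study is
  ≈ 0.75, the operating point of interest.
* COPD-specific wiring as a rank-1 pathway-activity factor: +0.30
  pairwise correlation among all 34 primary assays, positive definite by
  construction. This reproduces a much denser case network (≈ 220 vs
  ≈ 70 edges), which is the qualitative topology difference the network
  module is meant to detect; an arbitrary pair list is also accepted and
  validated for positive definiteness, with offending pairs named on
  failure.
* Reads: per-(subject, assay) Gamma amplification factor shared by native
  and IS template, Poisson sampling on top — marginally each count is
  negative binomial with dispersion 0.05, but the native/IS *ratio*
  carries Poisson-only noise, matching the competitive-template chemistry.
  Assays whose latent molecules fall below 4500 emit zero native reads
  (low-expression dropout): missingness is abundance-driven, not at
  random, and the default panel loses roughly a quarter of assays to the
  70 % filter (the real study lost about half).
* Allele counts at five transcribed SNPs in classifier genes, minor-allele
  frequencies 0.115–0.45, Hardy-Weinberg genotypes, 160 subjects (the
  allele analysis cohort exceeds the classifier cohort, as with archival
  samples). gDNA heterozygote allele fractions are logit-normal around 0.5
  (SD 0.15); cDNA adds β·g on the logit scale with unobserved phase
  g = ±1 (default β = 0.6), the variance-inflation signature the F test
  detects.
* Sequencing depth and spike quantities (3000 reads/assay, 10⁴ IS
  molecules) are not published quantities; they are explicit, documented
  defaults.

What the generator does **not** emulate: mapping or reference bias in
allele counts, PCR chimeras, batch effects, genuine biological pathway
structure beyond the planted blocks, linkage between the measured SNP and
the causal regulatory variant (assumed perfect), or uncertainty in the
demographic margins. Passing tests therefore demonstrate the statistical
machinery under the stated model, not robustness to these artifacts.

## Numerical conventions and degenerate inputs

Seeds: every stochastic routine takes an explicit seed or derives one
deterministically from the config; identical configs give byte-identical
tables. Zero IS reads → missing value with reason, never an exception;
zero gDNA variance → p at the machine floor with a flag; monomorphic HWE
input → p = 1 with a flag; |r| = 1 → Fisher transform error; edge filter,
significance filter, and Bonferroni decisions all use strict inequality.
The edge-significance boundary at n = 10 falls at r* ≈ 0.6319 (t(8) 97.5 %
point 2.3060); r = 0.632 is just inside significance (p = 0.049951).

## Known limitations

* Whole-cohort mean imputation before CV leaks label-free information
  across folds; kept as the default for fidelity to the workflow being
  reproduced.
* The pooled-CV model-size selection reports a maximum over candidate
  sizes; its AUC is optimistic by a few points. Nested CV would remove the
  bias at the cost of diverging from the reproduced design.
* Feature recovery at the default operating point is intrinsically noisy:
  with six signal features of per-feature t ≈ 2 among ~45 candidates at
  n = 60, no ranking reliably recovers the planted set (the test suite
  documents the achieved recovery rate rather than hiding it).
* The DAE F test assumes approximately normal log ratios; the generator's
  logit-normal noise is exactly normal on the log2-ratio scale, so the
  type-I calibration shown by the suite is a best case.
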