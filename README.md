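# becseq

Analysis toolkit for targeted RNA-seq of bronchial epithelial cells (BEC)
with competitive internal standards, built around a case/control COPD
study design: absolute transcript quantification, differential allelic
expression, co-expression network comparison, a shrinkage-LDA disease
classifier, and GWAS-integration utilities. A synthetic-data generator
reproduces the statistical structure of such a study end to end, so every
stage is testable without access to patient data.

## Who this is for

Groups running targeted amplicon expression panels on airway (or other)
epithelium who need the full downstream statistical chain, and
methodologists who want a reproducible harness for the individual pieces:
variance-based allelic-imbalance testing, correlation-adjusted t-score
(CAT) feature ranking, and internal-standard quantification.

## The models in brief

**Quantification.** Each assay co-amplifies the native transcript with a
known number of internal-standard (IS) molecules. The competitive design
makes the read ratio estimate the loaded molecule count independent of
amplification efficiency,

```
molecules = spike · native_reads / is_reads ,
abundance = 10^6 · molecules / ACTB_molecules .
```

Cells with fewer than 20 reads in either template are censored
(stochastic sampling error); assays measured in < 70 % of subjects are
dropped; remaining gaps are mean-imputed per assay.

**Differential allelic expression (DAE).** For heterozygotes, gDNA carries
each allele exactly once, so the spread of log2(allele A / allele B)
across subjects in gDNA is pure analytic noise. cis-regulatory variation
inflates that spread in cDNA. The test is a variance-ratio F test,

```
F = var(log2 cDNA ratios) / var(log2 gDNA ratios)  ~  F(n1−1, n2−1) ,
```

upper tail by default, Bonferroni-adjusted across sites.

**Networks.** Per-cohort graphs over assays with a Pearson edge when the
two-sided p of `t = r·sqrt((n−2)/(1−r²))` is < 0.05 on log10 abundance;
cohorts are compared by Wilcoxon rank-sum tests on per-node degree,
normalized betweenness, and normalized harmonic closeness, and individual
gene pairs by the Fisher r-to-z test.

**Classifier.** Two-class shrinkage LDA: pooled variances shrunk toward
their median, feature correlation shrunk toward the identity
(`R* = (1−λ)R + λI`, analytic λ), features ranked by the CAT score
`τ = (R*)^(−1/2) t`, model size chosen by pooled 10-fold cross-validated
ROC AUC, cut-point by Youden's J under repeated CV, performance summarized
by a stratified-bootstrap AUC CI and the diagnostic odds ratio.

**GWAS integration.** Restrict an association table to putative
cis-regulatory intervals (BED, 0-based half-open; SNP positions 1-based),
intersect with gene spans ± flank, keep p < 0.05, Bonferroni-validate
follow-up queries, and compute D′ linkage from two-site haplotype counts.

## Worked example

```python
from becseq import pipeline

res = pipeline.run_study(seed=1)
print(len(res.retained_assays), res.retained_genes)
print(res.networks["COPD"].n_edges, res.networks["control"].n_edges)
print(round(100 * res.cv_report.auc, 1), res.cv_report.selected_features[:4])
```

prints

```
50 34
221 70
83.3 ['pack_years', 'TP73_1', 'XPA_2', 'XPA_1']
```

— of the 68-assay panel, 50 assays on 34 genes survive the 70 %
representation filter; the simulated COPD cohort's correlation network has
221 significant edges against 70 in controls (the planted pathway-factor
wiring); and the CAT-ranked shrinkage-LDA classifier reaches a pooled
10-fold CV AUC of 83.3 % for this seed (mean ≈ 0.76 across replicate
studies), ranking planted signal genes and demographic covariates first.

The same steps are exposed as a CLI:

```
becseq simdata --out data/ --seed 1
becseq quantify --counts data/counts.tsv --out quant/
becseq dae --counts data/allele_counts.tsv --out dae.tsv
becseq netcmp --matrix quant/abundance.tsv --meta data/meta.tsv --out net/
becseq classify --matrix quant/abundance.tsv --meta data/meta.tsv --out clf.json
```

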