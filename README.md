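# methdyn

Does short-term, within-individual variation in DNA methylation explain
short-term variation in gene expression? `methdyn` implements the analysis
pipeline for answering that question from a densely sampled longitudinal
design — one individual, ~24 timepoints, paired bulk expression (FPKM) and
450K-style methylation (beta values) from a mixed leukocyte sample — plus a
synthetic-data generator with planted ground truth so that every inference
stage can be validated without access to any real cohort.

It is aimed at epigenomics analysts who have matched expression and
methylation time courses and want a tested, reproducible implementation of
the four stages below rather than a pile of one-off scripts.

## The four stages

1. **Cell-type deconvolution.** Bulk methylation is a mixture over cell
   types. Per sample *t*, proportions are estimated by constrained
   projection on a reference signature *S* (mean beta of signature CpGs in
   purified cell types):
   `w_t = argmin_{w ≥ 0} ‖S w − m_t‖²` (non-negative least squares; the raw
   projection is not forced to sum to 1).
2. **Dynamic genes.** Each gene's mean log₁₀(FPKM+1) places it in a
   0.05-wide abundance bin; within each bin, coefficient-of-variation
   (CV = SD/mean) outliers are flagged by the iterative one-sided
   Smirnov–Grubbs test, `G = (max CV − mean CV)/SD(CV)` against
   `G_crit(N, α) = ((N−1)/√N)·√(t²/(N−2+t²))`, `t = t_{α/N, N−2}`.
3. **CEA (composition/expression association).** Per gene, the ANOVA
   comparison of `M1: E_t = β₀ + Σ_c β_c P_ct` against `M0: E_t = β₀`
   (E on the log₁₀(FPKM+1) scale, P the estimated proportions), with
   rank-aware degrees of freedom because the proportions nearly sum to 1.
   Genes with p < 0.05 respond to composition, not necessarily to
   regulation in cis.
4. **MEA (methylation/expression association).** Genes are paired with
   CpGs within 5,000 bp of the TSS (SNP-overlapping probes excluded);
   expression and beta series are converted to ratios relative to Day 1;
   `Model 1: E_t = β₀ + β_m M_t` gives the variance in expression
   explained by methylation (R²), `Model 2` adds the best CEA cell type as
   a covariate (partial R²), and significance comes from a permutation
   test on the Spearman correlation (1,000 permutations of the expression
   vector, add-one corrected). CEA genes are excluded from the stratified
   report so composition effects cannot masquerade as cis regulation.

## Worked example

```sh
methdyn simulate --seed 5 --out data --n-genes 300 --n-cpgs 1800
methdyn run-all --data-dir data --out results --seed 6
```

The first command writes a complete synthetic study (expression and
methylation TSVs, annotations, a reference signature, and
`ground_truth.tsv` recording what was planted). The second runs all four
stages. On this seed the run prints

```
pipeline complete; results in results
```

and `results/` then contains, among others:

* `composition.tsv` — 24 samples × 6 leukocyte types; sums near 1
  (the generator's true compositions are recovered with a mean absolute
  error of about 0.001);
* `dynamic.tsv` — per-gene CV, bin, Grubbs statistic and flag;
* `strata.tsv` — the 2×2 dynamic × CEA count table;
* `mea_summary.json` — medians and IQRs of R², permutation p and per-CpG
  SD for dynamic vs non-dynamic pairs. For unplanted (null) pairs at 24
  timepoints the median Model-1 R² is ≈ 0.02: that is the baseline level
  of "variance explained" one gets by regression alone at this sample
  size, which is exactly why the permutation test, not R², carries the
  inferential weight.

The same stages are available individually (`methdyn deconvolve`,
`dynamic`, `cea`, `mea`) for real TSV inputs; every threshold in
`RunConfig` can be set by flag or YAML config.

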