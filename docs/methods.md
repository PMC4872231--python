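# Methods

## Design assumptions

The pipeline targets a strictly intraindividual design: one subject,
repeated sampling (default 24 timepoints), paired bulk RNA expression
(FPKM) and array methylation (beta values in [0, 1]) from a mixed
leukocyte sample. All stages assume complete matrices (no missing cells),
a shared, ordered set of timepoint labels after alignment (the expression
matrix's column order is authoritative), and 1-based genomic coordinates.
Autocorrelation across timepoints is deliberately not modelled: every test
treats the 24 observations as exchangeable, which is the right null for
"is there any systematic association" screens but means p-values would be
anticonservative if expression had strong day-to-day autocorrelation.

## Stage models

**Deconvolution.** Non-negative least squares of each sample's signature
betas on the reference signature. NNLS (active-set) finds the same optimum
as a quadratic-programming formulation of this convex problem, so no
bespoke QP solver is used. No sum-to-one constraint is imposed during
optimisation; rescaling to the simplex is a post-hoc option (default off),
and per-sample sums outside [0.8, 1.2] are QC-flagged. A rank check on the
signature rejects degenerate references up front.

**Dynamic genes.** CV is computed by default on the log10(FPKM+1) scale —
the same scale as the binning axis — with `cv_scale="raw"` available; the
sample SD uses the n−1 denominator. The Grubbs test is one-sided upper
(only unusually *variable* genes are of interest) and iterated to
exhaustion, with both choices configurable. Its critical value uses the
exact t-quantile identity, verified in the tests against an independent
root-finding oracle to 1e-8 over N = 3..200. Bins with fewer than
`min_bin_size` (3) genes are skipped; genes with zero expression at every
timepoint have no CV and are excluded with a log line; ties at the bin
maximum are broken toward the lexicographically first gene id, making
results order-independent.

**CEA.** The design [1 | P] is near-collinear because estimated proportions
sum to ~1 (exactly 1 for simplex compositions). The fit uses an SVD
pseudo-inverse with a relative singular-value cutoff of 1e-8, and the
F-test's numerator df is rank(M1) − 1, so a duplicated or dependent
composition column changes neither F nor p. A drop-one-column
parameterisation would give the identical F; the rank-aware route avoids
choosing which type to drop. The per-cell-type univariate regression
p-values (and the arg-min "best cell type") are an operational addition:
the joint ANOVA yields one p per gene, but the MEA adjustment needs a
single covariate series, and the cell type with the smallest univariate p
is the natural reading of "the most associated cell type". No multiplicity
correction is applied by default (raw p < 0.05 defines CEA), matching the
screening character of the stage; Benjamini–Hochberg is a config option.

**MEA.** Both series are divided by their Day-1 value (expression on the
log10(FPKM+1) scale first). Division by a constant preserves linear
relationships and R², so the transformation is a unit normalisation, not a
model change; series whose reference value is below 1e-6 are excluded
outright rather than stabilised with a pseudo-count, because inventing a
reference value would manufacture associations. Model-2's
methylation-attributed R² is the squared correlation between the
composition-adjusted partial residual (E − β̂₀ − β̂_CT·CT) and β̂_m·M — the
partial-R² convention; the plain joint-model R² is available via config.
The permutation p is two-sided on |ρ| with the add-one correction
(p ≥ 1/(B+1), B = 1000 by default), deterministic given the run seed;
one-sided is a config option. The CpG-level SD is computed on the raw beta
series (not the Day-1 ratios). Distribution comparisons between dynamic
and non-dynamic pair groups use the two-sided Mann–Whitney U test with tie
correction (Kolmogorov–Smirnov via config), reporting medians and IQRs
alongside p.

Stratification default: CEA genes are removed before the MEA report, so
that composition-driven expression variation cannot be attributed to
methylation; the unstratified variant (Model 2 adjustment on all genes) is
obtained by setting `mea_stratified: false` and supplying a composition
matrix.

## Synthetic data

The generator emulates the study conditions, not any particular dataset:

* **Composition** — per-timepoint Dirichlet draws over six leukocyte
  labels (CD8T, CD4T, NK, B cell, monocyte, granulocyte; labels only)
  with whole-blood-like means (0.08/0.15/0.07/0.05/0.10/0.55) and total
  concentration 100, giving day-to-day proportion SDs of ~0.02–0.05 —
  visible but modest composition drift.
* **Expression** — FPKM_gt = Σ_k w_tk·e_gk·exp(ε_gt); per-(gene, type)
  levels e_gk are log-normal (median ~5 FPKM, gene-level spread σ = 1.2 on
  the natural-log scale, type-level spread σ = 0.3) and ε ~ N(0, 0.05²).
  The type-level spread means many baseline genes are *genuinely*
  composition-associated, which is realistic for bulk leukocyte data and
  is why CEA flags far more than 5% of genes.
* **Dynamic genes** — a multiplicative fold change (default 4×) on one
  stimulus day (index 12), mimicking a transient inflammatory response;
  multiplicative because the detection axis is logarithmic.
* **CEA genes** — expression concentrated in one randomly assigned cell
  type, so the bulk series is an affine function of that type's
  proportion.
* **MEA pairs** — the CpG beta series is a smoothed random walk (SD 0.05
  on the beta scale) and the gene's log-expression is a + b·M_t + ξ with
  b and var(ξ) split against the realised variance of M so the population
  R² equals the target (default 0.5) exactly; a target of 1 implies zero
  noise.
* **Methylation baseline** — per-CpG levels from a bimodal mixture
  (Beta components at modes 0.1 and 0.9, weights 0.45/0.45, plus a 10%
  uniform shelf — the typical marginal shape of array betas) with iid
  temporal noise of SD 0.01, clipped to [0, 1]. With 24 timepoints the
  median per-CpG sample SD lands in [0.008, 0.012], the stability scale of
  repeated-sampling methylome data.
* **Signature CpGs** — 100 per cell type, high (0.70–0.95) in their own
  type and low (0.05–0.30) elsewhere, mixed through the true composition
  in the observed matrix; the pure matrix is emitted as the reference.
  Signature selection from sorted-cell panels is out of scope — the
  signature is an input.
* **Genome layout** — genes every 100 kb (so 5 kb TSS windows never
  overlap), three cis CpGs per gene of which 5% are SNP-flagged, MEA CpGs
  within ±2 kb of their own gene, signature and filler CpGs on distal
  contigs so they never enter the pair list.

All randomness flows from one seed through deterministically spawned child
generators; identical parameters and seed give bit-identical matrices.

What the generator does **not** emulate: probe-intensity noise and
normalisation artefacts, batch/chip effects, autocorrelated expression
dynamics, interindividual variation, and realistic linkage between CpG
density and gene class. Passing tests therefore demonstrate correctness of
the inference machinery under the stated generative model, not performance
guarantees on real arrays.

## Numerical choices

* Binning: left-closed right-open, `bin = floor(mean/width)`; a mean on a
  left edge opens its bin.
* TSS window: inclusive at exactly `window` bases; distances are signed
  and strand-adjusted but filtered on absolute value.
* Rank decisions (CEA design, signature) use a relative singular-value
  cutoff of 1e-8.
* Constant series conventions: CV of a constant positive series is 0; a
  constant response gives F = 0, p = 1 (CEA) and R² = 0 (MEA); a constant
  rank vector gives ρ = 0, p = 1 with a degeneracy flag.
* Permutation p never drops below 1/(B+1) (add-one correction) and ties
  between permuted and observed |ρ| count as at least as extreme.

## Problem sizes

The validation suite calibrates the three tests on 10,000 null
replicates each at the study's sample size (n = 24; bins of N = 50 for
Grubbs) and runs the full pipeline on a 5,000-gene × 20,000-CpG synthetic
study with 50 planted dynamic genes, 100 CEA genes and 50 MEA pairs —
sizes at which binomial confidence intervals around the nominal 5% level
are tight (±0.6%) and recovery fractions are stable across seeds.

## Known limitations

* The F-test and permutation test assume exchangeable timepoints; strong
  autocorrelation would inflate both.
* The "best cell type" covariate for Model 2 is selected on the same data
  it adjusts, a mild post-selection effect inherent to the procedure.
* NNLS composition estimates are consistent only insofar as the reference
  signature matches the sample's cell types; missing types inflate the
  residual and bias proportions upward for correlated types.
* R² values at n = 24 are optimistic (null median ≈ 0.02); they are
  reported as descriptive effect sizes, with inference carried by the
  permutation test.
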