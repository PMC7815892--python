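# Methods

## The synthetic spike-in benchmark

The generator emulates a three-proteome spike-in experiment: E.coli and
yeast protein digests mixed into a constant human background at designed
mass fractions, four groups (A–D) of eight replicates. Each protein `p`
receives a baseline abundance `b_p = 2^Normal(location, scale)` drawn once
and shared across samples; defaults are location 20 and scale 2 on log2
scale, giving intensities around 10^6 with a realistic dynamic range of
several orders of magnitude, and an observed log2 spread (σ ≈ 2) on which
the amputation threshold width σ_T = 0.3 is meaningful. Each sample `j`
applies a per-species scaling `prop(s, g) · (1 + ε_j)` with ε drawn at the
design's intragroup CV (default 0.05, a typical replicate-level variation
for spike-in experiments) and mean-centered within each group. Entry-level
multiplicative log-normal measurement noise (σ = 0.2 log2 units, i.e.
~15% CV, typical LFQ technical noise) is applied on top.

**Group-mean enforcement.** With the default `enforce_group_means=True`,
each protein's replicate block is rescaled so its arithmetic group mean
equals `b_p · prop(s, g)` exactly. Centering the species scalings alone
would leave the entry-level noise un-centered, and the product of two
mean-one factors is not itself mean-one; enforcing the constraint on the
composed entries makes the designed ratio table an exact property of every
generated dataset rather than an expectation. Consequently
`realized_ratio_table` (arithmetic group means, linear scale) reproduces
the designated ratios to machine precision at any CV and noise level. The
log2-scale (geometric-mean) ratios used downstream differ from the
designed values by a Jensen-gap term of order CV², far below the
imputation errors being measured.

A consequence worth knowing: human (background) proteins have *exactly*
equal linear group means, so their log2-scale t-tests on complete data are
conservative rather than uniform-null. False positives in the benchmark
therefore arise from imputation distortion, which is precisely the effect
the FADR metric is meant to isolate.

`significance_audit` checks the design contract on generated data: it sums
each species' linear intensities per sample, log2-transforms the totals and
runs the pipeline's pooled t-test for each group vs the control. At desk
scale (tens of proteins per species) the weakest contrast — yeast B/A,
ratio 0.9 — is occasionally borderline; the audit exists so such a dataset
can be rejected and regenerated.

**What the generator does not emulate:** peptide-level structure and
peptide→protein roll-up, correlated protein covariation within pathways,
batch effects, and the heavy-tailed error structure of real LC–MS
quantification. Passing tests on this benchmark therefore demonstrate
correctness of the pipeline's machinery and the qualitative method
ordering, not quantitative performance on any real dataset.

## Amputation

For a complete log2 matrix `D` with `N` entries, a total missing rate α and
MNAR share β are enforced as exact counts: `round(N·α·β)` MNAR entries and
`round(N·α) − round(N·α·β)` MAR entries. MNAR candidates are entries with
`D_ij < T_ij` and gate `P_ij = 1`, where `T_ij ~ Normal(q_α(D), σ_T)`
(σ_T = 0.3 log2 units, q_α the α-quantile over all values) and
`P ~ Bernoulli(β)`. Surplus candidates are uniformly subsampled; a
shortfall raises the quantile level in steps of 0.01 (with a fresh draw of
T) up to level 1, beyond which the configuration is reported as infeasible.
MAR entries are then drawn uniformly from the remaining observed entries.
Rows missing in every sample are removed (their ids retained), so every
retained protein keeps at least one observed value.

The count enforcement makes realized rates exact for every seed, at the
cost of the selection being conditional rather than fully i.i.d.; the MAR
step can still create MNAR-like patterns by chance, which is accepted
as-is. The quantile is computed over all values of the matrix, not per
sample. Whether amputation rates should be exact or merely expected counts
is genuinely open; exactness was chosen so that realized-rate checks and
downstream comparisons are deterministic.

## Imputation methods

All methods operate on the log2 matrix, never alter observed entries, and
are deterministic given a seed. Fallback paths are counted in the returned
diagnostics, never silent.

* **LOD** — every missing entry gets the global minimum observed value.
* **ND** — draws from `Normal(μ_m − 2.2·σ_m, 0.3·σ_m)` with μ_m, σ_m the
  mean and sample standard deviation of *all* observed values (a per-column
  variant is deliberately not the default; the global statistics match the
  convention of treating the dataset as one abundance distribution).
* **kNN** (k = 6) — neighbors are proteins. Distance is Euclidean over
  co-observed samples rescaled by `sqrt(n_samples / n_co_observed)`;
  candidates for a missing entry must be observed in that sample; the
  imputed value is the unweighted mean of the k nearest candidates' values.
  Fewer than k candidates: use all; none: the protein's own row mean.
* **LLS** (k = 150) — for each target protein the k most similar proteins
  by absolute Pearson correlation over the target's observed samples serve
  as regressors; the target's observed values are fit as a linear
  combination of the neighbors' values via the minimum-norm pseudoinverse
  solution, and missing entries are predicted from the neighbors' values in
  the missing samples. Neighbor values come from a row-mean-initialized
  copy of the matrix, since at realistic missing rates no protein is
  complete in all needed columns; degenerate targets fall back to row
  means.
* **RF** (ntree = 100) — the iterative missForest scheme with samples as
  variables and proteins as cases: initialize missing entries with column
  means, visit columns in increasing order of missing count, fit a random
  forest (mtry = ⌊√(n_cols−1)⌋, terminal node size 5, the standard
  regression-forest setting) of each column on all others over the rows
  observed in it, and predict its missing rows; sweep until the normalized
  squared difference between successive imputations increases (return the
  previous sweep) or 10 sweeps.
* **SVD** (nPCs = 2) — EM-style completion: row-mean initialization, then
  iterate column-center → rank-2 truncated SVD → replace missing entries
  with the reconstruction, until the relative change of the imputed entries
  falls below 1e-3 (max 100 iterations; non-convergence is flagged).
* **BPCA** (nPCs = 2) — variational Bayesian PCA: probabilistic PCA with
  isotropic noise and an automatic-relevance-determination prior on the
  loading columns, fit by EM over the observed entries of each row, with
  missing entries replaced by their posterior expectation. Initialization
  is the SVD of the row-mean-imputed matrix; convergence is a relative
  change of the noise precision below 1e-3. The ARD prior shrinks
  superfluous components, so the effective rank adapts to the data.

Matrix orientation is fixed: proteins are rows. kNN and LLS match proteins
(the "number of similar proteins" semantics of their k parameters); RF,
SVD and BPCA treat samples as variables, which keeps the forest problem
small (≤ a few dozen variables) and many cases. Convergence tolerances and
iteration caps are implementation choices; exact numeric parity with the R
reference packages (VIM, pcaMethods, missForest) is not a goal — their
distance metrics and update orders differ in details — but each method is
validated against independent oracles (brute-force neighbor enumeration,
normal-equation solutions, low-rank recovery) in the test suite.

## Scoring

* **Abundance NRMSE** = `sqrt(mean((imputed − truth)²) / var(truth))`
  over the originally-missing entries only, with the sample variance
  (n−1) of the true missing values, on log2 scale. Restricting to missing
  entries follows the usual imputation-error convention: observed entries
  pass through unchanged and would dilute the error toward zero.
* **Ratio NRMSE** — per-protein intergroup ratios
  `2^(mean log2 group − mean log2 control)` are compared with the designed
  ratios on linear scale (the designed values 1.5…2.5, 0.9…0.7 are linear
  fold changes), pooled over all proteins with a designed ratio, including
  human proteins at ratio 1, which dominate the matrix as they do in the
  data.
* **DE testing** — two-sided pooled-variance two-sample t-test
  (df = n_a + n_b − 2) per protein, Benjamini–Hochberg adjustment across
  the proteins of each comparison, significance at adjusted p < 0.05.
  Zero pooled variance is resolved by convention: p = 1 for equal means,
  p = 0 otherwise.
* **Confusion counts** — spike-in (E.coli, yeast) proteins significant in
  a B–D vs A comparison are TPs; significant human proteins are FPs;
  FADR = FP/(TP+FP) with 0/0 ↦ 0.
* **ROC** — for each adjusted-p threshold on a uniform grid over [0, 1],
  (FPR, TPR) is computed per repeat and averaged threshold-wise (vertical
  averaging); endpoints (0,0) and (1,1) anchor the curve and the AUC is
  trapezoidal.

## Orchestration

The grid defaults to MV rates {0.1, 0.2, 0.3} × MNAR shares
{0.2, 0.5, 0.8}. Within a (condition, repeat) cell, the amputation seed is
`base_seed + repeat`, and all methods receive the identical masked dataset
(verified by mask hashing), so method comparisons are paired. Per-cell
failures are recorded in the report rather than aborting the grid.

## Problem sizes

The full-scale benchmark (1,184 E.coli / 1,081 yeast / 4,424 human
proteins) is the generator's reference composition; `scaled_counts(n)`
preserves the species mix at any total. The package's own standing runs
use desk scales chosen to keep a single-CPU run comfortable: the
acceptance script evaluates the ratio targets and the RF FADR grid at
~800 proteins with 2 repeats per condition, and the test suite exercises the
method-ranking properties at ~800 proteins over 5 amputation seeds and the
RF FADR grid at ~400 proteins with 2 repeats. The qualitative properties
asserted (method ordering, MNAR-rate sensitivity, FADR control) are stable
across these scales; absolute NRMSE values shift slightly with matrix size
and are not asserted as constants.

## Known limitations

* Protein-level only; peptide-level missingness and roll-up are out of
  scope.
* The generator's independence assumptions (no protein-protein
  correlation beyond species scaling) make global-structure methods'
  task easier than on real data with pathway-level covariation.
* The amputation model underestimates the effective MNAR rate slightly,
  since uniformly drawn MAR entries can also fall in the censored tail.
* BPCA uses a standard variational approximation; second-order
  missing-entry correction terms are omitted from the noise update, which
  in practice changes imputations negligibly relative to the tolerance.
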