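# mvbench

Benchmarking missing-value imputation for label-free quantitative
proteomics, with spike-in ground truth.

Label-free LC–MS proteomics matrices routinely lose 10–30% of their entries
to missing values, a mixture of abundance-independent dropouts (MAR) and
abundance-dependent censoring below the detection limit (MNAR). Which
imputation method to use — and how badly a poor choice distorts downstream
differential-expression calls — is an empirical question that needs a
dataset where the true fold changes are known. `mvbench` provides the whole
evaluation loop as a reusable library and CLI:

1. **Synthetic spike-in benchmark** (`mvbench.generate`): a three-species
   design in which E.coli and yeast proteomes are mixed into a constant 70%
   human background across four groups (A–D, 8 replicates each). E.coli
   rises 5 / 7.5 / 10 / 12.5% and yeast falls 25 / 22.5 / 20 / 17.5% of
   total protein mass, so every protein's true intergroup ratio is known:
   E.coli 1.5 / 2 / 2.5 and yeast 0.9 / 0.8 / 0.7 vs the control group A,
   human identically 1. Per-sample intragroup variation (CV 5%) is
   mean-centered within each group so the designed ratios hold exactly.
2. **Controlled amputation** (`mvbench.amputate`): total missing rate α and
   MNAR share β are enforced as exact counts. MNAR entries are censored
   below a stochastic threshold `T ~ Normal(q_α(D), σ_T)` gated by a
   Bernoulli(β) coin; MAR entries are uniform over the remainder.
3. **Seven imputation methods** (`mvbench.impute`), re-implemented behind
   one interface: LOD (global minimum), ND (draws from
   `Normal(μ_m − 2.2σ_m, 0.3σ_m)`), kNN (k = 6 protein neighbors),
   LLS (local least squares on the k = 150 most correlated proteins),
   RF (iterative missForest scheme, ntree = 100), SVD and BPCA (rank-2
   low-rank completion; BPCA with an ARD prior).
4. **Scoring** (`mvbench.evaluate`): NRMSE of abundances (on the originally
   missing entries) and of intergroup ratios vs the designed values; pooled
   two-sample t-tests with Benjamini–Hochberg adjustment; TP counts and the
   false altered-protein discovery rate FADR = FP/(TP+FP), where spike-in
   species are true positives and human proteins false positives; ROC
   curves averaged over repeats.
5. **Orchestration** (`mvbench.benchmark`): the 3 MV rates × 3 MNAR rates
   grid with repeats, identical amputation masks shared across methods
   within each repeat, and aggregated reports.

## Worked example

```python
import mvbench as mb

design = mb.spikein_design()                      # 4 groups x 8 replicates
matrix = mb.generate_benchmark(design, mb.scaled_counts(800), seed=1)

print(mb.realized_ratio_table(matrix, design).round(3))
#            A    B    C    D
# species
# E.coli   1.0  1.5  2.0  2.5
# yeast    1.0  0.9  0.8  0.7
# human    1.0  1.0  1.0  1.0

md = mb.simulate_missingness(matrix.to_log2(),
                             mb.MissingnessSpec(alpha=0.2, beta=0.5, seed=7))
print(mb.missingness_summary(md)["mv_rate"])      # 0.2 exactly

for method in ("LOD", "ND", "RF"):
    imp = mb.impute(md, mb.ImputationConfig(method=method, seed=3))
    print(method, round(mb.nrmse_abundance(imp.values, md.truth, md.mask), 3))
# LOD 2.948
# ND 1.569
# RF 0.133
```

The NRMSE values show the core finding this benchmark is built to expose:
left-censored methods (LOD, ND) impute every missing value at the bottom of
the abundance distribution and incur large errors when half of the
missingness is actually random, while random-forest imputation reconstructs
missing entries from the correlated samples with an order of magnitude less
error.

The same pipeline is available from the shell:

```sh
mvbench generate --n-proteins 800 --seed 1 --out matrix.tsv
mvbench ampute --in matrix.tsv --alpha 0.2 --beta 0.5 --seed 7 --out masked/
mvbench impute --in masked/ --method rf --seed 7 --out imputed.tsv
mvbench evaluate --imputed imputed.tsv --out de/
mvbench benchmark --n-proteins 400 --methods rf,lod --repeats 2 --out bench/
```

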