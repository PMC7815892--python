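"""Iterative random-forest imputation (the missForest scheme).

Samples are the variables and proteins the cases: each sample column with
missing entries is regressed on all other columns with a random forest, and
the matrix is swept repeatedly until the imputation stops improving.
"""

from __future__ import annotations

import numpy as np
from sklearn.ensemble import RandomForestRegressor


def impute_rf(X: np.ndarray, mask: np.ndarray, cfg) -> tuple[np.ndarray, dict]:
    """missForest-style imputation with ntree trees per column model.

    Missing entries are initialized with column means. Columns are visited
    in increasing order of missing count; for each, a random-forest
    regression (mtry = floor(sqrt(n_cols - 1)) candidate features per split,
    terminal node size 5 as is standard for regression forests) is fit on
    the rows observed in that column and used to predict its missing rows. Full sweeps repeat until the normalized squared difference
    between successive imputations increases, at which point the previous
    sweep's matrix is returned, or until max_iter sweeps.
    """
    n, m = X.shape
    if m < 2:
        raise ValueError("RF imputation requires at least two samples")
    obs = ~mask

    col_means = np.nanmean(X, axis=0)
    filled = np.where(mask, col_means[None, :], X)
    miss_cols = np.flatnonzero(mask.any(axis=0))
    order = miss_cols[np.argsort(mask[:, miss_cols].sum(axis=0), kind="stable")]
    mtry = max(1, int(np.floor(np.sqrt(m - 1))))
    rng = np.random.default_rng(cfg.seed)

    trace: list[float] = []
    prev_diff = np.inf
    n_iter = 0
    converged = False
    max_iter = cfg.resolved_max_iter

    for _ in range(max_iter):
        n_iter += 1
        before = filled.copy()
        for j in order:
            rows_obs = obs[:, j]
            rows_mis = mask[:, j]
            others = np.delete(np.arange(m), j)
            rf = RandomForestRegressor(
                n_estimators=cfg.ntree,
                max_features=mtry,
                min_samples_leaf=5,
                random_state=int(rng.integers(2**31 - 1)),
                n_jobs=1,
            )
            rf.fit(filled[np.ix_(rows_obs, others)], X[rows_obs, j])
            filled[rows_mis, j] = rf.predict(filled[np.ix_(rows_mis, others)])

        denom = float((filled[mask] ** 2).sum())
        diff = float(((filled[mask] - before[mask]) ** 2).sum()) / max(denom, 1e-300)
        trace.append(diff)
        if diff > prev_diff:
            # stopping criterion triggered: keep the previous sweep's result
            filled = before
            converged = True
            break
        prev_diff = diff

    return filled, {
        "iterations": n_iter,
        "converged": converged,
        "trace": trace,
        "mtry": mtry,
    }
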