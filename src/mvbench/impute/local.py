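"""Local-similarity imputation: k-nearest neighbors and local least squares.

Both operate protein-wise: the objects being matched are proteins (rows),
following the convention that similar proteins carry information about each
other's abundances across samples.
"""

from __future__ import annotations

import numpy as np


def impute_knn(X: np.ndarray, mask: np.ndarray, cfg) -> tuple[np.ndarray, dict]:
    """Impute each missing entry from the k most similar proteins.

    Distance between proteins is Euclidean over their co-observed samples,
    rescaled by sqrt(n_samples / n_co_observed) to stay comparable across
    different overlap sizes. For a protein missing in sample j, candidates
    are proteins observed in j that share at least one co-observed sample;
    the imputed value is the unweighted mean of the k nearest candidates'
    values in j. Fewer than k candidates: use all. No candidates: fall back
    to the protein's own observed row mean.
    """
    n, m = X.shape
    obs = ~mask
    filled = X.copy()
    fallback_rows = 0
    order_idx = np.arange(n)

    for i in np.flatnonzero(mask.any(axis=1)):
        co = obs & obs[i]  # (n, m) co-observation with the target
        n_co = co.sum(axis=1)
        sq = np.where(co, (X - X[i]) ** 2, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            dist = np.sqrt(np.nansum(sq, axis=1) * (m / n_co))
        dist[i] = np.inf
        dist[n_co == 0] = np.inf

        row_mean = X[i, obs[i]].mean()
        for j in np.flatnonzero(mask[i]):
            cand = obs[:, j] & np.isfinite(dist)
            if not cand.any():
                filled[i, j] = row_mean
                fallback_rows += 1
                continue
            cand_idx = order_idx[cand]
            # stable sort on distance keeps ties deterministic (row order)
            nearest = cand_idx[np.argsort(dist[cand], kind="stable")][: cfg.k_neighbors]
            filled[i, j] = X[nearest, j].mean()

    return filled, {"fallback_entries": fallback_rows}


def impute_lls(X: np.ndarray, mask: np.ndarray, cfg) -> tuple[np.ndarray, dict]:
    """Local least squares: regress each target protein on similar proteins.

    Candidate neighbor values are taken from a row-mean-initialized copy of
    the matrix so that proteins with missing entries can still serve as
    regressors. For each target protein: the k_similar most similar proteins
    by absolute Pearson correlation over the target's observed samples are
    selected; the target's observed values are expressed as a linear
    combination of the neighbors' values in those samples via the
    minimum-norm least-squares solution (pseudoinverse); missing entries are
    predicted from the neighbors' values in the missing samples. Targets
    with fewer than two observed samples, fewer than two usable neighbors,
    or a degenerate system fall back to row-mean imputation (counted).
    """
    n, m = X.shape
    obs = ~mask
    row_means = np.array([X[i, obs[i]].mean() for i in range(n)])
    F = np.where(mask, row_means[:, None], X)  # neighbor value source
    filled = X.copy()
    fallback_rows = 0

    for i in np.flatnonzero(mask.any(axis=1)):
        oc = np.flatnonzero(obs[i])
        mc = np.flatnonzero(mask[i])
        if oc.size < 2:
            filled[i, mc] = row_means[i]
            fallback_rows += 1
            continue

        y = X[i, oc]
        C = F[:, oc]
        yc = y - y.mean()
        y_norm = np.linalg.norm(yc)
        Cc = C - C.mean(axis=1, keepdims=True)
        c_norm = np.linalg.norm(Cc, axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            corr = np.abs(Cc @ yc) / (c_norm * y_norm)
        corr[i] = -np.inf  # never self
        corr[~np.isfinite(corr)] = -np.inf  # zero-variance rows unusable

        usable = np.flatnonzero(corr > -np.inf)
        if usable.size < 2 or y_norm == 0:
            filled[i, mc] = row_means[i]
            fallback_rows += 1
            continue

        top = usable[np.argsort(-corr[usable], kind="stable")][: cfg.k_similar]
        A = F[top][:, oc].T  # (n_obs, k)
        coef = np.linalg.pinv(A) @ y
        pred = F[top][:, mc].T @ coef
        if not np.all(np.isfinite(pred)):
            filled[i, mc] = row_means[i]
            fallback_rows += 1
            continue
        filled[i, mc] = pred

    return filled, {"fallback_rows": fallback_rows}
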