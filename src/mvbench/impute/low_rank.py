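"""Global-structure imputation: iterative SVD completion and Bayesian PCA.

Both model the proteins x samples matrix as low-rank plus noise and
reconstruct missing entries from the dominant principal components, with
samples as the variables being modeled.
"""

from __future__ import annotations

import numpy as np

_EPS = 1e-12


def impute_svd(X: np.ndarray, mask: np.ndarray, cfg) -> tuple[np.ndarray, dict]:
    """EM-style low-rank completion with a truncated SVD.

    Missing entries are initialized with row means; then, repeatedly, the
    matrix is column-centered, decomposed, and the missing entries are
    replaced by the rank-npcs reconstruction (plus centers) until the
    relative change of the imputed entries drops below tol or max_iter is
    reached (a non-convergence flag is set in the diagnostics).
    """
    q = cfg.npcs
    if q >= min(X.shape):
        raise ValueError("npcs must be < min(n_rows, n_cols)")
    obs = ~mask
    row_means = np.array([X[i, obs[i]].mean() for i in range(X.shape[0])])
    filled = np.where(mask, row_means[:, None], X)

    trace: list[float] = []
    converged = False
    n_iter = 0
    prev = filled[mask].copy()
    for _ in range(cfg.resolved_max_iter):
        n_iter += 1
        mu = filled.mean(axis=0)
        U, S, Vt = np.linalg.svd(filled - mu, full_matrices=False)
        recon = (U[:, :q] * S[:q]) @ Vt[:q] + mu
        filled[mask] = recon[mask]
        cur = filled[mask]
        change = float(
            np.linalg.norm(cur - prev) / max(np.linalg.norm(prev), _EPS)
        )
        trace.append(change)
        prev = cur.copy()
        if change < cfg.tol:
            converged = True
            break

    return filled, {"iterations": n_iter, "converged": converged, "trace": trace}


def impute_bpca(X: np.ndarray, mask: np.ndarray, cfg) -> tuple[np.ndarray, dict]:
    """Bayesian PCA imputation by variational EM with an ARD prior.

    A probabilistic PCA model (y = W x + mu + eps, isotropic noise) is fit
    to the incomplete matrix. An automatic-relevance-determination prior on
    the columns of the loading matrix W shrinks superfluous components to
    zero, making the effective rank data-driven. EM alternates the posterior
    of the factor scores given the observed part of each row with
    re-estimation of W, mu and the noise variance; missing entries are
    replaced by their posterior expectation. Initialization is the SVD of a
    row-mean-imputed matrix; convergence is declared when the relative
    change of the noise precision falls below tol.
    """
    n, d = X.shape
    q = cfg.npcs
    if q >= min(n, d):
        raise ValueError("npcs must be < min(n_rows, n_cols)")
    obs = ~mask
    eye = np.eye(q)

    row_means = np.array([X[i, obs[i]].mean() for i in range(n)])
    filled = np.where(mask, row_means[:, None], X)
    mu = filled.mean(axis=0)
    U, S, Vt = np.linalg.svd(filled - mu, full_matrices=False)
    W = Vt[:q].T * (S[:q] / np.sqrt(n))
    resid0 = filled - mu - (U[:, :q] * S[:q]) @ Vt[:q]
    sigma2 = max(float((resid0**2).mean()), _EPS)
    alpha = d / np.maximum((W**2).sum(axis=0), _EPS)

    trace: list[float] = []
    converged = False
    n_iter = 0
    for _ in range(cfg.resolved_max_iter):
        n_iter += 1
        # E-step: per-row posterior of factor scores from observed entries
        WWo = np.einsum("dq,nd,dk->nqk", W, obs, W, optimize=True)
        Minv = np.linalg.inv(sigma2 * eye[None] + WWo)
        Yc = np.where(obs, X - mu, 0.0)
        x = np.einsum("nqk,nk->nq", Minv, Yc @ W)
        Cx = sigma2 * Minv

        filled = np.where(obs, X, x @ W.T + mu)

        # M-step with ARD regularization on the loading columns
        mu = filled.mean(axis=0)
        Zc = filled - mu
        Sxx = x.T @ x + Cx.sum(axis=0)
        W = np.linalg.solve(Sxx + sigma2 * np.diag(alpha), x.T @ Zc).T
        alpha = d / np.maximum((W**2).sum(axis=0), _EPS)
        alpha = np.minimum(alpha, 1e10)

        resid = float(((Zc - x @ W.T)[obs] ** 2).sum())
        tr_term = float(
            np.einsum("nqk,dq,nd,dk->", Cx, W, obs, W, optimize=True)
        )
        sigma2_new = max((resid + tr_term) / obs.sum(), _EPS)
        change = abs(1.0 / sigma2_new - 1.0 / sigma2) * sigma2
        trace.append(change)
        sigma2 = sigma2_new
        if change < cfg.tol:
            converged = True
            break

    filled = np.where(obs, X, x @ W.T + mu)
    return filled, {
        "iterations": n_iter,
        "converged": converged,
        "trace": trace,
        "sigma2": sigma2,
        "loading_norms": np.sqrt((W**2).sum(axis=0)),
    }
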