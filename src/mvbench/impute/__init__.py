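"""Seven missing-value imputation methods behind one dispatch interface.

Left-censored: LOD (global-minimum substitution) and ND (draws from a
downshifted, narrowed normal). Local similarity: kNN and LLS operating
protein-wise (neighbors are proteins), and RF, an iterative random-forest
scheme with samples as variables. Global structure: SVD (iterative low-rank
completion) and BPCA (variational Bayesian PCA with automatic relevance
determination). All methods leave observed entries untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ..amputate import MaskedDataset

METHODS = ("LOD", "ND", "KNN", "LLS", "RF", "SVD", "BPCA")

_DEFAULT_MAX_ITER = {"RF": 10}


@dataclass(frozen=True)
class ImputationConfig:
    """Hyperparameters for the seven imputation methods.

    Only the fields relevant to ``method`` are consulted. ``max_iter``
    defaults to 100 for the iterative methods except RF, where a full sweep
    refits one forest per sample and 10 sweeps are ample.
    """

    method: str
    k_neighbors: int = 6  # kNN
    k_similar: int = 150  # LLS
    ntree: int = 100  # RF
    npcs: int = 2  # SVD / BPCA
    nd_shift: float = 2.2  # ND: downshift, multiples of sigma_m
    nd_width: float = 0.3  # ND: width, multiples of sigma_m
    nd_per_column: bool = False  # ND: per-sample statistics instead of global
    max_iter: Optional[int] = None
    tol: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; choose from {METHODS}")
        if self.k_neighbors < 1 or self.k_similar < 1 or self.ntree < 1:
            raise ValueError("k_neighbors, k_similar and ntree must be >= 1")
        if self.npcs < 1:
            raise ValueError("npcs must be >= 1")
        if self.nd_width <= 0:
            raise ValueError("nd_width must be > 0")
        if self.max_iter is not None and self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")

    @property
    def resolved_max_iter(self) -> int:
        if self.max_iter is not None:
            return self.max_iter
        return _DEFAULT_MAX_ITER.get(self.method, 100)


@dataclass
class ImputedMatrix:
    """A completed matrix plus the config and convergence diagnostics."""

    values: np.ndarray
    config: ImputationConfig
    diagnostics: dict = field(default_factory=dict)
    protein_ids: Optional[np.ndarray] = None
    protein_species: Optional[np.ndarray] = None
    sample_ids: Optional[np.ndarray] = None
    sample_group: Optional[np.ndarray] = None


def impute(md: MaskedDataset, cfg: ImputationConfig) -> ImputedMatrix:
    """Impute a MaskedDataset with the configured method.

    Observed entries pass through bit-identically; only masked entries are
    filled. Deterministic for a fixed (dataset, config).
    """
    from . import forest, left_censored, local, low_rank

    X = md.observed
    mask = md.mask
    if mask.size and mask.all(axis=1).any():
        raise ValueError("every row must have at least one observed entry")
    if cfg.method in ("SVD", "BPCA") and cfg.npcs >= min(X.shape):
        raise ValueError("npcs must be < min(n_rows, n_cols)")
    if cfg.method == "KNN" and cfg.k_neighbors >= X.shape[0]:
        raise ValueError("k_neighbors must be < number of proteins")

    dispatch = {
        "LOD": left_censored.impute_lod,
        "ND": left_censored.impute_nd,
        "KNN": local.impute_knn,
        "LLS": local.impute_lls,
        "RF": forest.impute_rf,
        "SVD": low_rank.impute_svd,
        "BPCA": low_rank.impute_bpca,
    }
    filled, diagnostics = dispatch[cfg.method](X, mask, cfg)

    # Contract: imputers only ever write into masked entries.
    filled = np.where(mask, filled, X)
    if np.isnan(filled).any():
        raise RuntimeError(f"{cfg.method} left NaN entries after imputation")

    return ImputedMatrix(
        values=filled,
        config=cfg,
        diagnostics=diagnostics,
        protein_ids=md.protein_ids,
        protein_species=md.protein_species,
        sample_ids=md.sample_ids,
        sample_group=md.sample_group,
    )


__all__ = ["METHODS", "ImputationConfig", "ImputedMatrix", "impute"]
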