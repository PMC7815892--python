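"""Controlled amputation: inject MNAR/MAR missing values at exact rates.

Missingness is parameterized by the total missing-value rate alpha and the
MNAR share beta. MNAR entries are censored below a stochastic threshold
drawn around the alpha-th abundance quantile (abundance-dependent), gated by
a Bernoulli(beta) coin; MAR entries are then drawn uniformly from the
remaining observed entries (abundance-independent). Counts are enforced
exactly: round(N*alpha*beta) MNAR and round(N*alpha) - round(N*alpha*beta)
MAR entries for a matrix of N entries, for every seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .matrix import LabeledAbundanceMatrix

OBSERVED, MNAR, MAR = 0, 1, 2

_QUANTILE_STEP = 0.01


@dataclass(frozen=True)
class MissingnessSpec:
    """Amputation parameters.

    alpha: total missing fraction in [0, 1); beta: MNAR share of the missing
    entries in [0, 1]; sigma_T: std of the censoring threshold matrix, in
    log2 units (the same units as the data).
    """

    alpha: float
    beta: float
    sigma_T: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.alpha < 1:
            raise ValueError("alpha must lie in [0, 1)")
        if not 0 <= self.beta <= 1:
            raise ValueError("beta must lie in [0, 1]")
        if self.sigma_T <= 0:
            raise ValueError("sigma_T must be > 0")


@dataclass
class MaskedDataset:
    """Amputed matrix plus full provenance of the injected missingness.

    ``observed`` holds NaN at missing entries; ``mask`` is True where
    missing; ``provenance`` is 0/1/2 for observed/MNAR/MAR; ``truth`` is the
    pre-amputation matrix. All arrays are restricted to retained rows (rows
    missing in every sample are removed, their ids kept in ``dropped_rows``).
    Pre-drop totals are kept so realized rates can be audited exactly.
    """

    observed: np.ndarray
    mask: np.ndarray
    provenance: np.ndarray
    truth: np.ndarray
    protein_ids: np.ndarray
    protein_species: np.ndarray
    sample_ids: np.ndarray
    sample_group: np.ndarray
    dropped_rows: np.ndarray
    spec: MissingnessSpec
    n_entries_predrop: int
    n_missing_predrop: int
    n_mnar_predrop: int

    def __post_init__(self) -> None:
        if not (self.mask.shape == self.observed.shape == self.truth.shape):
            raise ValueError("shape mismatch between observed/mask/truth")
        if not np.array_equal(np.isnan(self.observed), self.mask):
            raise ValueError("mask must flag exactly the NaN entries of observed")
        if np.isnan(self.truth).any():
            raise ValueError("truth must be complete")
        if not np.array_equal(self.provenance != OBSERVED, self.mask):
            raise ValueError("provenance must be MNAR/MAR exactly on masked entries")
        if self.mask.size and self.mask.all(axis=1).any():
            raise ValueError("retained rows must each keep >= 1 observed entry")

    @property
    def n_proteins(self) -> int:
        return self.observed.shape[0]

    @property
    def n_samples(self) -> int:
        return self.observed.shape[1]


def simulate_missingness(
    complete: LabeledAbundanceMatrix, spec: MissingnessSpec
) -> MaskedDataset:
    """Ampute a complete log2-scale matrix at exact (alpha, beta) rates.

    The censoring threshold matrix T is Normal(q, sigma_T) with q the
    alpha-th quantile of all values; the Bernoulli(beta) gate P marks which
    entries are MNAR-eligible. Candidates {D < T and P = 1} are uniformly
    subsampled to the exact MNAR target; if too few exist, T is redrawn with
    the quantile level raised in steps of 0.01 (error if still short at
    level 1). MAR entries are then uniform over the remaining observed
    entries. Rows left with no observed value are removed. Deterministic for
    a fixed (matrix, spec).
    """
    if complete.scale != "log2":
        raise ValueError("amputation operates on log2 scale; call .to_log2() first")
    if complete.has_missing:
        raise ValueError("input matrix must be complete")

    D = complete.values
    n_total = D.size
    n_missing = round(n_total * spec.alpha)
    n_mnar = round(n_total * spec.alpha * spec.beta)
    n_mar = n_missing - n_mnar

    rng = np.random.default_rng(spec.seed)
    mask = np.zeros(D.shape, dtype=bool)
    provenance = np.full(D.shape, OBSERVED, dtype=np.int8)

    if n_mnar > 0:
        gate = rng.random(D.shape) < spec.beta
        level = spec.alpha
        while True:
            mu = np.quantile(D, min(level, 1.0))
            T = rng.normal(mu, spec.sigma_T, D.shape)
            candidates = np.flatnonzero((D < T) & gate)
            if candidates.size >= n_mnar:
                break
            if level >= 1.0:
                raise RuntimeError(
                    f"cannot censor {n_mnar} entries: only {candidates.size} fall "
                    "below the threshold even at quantile level 1"
                )
            level = min(level + _QUANTILE_STEP, 1.0)
        chosen = rng.choice(candidates, size=n_mnar, replace=False)
        mask.flat[chosen] = True
        provenance.flat[chosen] = MNAR

    if n_mar > 0:
        remaining = np.flatnonzero(~mask.ravel())
        chosen = rng.choice(remaining, size=n_mar, replace=False)
        mask.flat[chosen] = True
        provenance.flat[chosen] = MAR

    keep = ~mask.all(axis=1)
    dropped = complete.protein_ids[~keep]
    mask_kept = mask[keep]
    observed = np.where(mask_kept, np.nan, D[keep])

    return MaskedDataset(
        observed=observed,
        mask=mask_kept,
        provenance=provenance[keep],
        truth=D[keep].copy(),
        protein_ids=complete.protein_ids[keep],
        protein_species=complete.protein_species[keep],
        sample_ids=complete.sample_ids.copy(),
        sample_group=complete.sample_group.copy(),
        dropped_rows=dropped,
        spec=spec,
        n_entries_predrop=n_total,
        n_missing_predrop=n_missing,
        n_mnar_predrop=n_mnar,
    )


def missingness_summary(md: MaskedDataset) -> dict:
    """Realized missingness diagnostics of a MaskedDataset.

    ``mv_rate`` and ``mnar_share`` are computed on the retained matrix;
    ``mv_rate_predrop``/``mnar_share_predrop`` use the pre-drop counts and
    equal the configured rates exactly by count enforcement.
    """
    n_missing = int(md.mask.sum())
    n_mnar = int((md.provenance == MNAR).sum())
    return {
        "mv_rate": n_missing / md.mask.size if md.mask.size else 0.0,
        "mnar_share": n_mnar / n_missing if n_missing else 0.0,
        "mv_rate_predrop": (
            md.n_missing_predrop / md.n_entries_predrop if md.n_entries_predrop else 0.0
        ),
        "mnar_share_predrop": (
            md.n_mnar_predrop / md.n_missing_predrop if md.n_missing_predrop else 0.0
        ),
        "per_sample_rates": md.mask.mean(axis=0),
        "per_protein_counts": md.mask.sum(axis=1),
        "n_dropped_rows": int(len(md.dropped_rows)),
    }
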