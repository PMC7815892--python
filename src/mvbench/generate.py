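"""Synthetic spike-in benchmark generator.

Each protein gets a baseline abundance drawn once from a log-normal (on log2
scale: Normal(location, scale)) shared across samples. Each sample applies a
per-species scaling factor equal to the designed mass proportion times
(1 + perturbation), perturbations drawn at the design's intragroup CV and
mean-centered within each group. Entry-level multiplicative log-normal
measurement noise is added on top. With group-mean enforcement on (default)
each protein's arithmetic group mean is rescaled to exactly
baseline x designed proportion, so the realized intergroup ratios of group
means reproduce the designated ratio table to machine precision — the
property the benchmark's ground truth rests on.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .design import GroupDesign
from .matrix import LabeledAbundanceMatrix

DEFAULT_BASE_LOCATION = 20.0  # log2 units
DEFAULT_BASE_SCALE = 2.0  # log2 units
DEFAULT_NOISE_SIGMA = 0.2  # log2 units, entry-level measurement noise
_MAX_RESAMPLE = 100


def generate_benchmark(
    design: GroupDesign,
    n_proteins_per_species: dict[str, int],
    base_location: float = DEFAULT_BASE_LOCATION,
    base_scale: float = DEFAULT_BASE_SCALE,
    noise_sigma: float = DEFAULT_NOISE_SIGMA,
    seed: int = 0,
    enforce_group_means: bool = True,
) -> LabeledAbundanceMatrix:
    """Generate a complete (no-missing) benchmark matrix on linear scale.

    Parameters
    ----------
    design
        Group compositions, replicate count and intragroup CV.
    n_proteins_per_species
        Number of proteins per species label (all >= 1).
    base_location, base_scale
        Log2-scale location and scale of the per-protein baseline abundance
        distribution.
    noise_sigma
        Std (log2 units) of the entry-level multiplicative measurement noise.
    enforce_group_means
        Rescale each protein's replicate block so its arithmetic group mean
        equals baseline x designed proportion exactly. Leaves the designated
        ratios exact per dataset instead of only in expectation.
    """
    for s in design.species:
        if s not in n_proteins_per_species:
            raise ValueError(f"missing protein count for species {s!r}")
        if n_proteins_per_species[s] < 1:
            raise ValueError(f"protein count for {s!r} must be >= 1")
    if noise_sigma < 0 or not np.isfinite([base_location, base_scale]).all():
        raise ValueError("invalid abundance parameters")

    rng = np.random.default_rng(seed)
    species = list(design.species)
    reps = design.replicates_per_group
    cv = design.intragroup_cv

    protein_species = np.concatenate(
        [np.repeat(s, n_proteins_per_species[s]) for s in species]
    )
    n_proteins = len(protein_species)
    protein_ids = np.array(
        [f"{s}_{i + 1}" for s in species for i in range(n_proteins_per_species[s])],
        dtype=object,
    )
    baselines = np.exp2(rng.normal(base_location, base_scale, n_proteins))

    # Per-(species, sample) scaling factors, group means enforced exactly.
    scaling = np.empty((len(species), len(design.sample_ids)))
    col = 0
    for g in design.group_ids:
        for si, s in enumerate(species):
            prop = design.proportion(s, g)
            factors = _centered_factors(rng, cv, reps)
            scaling[si, col : col + reps] = prop * factors
        col += reps

    species_index = {s: i for i, s in enumerate(species)}
    row_scaling = scaling[[species_index[s] for s in protein_species], :]
    noise = np.exp2(rng.normal(0.0, noise_sigma, (n_proteins, scaling.shape[1])))
    values = baselines[:, None] * row_scaling * noise

    if enforce_group_means:
        col = 0
        for g in design.group_ids:
            block = values[:, col : col + reps]
            target = baselines * np.array(
                [design.proportion(s, g) for s in protein_species]
            )
            block *= (target / block.mean(axis=1))[:, None]
            col += reps

    return LabeledAbundanceMatrix(
        values=values,
        protein_ids=protein_ids,
        protein_species=protein_species,
        sample_ids=np.array(design.sample_ids, dtype=object),
        sample_group=np.array(design.sample_groups, dtype=object),
        scale="linear",
    )


def _centered_factors(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """(1 + eps) factors with eps mean-centered within the group; all > 0."""
    for _ in range(_MAX_RESAMPLE):
        eps = rng.normal(0.0, cv, n)
        eps -= eps.mean()
        factors = 1.0 + eps
        if np.all(factors > 0):
            return factors
    raise RuntimeError(
        f"could not draw positive scaling factors at cv={cv}; reduce intragroup_cv"
    )


def realized_ratio_table(
    matrix: LabeledAbundanceMatrix, design: GroupDesign
) -> pd.DataFrame:
    """Mean intergroup ratio per species from arithmetic group means.

    For every protein the linear-scale ratio of its group mean vs the control
    group mean is computed, then averaged within each species. With group
    means enforced this reproduces :func:`designated_ratio_table` exactly.
    """
    lin = matrix.to_linear()
    control_cols = lin.group_columns(design.control_group)
    control_mean = lin.values[:, control_cols].mean(axis=1)
    table = {}
    for g in design.group_ids:
        gmean = lin.values[:, lin.group_columns(g)].mean(axis=1)
        ratios = gmean / control_mean
        table[g] = {
            s: float(ratios[lin.species_rows(s)].mean()) for s in design.species
        }
    out = pd.DataFrame(table).loc[list(design.species), list(design.group_ids)]
    out.index.name = "species"
    return out


def significance_audit(
    matrix: LabeledAbundanceMatrix, design: GroupDesign
) -> pd.DataFrame:
    """P-values of the designed intergroup differences on species totals.

    Sums each species' linear intensities per sample, log2-transforms the
    totals, and runs the pipeline's pooled two-sample t-test for every
    non-control group against the control. A generated dataset whose spike-in
    contrasts fail p < 0.05 violates the design contract and should be
    regenerated.
    """
    from .evaluate import pooled_ttest

    if design.replicates_per_group < 2:
        raise ValueError("audit requires >= 2 replicates per group")
    lin = matrix.to_linear()
    if lin.has_missing:
        raise ValueError("audit requires a complete matrix")

    totals = {
        s: np.log2(lin.values[lin.species_rows(s), :].sum(axis=0))
        for s in design.species
    }
    control_cols = lin.group_columns(design.control_group)
    out: dict[str, dict[str, float]] = {}
    for test_g, control_g in design.comparisons():
        comp = f"{test_g}/{control_g}"
        cols = lin.group_columns(test_g)
        out[comp] = {}
        for s in design.species:
            _, p = pooled_ttest(
                totals[s][control_cols][None, :], totals[s][cols][None, :]
            )
            out[comp][s] = float(p[0])
    table = pd.DataFrame(out).loc[list(design.species)]
    table.index.name = "species"
    return table
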