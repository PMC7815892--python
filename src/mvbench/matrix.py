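"""Labeled protein-abundance matrix container.

The whole pipeline operates on a proteins x samples intensity matrix with a
species label per protein (the spike-in ground truth) and a group label per
sample (the experimental design). Intensities live either on linear scale
(strictly positive) or on log2 scale; the container records which.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

SCALES = ("linear", "log2")


@dataclass
class LabeledAbundanceMatrix:
    """Proteins x samples abundance matrix with species and group labels.

    Parameters
    ----------
    values
        Float matrix of shape ``(n_proteins, n_samples)``. NaN marks a
        missing entry (only permitted for matrices loaded from real data;
        generated benchmarks are complete).
    protein_ids, protein_species
        Per-row identifiers and species labels.
    sample_ids, sample_group
        Per-column identifiers and group labels.
    scale
        ``"linear"`` or ``"log2"``.
    """

    values: np.ndarray
    protein_ids: np.ndarray
    protein_species: np.ndarray
    sample_ids: np.ndarray
    sample_group: np.ndarray
    scale: str = "linear"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.protein_ids = np.asarray(self.protein_ids, dtype=object)
        self.protein_species = np.asarray(self.protein_species, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.sample_group = np.asarray(self.sample_group, dtype=object)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n, m = self.values.shape
        if len(self.protein_ids) != n or len(self.protein_species) != n:
            raise ValueError("row labels do not match matrix height")
        if len(self.sample_ids) != m or len(self.sample_group) != m:
            raise ValueError("column labels do not match matrix width")
        if self.scale not in SCALES:
            raise ValueError(f"scale must be one of {SCALES}, got {self.scale!r}")
        if self.scale == "linear":
            obs = self.values[~np.isnan(self.values)]
            if obs.size and not np.all(obs > 0):
                raise ValueError("linear-scale intensities must be strictly positive")

    # -- basic queries ----------------------------------------------------

    @property
    def n_proteins(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def has_missing(self) -> bool:
        return bool(np.isnan(self.values).any())

    @property
    def groups(self) -> list[str]:
        """Group labels in first-appearance (column) order."""
        seen: dict[str, None] = {}
        for g in self.sample_group:
            seen.setdefault(g, None)
        return list(seen)

    def group_columns(self, group: str) -> np.ndarray:
        cols = np.flatnonzero(self.sample_group == group)
        if cols.size == 0:
            raise KeyError(f"no samples in group {group!r}")
        return cols

    def species_rows(self, species: str) -> np.ndarray:
        rows = np.flatnonzero(self.protein_species == species)
        if rows.size == 0:
            raise KeyError(f"no proteins with species label {species!r}")
        return rows

    # -- transforms -------------------------------------------------------

    def to_log2(self) -> "LabeledAbundanceMatrix":
        if self.scale == "log2":
            return self
        return replace(self, values=np.log2(self.values), scale="log2")

    def to_linear(self) -> "LabeledAbundanceMatrix":
        if self.scale == "linear":
            return self
        return replace(self, values=np.exp2(self.values), scale="linear")

    def copy(self) -> "LabeledAbundanceMatrix":
        return replace(self, values=self.values.copy())

    def to_frame(self) -> pd.DataFrame:
        """DataFrame with protein ids as index, species as first column."""
        df = pd.DataFrame(self.values, index=self.protein_ids, columns=self.sample_ids)
        df.insert(0, "species", self.protein_species)
        df.index.name = "protein"
        return df
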