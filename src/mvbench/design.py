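"""Spike-in experimental design: group compositions and designated ratios.

A three-species spike-in benchmark mixes E.coli and yeast proteomes into a
constant human background at designed mass fractions per group, so that the
true intergroup fold change of every protein is known from the design alone:
ratio(species, group) = proportion(species, group) / proportion(species,
control). Human background at a constant fraction makes every human protein
a true negative (ratio 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

PROPORTION_TOL = 1e-9


@dataclass(frozen=True)
class GroupDesign:
    """Composition of the spike-in benchmark.

    ``species_proportions`` maps group id -> species -> fraction of total
    protein mass; fractions sum to 1 within each group. ``intragroup_cv`` is
    the coefficient of variation of the per-sample species scaling factors
    used to mimic biological replicates.
    """

    group_ids: tuple[str, ...]
    replicates_per_group: int
    species_proportions: Mapping[str, Mapping[str, float]]
    intragroup_cv: float = 0.05
    control_group: str = "A"

    def __post_init__(self) -> None:
        if self.replicates_per_group < 2:
            raise ValueError("need at least 2 replicates per group")
        if self.control_group not in self.group_ids:
            raise ValueError(f"control group {self.control_group!r} not in group_ids")
        if self.intragroup_cv < 0:
            raise ValueError("intragroup_cv must be >= 0")
        species = None
        for g in self.group_ids:
            if g not in self.species_proportions:
                raise ValueError(f"no proportions given for group {g!r}")
            props = self.species_proportions[g]
            if species is None:
                species = tuple(props)
            elif tuple(props) != species:
                raise ValueError("species sets must agree across groups")
            total = sum(props.values())
            if abs(total - 1.0) > PROPORTION_TOL:
                raise ValueError(
                    f"proportions for group {g!r} sum to {total}, expected 1"
                )
            if any(p < 0 or p > 1 for p in props.values()):
                raise ValueError("proportions must lie in [0, 1]")

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(self.species_proportions[self.group_ids[0]])

    @property
    def sample_ids(self) -> list[str]:
        return [
            f"{g}_{r + 1}"
            for g in self.group_ids
            for r in range(self.replicates_per_group)
        ]

    @property
    def sample_groups(self) -> list[str]:
        return [g for g in self.group_ids for _ in range(self.replicates_per_group)]

    def proportion(self, species: str, group: str) -> float:
        return self.species_proportions[group][species]

    def comparisons(self) -> list[tuple[str, str]]:
        """(test, control) pairs: every non-control group vs the control."""
        return [(g, self.control_group) for g in self.group_ids if g != self.control_group]

    def to_dict(self) -> dict:
        return {
            "group_ids": list(self.group_ids),
            "replicates_per_group": self.replicates_per_group,
            "species_proportions": {
                g: dict(p) for g, p in self.species_proportions.items()
            },
            "intragroup_cv": self.intragroup_cv,
            "control_group": self.control_group,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "GroupDesign":
        return cls(
            group_ids=tuple(d["group_ids"]),
            replicates_per_group=int(d["replicates_per_group"]),
            species_proportions={
                g: dict(p) for g, p in d["species_proportions"].items()
            },
            intragroup_cv=float(d.get("intragroup_cv", 0.05)),
            control_group=d.get("control_group", d["group_ids"][0]),
        )


def spikein_design(intragroup_cv: float = 0.05) -> GroupDesign:
    """The four-group benchmark composition.

    Human background constant at 70%; E.coli at 5 / 7.5 / 10 / 12.5% and
    yeast at 25 / 22.5 / 20 / 17.5% across groups A-D, giving designated
    E.coli ratios 1.5 / 2 / 2.5 and yeast ratios 0.9 / 0.8 / 0.7 vs A.
    """
    ecoli = {"A": 0.05, "B": 0.075, "C": 0.10, "D": 0.125}
    yeast = {"A": 0.25, "B": 0.225, "C": 0.20, "D": 0.175}
    props = {
        g: {"E.coli": ecoli[g], "yeast": yeast[g], "human": 0.70}
        for g in "ABCD"
    }
    return GroupDesign(
        group_ids=("A", "B", "C", "D"),
        replicates_per_group=8,
        species_proportions=props,
        intragroup_cv=intragroup_cv,
        control_group="A",
    )


# Protein counts of the full-scale benchmark (E.coli / yeast / human).
FULL_SCALE_COUNTS = {"E.coli": 1184, "yeast": 1081, "human": 4424}


def scaled_counts(n_total: int) -> dict[str, int]:
    """Protein counts at the benchmark's species mix, scaled to ~n_total rows."""
    total = sum(FULL_SCALE_COUNTS.values())
    return {
        s: max(1, round(c * n_total / total)) for s, c in FULL_SCALE_COUNTS.items()
    }


def designated_ratio_table(design: GroupDesign) -> pd.DataFrame:
    """Designed intergroup ratios vs the control group.

    Returns a species x group DataFrame; control column is identically 1.
    """
    control = design.control_group
    rows = {}
    for s in design.species:
        p0 = design.proportion(s, control)
        if p0 == 0:
            raise ValueError(f"control proportion for species {s!r} is zero")
        rows[s] = {g: design.proportion(s, g) / p0 for g in design.group_ids}
    table = pd.DataFrame.from_dict(rows, orient="index")
    table = table.loc[list(design.species), list(design.group_ids)]
    table.index.name = "species"
    return table
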