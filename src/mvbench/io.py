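"""Reading and writing abundance matrices and masked datasets.

The on-disk matrix format is TSV: first column protein id, second column
species, remaining columns samples named ``<group>_<replicate>``. Empty
fields are missing values. A generated matrix may carry a JSON sidecar with
its GroupDesign. MaxQuant proteinGroups tables can be loaded via their LFQ
intensity columns.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .amputate import MaskedDataset, MissingnessSpec
from .design import GroupDesign
from .matrix import LabeledAbundanceMatrix


def write_abundance_tsv(
    m: LabeledAbundanceMatrix,
    path: str | Path,
    design: GroupDesign | None = None,
) -> None:
    """Write a labeled matrix as TSV (missing entries become empty fields)."""
    path = Path(path)
    m.to_frame().to_csv(path, sep="\t", na_rep="")
    if design is not None:
        path.with_suffix(".design.json").write_text(
            json.dumps(design.to_dict(), indent=2)
        )


def read_abundance_tsv(
    path: str | Path, scale: str = "linear"
) -> LabeledAbundanceMatrix:
    """Read a labeled abundance matrix written by :func:`write_abundance_tsv`.

    Raises descriptive errors (with line numbers; line 1 is the header) for
    ragged rows, duplicate protein ids and non-numeric cells.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    if "species" not in df.columns:
        raise ValueError(f"{path}: expected a 'species' column after the protein id")

    dup = df.index[df.index.duplicated()]
    if len(dup):
        line = int(np.flatnonzero(df.index == dup[0])[1]) + 2
        raise ValueError(f"{path}: duplicate protein id {dup[0]!r} at line {line}")

    sample_cols = [c for c in df.columns if c != "species"]
    values = np.empty((len(df), len(sample_cols)))
    for j, col in enumerate(sample_cols):
        raw = df[col].to_numpy()
        empty = np.array([v.strip() == "" for v in raw])
        parsed = pd.to_numeric(pd.Series(np.where(empty, "nan", raw)), errors="coerce")
        bad = parsed.isna().to_numpy() & ~empty
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"{path}: non-numeric value {raw[i]!r} in column {col!r} "
                f"at line {i + 2}"
            )
        values[:, j] = parsed.to_numpy()

    groups = [c.rsplit("_", 1)[0] for c in sample_cols]
    return LabeledAbundanceMatrix(
        values=values,
        protein_ids=df.index.to_numpy(dtype=object),
        protein_species=df["species"].to_numpy(dtype=object),
        sample_ids=np.array(sample_cols, dtype=object),
        sample_group=np.array(groups, dtype=object),
        scale=scale,
    )


def read_design_json(path: str | Path) -> GroupDesign:
    return GroupDesign.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# MaxQuant proteinGroups


def read_maxquant_proteingroups(
    path: str | Path,
    intensity_prefix: str = "LFQ intensity ",
    log2: bool = False,
) -> LabeledAbundanceMatrix:
    """Load LFQ intensities from a MaxQuant proteinGroups table.

    Zero intensities become missing values; rows flagged in the standard
    "Reverse" or "Potential contaminant" columns are removed.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    lfq_cols = [c for c in df.columns if c.startswith(intensity_prefix)]
    if not lfq_cols:
        raise ValueError(
            f"{path}: no columns start with {intensity_prefix!r}; "
            f"available columns: {list(df.columns)}"
        )
    for flag in ("Reverse", "Potential contaminant"):
        if flag in df.columns:
            df = df[df[flag].fillna("") != "+"]

    id_col = next(
        (c for c in ("Majority protein IDs", "Protein IDs") if c in df.columns),
        None,
    )
    ids = (
        df[id_col].astype(str).to_numpy(dtype=object)
        if id_col
        else np.array([f"protein_{i}" for i in range(len(df))], dtype=object)
    )
    values = df[lfq_cols].to_numpy(dtype=float)
    values[values == 0] = np.nan
    sample_ids = [c[len(intensity_prefix):] for c in lfq_cols]
    groups = [s.rsplit("_", 1)[0] for s in sample_ids]
    m = LabeledAbundanceMatrix(
        values=values,
        protein_ids=ids,
        protein_species=np.repeat("unknown", len(df)),
        sample_ids=np.array(sample_ids, dtype=object),
        sample_group=np.array(groups, dtype=object),
        scale="linear",
    )
    return m.to_log2() if log2 else m


def complete_subset(m: LabeledAbundanceMatrix) -> LabeledAbundanceMatrix:
    """Retain only proteins quantified in every sample."""
    keep = ~np.isnan(m.values).any(axis=1)
    if not keep.any():
        raise ValueError("no protein is complete across all samples")
    return LabeledAbundanceMatrix(
        values=m.values[keep],
        protein_ids=m.protein_ids[keep],
        protein_species=m.protein_species[keep],
        sample_ids=m.sample_ids.copy(),
        sample_group=m.sample_group.copy(),
        scale=m.scale,
    )


# ---------------------------------------------------------------------------
# Masked dataset serialization


def write_masked_dataset(md: MaskedDataset, out_dir: str | Path) -> None:
    """Write a MaskedDataset as TSVs plus a JSON metadata sidecar.

    observed.tsv (empty field = missing), mask.tsv (0/1, 1 = missing),
    provenance.tsv (0 = observed, 1 = MNAR, 2 = MAR), truth.tsv, meta.json.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def frame(values: np.ndarray) -> pd.DataFrame:
        df = pd.DataFrame(values, index=md.protein_ids, columns=md.sample_ids)
        df.insert(0, "species", md.protein_species)
        df.index.name = "protein"
        return df

    frame(md.observed).to_csv(out / "observed.tsv", sep="\t", na_rep="")
    frame(md.mask.astype(int)).to_csv(out / "mask.tsv", sep="\t")
    frame(md.provenance).to_csv(out / "provenance.tsv", sep="\t")
    frame(md.truth).to_csv(out / "truth.tsv", sep="\t")
    meta = {
        "spec": {
            "alpha": md.spec.alpha,
            "beta": md.spec.beta,
            "sigma_T": md.spec.sigma_T,
            "seed": md.spec.seed,
        },
        "sample_group": list(md.sample_group),
        "dropped_rows": list(md.dropped_rows),
        "n_entries_predrop": md.n_entries_predrop,
        "n_missing_predrop": md.n_missing_predrop,
        "n_mnar_predrop": md.n_mnar_predrop,
    }
    (out / "meta.json").write_text(json.dumps(meta, indent=2))


def read_masked_dataset(in_dir: str | Path) -> MaskedDataset:
    """Read a MaskedDataset written by :func:`write_masked_dataset`."""
    src = Path(in_dir)
    observed = read_abundance_tsv(src / "observed.tsv", scale="log2")
    truth = read_abundance_tsv(src / "truth.tsv", scale="log2")
    mask_df = pd.read_csv(src / "mask.tsv", sep="\t", index_col=0)
    prov_df = pd.read_csv(src / "provenance.tsv", sep="\t", index_col=0)
    meta = json.loads((src / "meta.json").read_text())
    spec = MissingnessSpec(**meta["spec"])
    sample_cols = list(observed.sample_ids)
    return MaskedDataset(
        observed=observed.values,
        mask=mask_df[sample_cols].to_numpy(dtype=bool),
        provenance=prov_df[sample_cols].to_numpy(dtype=np.int8),
        truth=truth.values,
        protein_ids=observed.protein_ids,
        protein_species=observed.protein_species,
        sample_ids=observed.sample_ids,
        sample_group=np.array(meta["sample_group"], dtype=object),
        dropped_rows=np.array(meta["dropped_rows"], dtype=object),
        spec=spec,
        n_entries_predrop=meta["n_entries_predrop"],
        n_missing_predrop=meta["n_missing_predrop"],
        n_mnar_predrop=meta["n_mnar_predrop"],
    )
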