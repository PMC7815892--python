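"""Scoring: NRMSE, differential-expression testing, FADR and ROC curves.

Imputation accuracy is scored on the originally-missing entries only
(observed entries pass through imputation unchanged and would dilute the
error). Differential expression uses the pooled-variance two-sample t-test
with Benjamini-Hochberg adjustment; spike-in species provide the truth
labels for TP/FP counting, with FADR = FP / (TP + FP).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

POSITIVE_SPECIES = frozenset({"E.coli", "yeast"})
SIGNIFICANCE_LEVEL = 0.05


# ---------------------------------------------------------------------------
# NRMSE


def nrmse_abundance(
    imputed: np.ndarray, truth: np.ndarray, mask: np.ndarray
) -> float:
    """NRMSE between imputed and true values over the masked entries.

    sqrt( mean((imputed - truth)^2) / var(truth) ) with the sample variance
    (n-1) of the true masked values; 0 means perfect imputation, ~1 is the
    error of imputing the mean.
    """
    imputed = np.asarray(imputed, dtype=float)
    truth = np.asarray(truth, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if imputed.shape != truth.shape or truth.shape != mask.shape:
        raise ValueError("imputed, truth and mask shapes must agree")
    if not mask.any():
        raise ValueError("mask selects no entries")
    t = truth[mask]
    var = t.var(ddof=1) if t.size > 1 else 0.0
    if var == 0:
        raise ValueError("true masked values are constant; NRMSE undefined")
    return float(np.sqrt(np.mean((imputed[mask] - t) ** 2) / var))


def intergroup_ratios(
    values_log2: np.ndarray,
    sample_group: Sequence[str],
    control_group: str,
) -> pd.DataFrame:
    """Per-protein linear ratios of every group vs the control.

    ratio = 2^(mean log2 in group - mean log2 in control). Requires a
    complete matrix (ratios are computed post-imputation or on complete
    data). Columns are labeled "<group>/<control>"; the control column is
    omitted.
    """
    values_log2 = np.asarray(values_log2, dtype=float)
    if np.isnan(values_log2).any():
        raise ValueError("matrix contains missing entries; impute first")
    sample_group = np.asarray(sample_group, dtype=object)
    groups = [g for g in dict.fromkeys(sample_group) if g != control_group]
    if control_group not in sample_group:
        raise ValueError(f"control group {control_group!r} absent")
    control_mean = values_log2[:, sample_group == control_group].mean(axis=1)
    out = {}
    for g in groups:
        gmean = values_log2[:, sample_group == g].mean(axis=1)
        out[f"{g}/{control_group}"] = np.exp2(gmean - control_mean)
    return pd.DataFrame(out)


def nrmse_ratios(
    observed_ratios: pd.DataFrame,
    designated: pd.DataFrame,
    protein_species: Sequence[str],
) -> float:
    """NRMSE between observed and designated intergroup ratios.

    ``observed_ratios`` is the per-protein output of
    :func:`intergroup_ratios` (columns "<group>/<control>");
    ``designated`` is the species x group designated-ratio table. The error
    is pooled over all (protein, comparison) pairs on linear ratio scale,
    normalized by the sample variance of the designated values.
    """
    protein_species = np.asarray(protein_species, dtype=object)
    if len(protein_species) != len(observed_ratios):
        raise ValueError("species labels must match the ratio table rows")
    obs_flat = []
    des_flat = []
    for col in observed_ratios.columns:
        group = col.split("/")[0]
        des_col = designated[group]
        obs_flat.append(observed_ratios[col].to_numpy(dtype=float))
        des_flat.append(des_col.loc[protein_species].to_numpy(dtype=float))
    obs = np.concatenate(obs_flat)
    des = np.concatenate(des_flat)
    var = des.var(ddof=1)
    if var == 0:
        raise ValueError("designated ratios are constant; NRMSE undefined")
    return float(np.sqrt(np.mean((obs - des) ** 2) / var))


# ---------------------------------------------------------------------------
# Differential expression


def pooled_ttest(
    a: np.ndarray, b: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise two-sample equal-variance Student's t-test (two-sided).

    ``a`` and ``b`` are (n_proteins, n_replicates) blocks. Degenerate rows
    with zero pooled variance get p = 1 when the means are equal and p = 0
    otherwise.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    na, nb = a.shape[1], b.shape[1]
    if na < 2 or nb < 2:
        raise ValueError("need >= 2 replicates per group")
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    df = na + nb - 2
    sp2 = ((na - 1) * va + (nb - 1) * vb) / df
    se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mb - ma) / se
        p = 2.0 * stats.t.sf(np.abs(t), df)
    degenerate = se == 0
    if degenerate.any():
        equal = degenerate & (mb == ma)
        t[degenerate & ~equal] = np.where(
            (mb - ma)[degenerate & ~equal] > 0, np.inf, -np.inf
        )
        t[equal] = 0.0
        p[equal] = 1.0
        p[degenerate & ~equal] = 0.0
    return t, p


@dataclass
class DEResult:
    """Per-protein differential-expression statistics for one comparison."""

    table: pd.DataFrame  # protein, species, mean_control, mean_test, ratio, t, p, adj_p
    comparison: str  # e.g. "B/A"

    @property
    def adj_p(self) -> np.ndarray:
        return self.table["adj_p"].to_numpy()

    @property
    def species(self) -> np.ndarray:
        return self.table["species"].to_numpy()

    def significant(self, alpha: float = SIGNIFICANCE_LEVEL) -> np.ndarray:
        return self.adj_p < alpha


def de_test(
    values_log2: np.ndarray,
    control_cols: np.ndarray,
    test_cols: np.ndarray,
    protein_ids: Sequence | None = None,
    protein_species: Sequence | None = None,
    comparison: str = "test/control",
) -> DEResult:
    """Pooled t-test plus BH adjustment for one intergroup comparison."""
    values_log2 = np.asarray(values_log2, dtype=float)
    if np.isnan(values_log2).any():
        raise ValueError("matrix contains missing entries; impute first")
    a = values_log2[:, np.asarray(control_cols)]
    b = values_log2[:, np.asarray(test_cols)]
    t, p = pooled_ttest(a, b)
    _, adj_p, _, _ = multipletests(p, method="fdr_bh")
    n = values_log2.shape[0]
    table = pd.DataFrame(
        {
            "protein": protein_ids if protein_ids is not None else np.arange(n),
            "species": (
                protein_species if protein_species is not None else [""] * n
            ),
            "mean_control": a.mean(axis=1),
            "mean_test": b.mean(axis=1),
            "ratio": np.exp2(b.mean(axis=1) - a.mean(axis=1)),
            "t": t,
            "p": p,
            "adj_p": adj_p,
        }
    )
    return DEResult(table=table, comparison=comparison)


# ---------------------------------------------------------------------------
# Confusion counts and ROC


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/FN/TN of spike-in detection with derived rates."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def fadr(self) -> float:
        """False altered-protein discovery rate FP/(TP+FP); 0/0 -> 0."""
        total = self.tp + self.fp
        return self.fp / total if total else 0.0

    @property
    def tpr(self) -> float:
        total = self.tp + self.fn
        return self.tp / total if total else 0.0

    @property
    def fpr(self) -> float:
        total = self.fp + self.tn
        return self.fp / total if total else 0.0


def confusion(
    de: DEResult,
    positive_species: Iterable[str] = POSITIVE_SPECIES,
    alpha: float = SIGNIFICANCE_LEVEL,
) -> ConfusionCounts:
    """Count spike-in detections: positives are the spiked species' proteins."""
    positive_species = set(positive_species)
    is_positive = np.array([s in positive_species for s in de.species])
    sig = de.significant(alpha)
    return ConfusionCounts(
        tp=int((sig & is_positive).sum()),
        fp=int((sig & ~is_positive).sum()),
        fn=int((~sig & is_positive).sum()),
        tn=int((~sig & ~is_positive).sum()),
    )


@dataclass
class ROCCurve:
    """ROC points parameterized by the adjusted-p-value threshold."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def roc_curve(
    de_results: Sequence[DEResult],
    positive_species: Iterable[str] = POSITIVE_SPECIES,
    thresholds: np.ndarray | None = None,
) -> ROCCurve:
    """Repeat-averaged ROC of spike-in detection.

    For every adjusted-p threshold, (FPR, TPR) is computed per repeat and
    averaged component-wise; the endpoints (0,0) and (1,1) anchor the curve
    and the AUC is trapezoidal.
    """
    if not de_results:
        raise ValueError("need at least one DE result")
    if thresholds is None:
        thresholds = np.linspace(0.0, 1.0, 101)
    thresholds = np.asarray(thresholds, dtype=float)
    positive_species = set(positive_species)

    fprs = np.zeros((len(de_results), len(thresholds)))
    tprs = np.zeros_like(fprs)
    for r, de in enumerate(de_results):
        is_positive = np.array([s in positive_species for s in de.species])
        n_pos = int(is_positive.sum())
        n_neg = int((~is_positive).sum())
        if n_pos == 0 or n_neg == 0:
            raise ValueError("ROC needs both positive and negative proteins")
        adj_p = de.adj_p
        for k, thr in enumerate(thresholds):
            sig = adj_p <= thr
            tprs[r, k] = (sig & is_positive).sum() / n_pos
            fprs[r, k] = (sig & ~is_positive).sum() / n_neg

    fpr = np.concatenate([[0.0], fprs.mean(axis=0), [1.0]])
    tpr = np.concatenate([[0.0], tprs.mean(axis=0), [1.0]])
    order = np.argsort(fpr, kind="stable")
    auc = float(np.trapezoid(tpr[order], fpr[order]))
    return ROCCurve(
        thresholds=np.concatenate([[-np.inf], thresholds, [np.inf]]),
        fpr=fpr,
        tpr=tpr,
        auc=auc,
    )
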