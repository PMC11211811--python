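"""Metrics and analyses for condition-level predictions.

All metrics compare a model's predicted *mean* post-perturbation expression
for a condition against the empirical mean over that condition's cells.
Differential-expression (DE) genes are ranked by the magnitude of the mean
shift versus the control mean; the headline MSE is computed on the top 20.
rel-MSE expresses a model's MSE(DE) as a percentage of the Ctrl baseline's
(the model that predicts the control mean for every condition), so Ctrl
itself always scores 100.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import Condition, ExpressionMatrix, format_condition
from .model import Model, predict_shift
from .sgconv import Propagator


@dataclass
class ConditionMetrics:
    mse_de: float            # MSE over the top-n DE genes
    rel_mse_de: float        # 100 * mse_de / Ctrl's mse_de
    pearson_delta_all: float # shift correlation over all genes
    direction_error: float   # fraction of DE genes with wrong shift sign
    sd_outlier: float        # fraction of DE genes off by > 1 sd

    def __post_init__(self):
        if self.mse_de < 0 or self.rel_mse_de < 0:
            raise ValueError("MSE values must be non-negative")
        for frac in (self.direction_error, self.sd_outlier):
            if not (0 <= frac <= 1):
                raise ValueError("error rates must lie in [0, 1]")


@dataclass
class NagSet:
    """Nonadditive genes of a two-gene condition at threshold eta."""

    condition: Condition
    eta: float
    genes: np.ndarray   # subset of the condition's top-200 DE genes


def ctrl_baseline(data: ExpressionMatrix) -> np.ndarray:
    """Element-wise mean of the control cells (the Ctrl model's prediction)."""
    mask = data.control_mask()
    if not mask.any():
        raise ValueError("dataset has no control cells")
    return data.values[mask].mean(axis=0)


def top_de_genes(data: ExpressionMatrix, c: Condition, n: int = 20) -> np.ndarray:
    """Indices of the n most differentially expressed genes for condition c.

    Ranked by |mean(y_c) - mean(controls)| descending; ties broken toward
    the smaller gene index.
    """
    if n > data.n_genes:
        raise ValueError(f"n={n} exceeds the {data.n_genes}-gene panel")
    shift = data.condition_mean(c) - ctrl_baseline(data)
    order = np.lexsort((np.arange(data.n_genes), -np.abs(shift)))
    return order[:n]


def condition_metrics(pred_mean: np.ndarray, data: ExpressionMatrix,
                      c: Condition, ctrl_pred: np.ndarray,
                      n_de: int = 20) -> ConditionMetrics:
    """Full metric set for one condition's mean prediction."""
    pred_mean = np.asarray(pred_mean, dtype=np.float64)
    ctrl_pred = np.asarray(ctrl_pred, dtype=np.float64)
    rows = data.cells_of(c)
    if rows.size < 2:
        raise ValueError("condition needs >= 2 cells for the sd metric")
    true_mean = data.values[rows].mean(axis=0)
    true_sd = data.values[rows].std(axis=0, ddof=1)
    ctrl_mean = ctrl_baseline(data)

    de = top_de_genes(data, c, n_de)
    mse_de = float(np.mean((pred_mean[de] - true_mean[de]) ** 2))
    mse_ctrl = float(np.mean((ctrl_pred[de] - true_mean[de]) ** 2))
    if mse_ctrl == 0:
        rel = 100.0 if mse_de == 0 else np.inf
    else:
        rel = 100.0 * mse_de / mse_ctrl

    pred_shift = pred_mean - ctrl_mean
    true_shift = true_mean - ctrl_mean
    if np.std(true_shift) == 0:
        raise ValueError("true shift has zero variance; Pearson undefined")
    if np.std(pred_shift) == 0:
        # constant predictor (e.g. the Ctrl baseline): no correlation
        pearson = 0.0
    else:
        pearson = float(stats.pearsonr(pred_shift, true_shift).statistic)

    # sign(0) mismatches any nonzero sign; two exact zeros agree
    direction = float(np.mean(
        np.sign(pred_shift[de]) != np.sign(true_shift[de])))
    sd_outlier = float(np.mean(
        np.abs(pred_mean[de] - true_mean[de]) > true_sd[de]))
    return ConditionMetrics(mse_de, rel, pearson, direction, sd_outlier)


def additive_baseline(c: Condition, data: ExpressionMatrix) -> np.ndarray:
    """Sum of the two single-gene mean shifts, Δ_i + Δ_j (length K)."""
    if c.m != 2:
        raise ValueError("additive baseline is defined for two-gene conditions")
    ctrl = ctrl_baseline(data)
    shift = np.zeros(data.n_genes)
    for g in c.genes:
        single = Condition([g])
        if data.cells_of(single).size == 0:
            raise ValueError(
                f"single-gene condition for gene {g} absent from the data")
        shift += data.condition_mean(single) - ctrl
    return shift


def nag_set(c: Condition, data: ExpressionMatrix, eta: float,
            n_de: int = 200) -> NagSet:
    """Nonadditive genes: top-200 DE genes where the pair shift deviates
    from the summed single shifts by at least eta times its own magnitude,
    |Δ_i,k + Δ_j,k - Δ_c,k| >= eta |Δ_c,k|.
    """
    if eta < 0:
        raise ValueError("eta must be >= 0")
    n_de = min(n_de, data.n_genes)
    de = top_de_genes(data, c, n_de)
    pair_shift = data.condition_mean(c) - ctrl_baseline(data)
    add_shift = additive_baseline(c, data)
    keep = np.abs(add_shift[de] - pair_shift[de]) >= eta * np.abs(pair_shift[de])
    return NagSet(condition=c, eta=eta, genes=de[keep])


def residual_matrix(preds: dict[Condition, np.ndarray], data: ExpressionMatrix,
                    conditions: list[Condition], n_de: int = 20) -> pd.DataFrame:
    """Column-scaled squared-error matrix (conditions x union of DE genes).

    Each entry is the squared error of the condition-mean prediction at
    that gene; columns are divided by their maximum so entries lie in
    [0, 1] (all-zero columns are left as zeros).
    """
    if not conditions:
        raise ValueError("empty condition list")
    cols = sorted({g for c in conditions for g in top_de_genes(data, c, n_de)})
    mat = np.zeros((len(conditions), len(cols)))
    for i, c in enumerate(conditions):
        err = preds[c] - data.condition_mean(c)
        mat[i] = err[cols] ** 2
    col_max = mat.max(axis=0)
    nonzero = col_max > 0
    mat[:, nonzero] /= col_max[nonzero]
    index = [format_condition(c, data.gene_index) for c in conditions]
    names = [data.gene_index.names[g] for g in cols]
    return pd.DataFrame(mat, index=index, columns=names)


def predict_condition_means(model: Model, conditions: list[Condition],
                            data: ExpressionMatrix, go_prop: Propagator,
                            aug_prop: Propagator) -> dict[Condition, np.ndarray]:
    """Model mean predictions: shift(c) + control mean, per condition."""
    ctrl = ctrl_baseline(data)
    return {c: predict_shift(c, model, go_prop, aug_prop) + ctrl
            for c in conditions}


def evaluation_report(preds: dict[Condition, np.ndarray],
                      data: ExpressionMatrix,
                      class_of: dict[Condition, str] | None = None,
                      n_de: int = 20) -> pd.DataFrame:
    """One metrics row per evaluated condition."""
    ctrl = ctrl_baseline(data)
    rows = []
    for c, pred in preds.items():
        m = condition_metrics(pred, data, c, ctrl, n_de)
        rows.append({
            "condition": format_condition(c, data.gene_index),
            "class": (class_of or {}).get(c, ""),
            "mse_de": m.mse_de,
            "rel_mse_de": m.rel_mse_de,
            "pearson_delta_all": m.pearson_delta_all,
            "direction_error": m.direction_error,
            "sd_outlier": m.sd_outlier,
        })
    return pd.DataFrame(rows)
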