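"""Validation metrics.

Layer identification is scored as a multiclass classification problem over
probe channels: a confusion matrix tallies predicted (rows) versus true
(columns) layers, and per-layer precision, recall, and F1 follow from its
row and column sums. Decomposition quality is scored by Pearson
correlation and relative MSE between estimated and ground-truth
per-population contributions, with an optimal-assignment matching step for
unlabelled components (PCA/ICA baselines).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.stats import pearsonr

from .core import relative_mse

__all__ = [
    "ConfusionMatrix",
    "confusion_matrix",
    "precision",
    "recall",
    "f1",
    "f1_from_scores",
    "pearson_correlation",
    "match_contributions",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Predicted-by-true layer counts with row-normalized proportions."""

    counts: pd.DataFrame  # rows = predicted layer, columns = true layer

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("confusion-matrix counts must be non-negative")

    @property
    def layers(self) -> tuple[str, ...]:
        return tuple(self.counts.index)

    @property
    def normalized(self) -> pd.DataFrame:
        """Each row divided by its sum (all-zero rows stay zero)."""
        sums = self.counts.sum(axis=1)
        safe = sums.replace(0, 1)
        return self.counts.div(safe, axis=0)

    def accuracy(self) -> float:
        total = self.counts.to_numpy().sum()
        return float(np.trace(self.counts.to_numpy()) / total)


def confusion_matrix(
    predicted: Sequence[str], truth: Sequence[str], layers: Sequence[str] | None = None
) -> ConfusionMatrix:
    """Tally channel-layer predictions against the true layers.

    For each channel, +1 is added at (row = predicted layer, column = true
    layer), so correct classifications accumulate on the diagonal.
    ``layers`` fixes the layer order; by default it is the sorted union of
    the labels seen.
    """
    predicted = list(predicted)
    truth = list(truth)
    if len(predicted) != len(truth):
        raise ValueError(f"{len(predicted)} predictions for {len(truth)} channels")
    if len(predicted) == 0:
        raise ValueError("empty label sequences")
    if layers is None:
        layers = sorted(set(predicted) | set(truth))
    layers = list(layers)
    unknown = (set(predicted) | set(truth)) - set(layers)
    if unknown:
        raise ValueError(f"labels not in the layer set: {sorted(unknown)}")
    counts = pd.DataFrame(0, index=layers, columns=layers, dtype=int)
    for p, t in zip(predicted, truth):
        counts.loc[p, t] += 1
    return ConfusionMatrix(counts)


def _tp_row_col(cm: ConfusionMatrix, layer: str) -> tuple[float, float, float]:
    if layer not in cm.counts.index:
        raise ValueError(f"layer {layer!r} not present in the confusion matrix")
    tp = float(cm.counts.loc[layer, layer])
    row = float(cm.counts.loc[layer].sum())     # TP + FP
    col = float(cm.counts[layer].sum())         # TP + FN
    return tp, row, col


def precision(cm: ConfusionMatrix, layer: str) -> float:
    """TP / (TP + FP): fraction of channels predicted in ``layer`` that are
    truly there. Defined as 0 (with a warning) when nothing is predicted
    in the layer."""
    tp, row, _ = _tp_row_col(cm, layer)
    if row == 0:
        warnings.warn(f"no channels predicted in layer {layer!r}; precision := 0")
        return 0.0
    return tp / row


def recall(cm: ConfusionMatrix, layer: str) -> float:
    """TP / (TP + FN): fraction of channels truly in ``layer`` that are
    predicted there. Defined as 0 (with a warning) when the layer holds no
    channels."""
    tp, _, col = _tp_row_col(cm, layer)
    if col == 0:
        warnings.warn(f"no channels truly in layer {layer!r}; recall := 0")
        return 0.0
    return tp / col


def f1_from_scores(precision_value: float, recall_value: float) -> float:
    """Harmonic mean of precision and recall (0 when both are 0)."""
    if precision_value + recall_value == 0:
        return 0.0
    return 2.0 * precision_value * recall_value / (precision_value + recall_value)


def f1(cm: ConfusionMatrix, layer: str) -> float:
    """Per-layer F1 score: harmonic mean of precision and recall."""
    return f1_from_scores(precision(cm, layer), recall(cm, layer))


def pearson_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson r over the flattened values of two equal-shape arrays."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Pearson correlation undefined for a constant input")
    return float(pearsonr(x.ravel(), y.ravel()).statistic)


def match_contributions(
    estimated: np.ndarray,
    truth: np.ndarray,
    labels: Sequence[str] | None = None,
    labelled: bool = True,
) -> pd.DataFrame:
    """Score estimated per-population contributions against ground truth.

    Parameters
    ----------
    estimated, truth
        Arrays of shape (k, N_ch, B). In labelled mode the population
        counts must match and component i is scored against truth i. In
        unlabelled mode (PCA/ICA components carry no population identity)
        each truth contribution is assigned the estimated component that
        maximizes the summed |correlation| via optimal assignment, and the
        sign of the correlation is kept in the report.
    labels
        Names for the truth populations (row index of the result).

    Returns
    -------
    DataFrame indexed by truth population with columns ``component``
    (matched estimate index), ``correlation`` and ``relative_mse``.
    Components (or truths) with zero variance score correlation 0.
    """

    def safe_corr(a: np.ndarray, b: np.ndarray) -> float:
        try:
            return pearson_correlation(a, b)
        except ValueError:
            return 0.0

    estimated = np.asarray(estimated, float)
    truth = np.asarray(truth, float)
    if estimated.ndim != 3 or truth.ndim != 3:
        raise ValueError("contributions must be (k, N_ch, B) arrays")
    if estimated.shape[1:] != truth.shape[1:]:
        raise ValueError("estimate and truth live on different channel/time grids")
    k_true = truth.shape[0]
    if labels is None:
        labels = [f"pop_{i}" for i in range(k_true)]
    if labelled:
        if estimated.shape[0] != k_true:
            raise ValueError(
                f"labelled mode: {estimated.shape[0]} estimated components "
                f"for {k_true} truth populations"
            )
        pairs = [(i, i) for i in range(k_true)]
    else:
        corr = np.zeros((k_true, estimated.shape[0]))
        for i in range(k_true):
            for j in range(estimated.shape[0]):
                corr[i, j] = safe_corr(truth[i], estimated[j])
        rows, cols = linear_sum_assignment(-np.abs(corr))
        pairs = list(zip(rows.tolist(), cols.tolist()))
    records = []
    for i, j in pairs:
        records.append(
            {
                "component": j,
                "correlation": safe_corr(truth[i], estimated[j]),
                "relative_mse": relative_mse(truth[i], estimated[j]),
            }
        )
    return pd.DataFrame(records, index=list(labels))
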