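"""Voxelwise confusion metrics, ROC curves, and threshold selection.

Accuracy is defined on voxel classification as (TP + TN) / (TP + FP + FN
+ TN). The saliency threshold ``T`` of the contour stage is chosen on
training data alone by splitting its slices in half, running the complete
pipeline on the held-out half for each candidate ``T``, and minimizing the
weighted error ``E = alpha * FPR + beta * (1 - TPR)`` — by default alpha=7
and beta=1, expressing a strong aversion to false positives.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .config import PipelineConfig
from .io import IntensityVolume, LabelVolume

__all__ = [
    "ConfusionCounts",
    "RocPoint",
    "confusion",
    "metrics",
    "roc_curve",
    "roc_auc",
    "select_threshold",
]


@dataclass
class ConfusionCounts:
    TP: int
    FP: int
    FN: int
    TN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


@dataclass
class RocPoint:
    threshold: float
    fpr: float
    tpr: float


def _as_binary(x) -> np.ndarray:
    data = x.data if isinstance(x, LabelVolume) else np.asarray(x)
    return data > 0


def confusion(pred, truth) -> ConfusionCounts:
    """Voxelwise confusion counts between binary prediction and truth."""
    p = _as_binary(pred)
    t = _as_binary(truth)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs truth {t.shape}")
    tp = int(np.logical_and(p, t).sum())
    fp = int(np.logical_and(p, ~t).sum())
    fn = int(np.logical_and(~p, t).sum())
    tn = int(np.logical_and(~p, ~t).sum())
    return ConfusionCounts(TP=tp, FP=fp, FN=fn, TN=tn)


def metrics(c: ConfusionCounts) -> tuple[float, float, float]:
    """(TPR, FPR, accuracy); raises when truth lacks a class."""
    if c.TP + c.FN == 0:
        raise ZeroDivisionError("TPR undefined: no positive truth voxels")
    if c.FP + c.TN == 0:
        raise ZeroDivisionError("FPR undefined: no negative truth voxels")
    tpr = c.TP / (c.TP + c.FN)
    fpr = c.FP / (c.FP + c.TN)
    acc = (c.TP + c.TN) / c.total
    return tpr, fpr, acc


def roc_curve(scores, truth, thresholds: Sequence[float]) -> list[RocPoint]:
    """One (FPR, TPR) point per threshold, predicting score >= threshold."""
    s = np.asarray(scores.data if hasattr(scores, "data") else scores, dtype=float)
    t = _as_binary(truth)
    if s.shape != t.shape:
        raise ValueError(f"shape mismatch: scores {s.shape} vs truth {t.shape}")
    n_pos = int(t.sum())
    n_neg = int(t.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ZeroDivisionError("ROC undefined: truth must contain both classes")
    points = []
    for thr in thresholds:
        pred = s >= thr
        tp = int(np.logical_and(pred, t).sum())
        fp = int(pred.sum()) - tp
        points.append(RocPoint(threshold=float(thr), fpr=fp / n_neg, tpr=tp / n_pos))
    return points


def roc_auc(scores, truth) -> float:
    """Area under the full-resolution ROC (rank statistic over all voxels)."""
    from sklearn.metrics import roc_auc_score

    s = np.asarray(scores.data if hasattr(scores, "data") else scores, dtype=float)
    t = _as_binary(truth)
    return float(roc_auc_score(t.reshape(-1), s.reshape(-1)))


def pick_threshold(rows: Sequence[dict], alpha: float, beta: float) -> tuple[float, list[dict]]:
    """Minimize ``E = alpha*fpr + beta*(1-tpr)`` over rows of (T, fpr, tpr).

    Ties break toward larger ``T`` (the alpha >> beta regime penalizes
    false positives, so prefer the stricter threshold). Returns the chosen
    T and the rows augmented with their E values.
    """
    table = []
    best_T, best_E = None, np.inf
    for row in rows:
        E = alpha * row["fpr"] + beta * (1.0 - row["tpr"])
        table.append({**row, "E": E})
        if E < best_E or (E == best_E and row["T"] > best_T):
            best_E, best_T = E, float(row["T"])
    if best_T is None:
        raise ValueError("no candidate thresholds")
    return best_T, table


def select_threshold(
    train_volume: IntensityVolume,
    train_labels: LabelVolume,
    config: PipelineConfig,
) -> tuple[float, list[dict]]:
    """Pick the saliency threshold ``T`` minimizing ``E = alpha*f + beta*(1-t)``.

    The training slices are split in half (first half fits the stage
    models, the second half measures error; with an odd count the middle
    slice is unused). The complete pipeline runs on the held-out half once
    per candidate ``T`` on the grid; ties break toward larger ``T`` (fewer
    false positives). Returns the chosen ``T`` and the E-vs-T table.
    """
    from .pipeline import _fit_stage_models, finalize_segmentation, prepare_segmentation

    nz = train_volume.shape[0]
    if nz < 14:
        raise ValueError(f"threshold selection needs >= 14 slices, got {nz}")
    k = nz // 2
    vol_a = IntensityVolume(train_volume.data[:k], train_volume.spacing)
    lab_a = LabelVolume(train_labels.data[:k], train_labels.spacing)
    vol_b = IntensityVolume(train_volume.data[nz - k :], train_volume.spacing)
    lab_b = LabelVolume(train_labels.data[nz - k :], train_labels.spacing)
    if lab_b.data.sum() == 0 or lab_b.data.sum() == lab_b.data.size:
        raise ValueError("degenerate truth in the error-measurement split")

    patch_model, contour_model = _fit_stage_models(vol_a, lab_a, config)
    prepared = prepare_segmentation(vol_b, patch_model, contour_model, config)
    rows: list[dict] = []
    for T in config.threshold_grid:
        result = finalize_segmentation(prepared, config.replace(pair_threshold_T=min(T, 1.0)))
        tpr, fpr, acc = metrics(confusion(result.labels, lab_b))
        rows.append({"T": float(T), "fpr": fpr, "tpr": tpr, "accuracy": acc})
    return pick_threshold(rows, config.alpha, config.beta)
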