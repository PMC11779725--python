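"""Detection and segmentation accuracy metrics as pure functions.

Covers generalized-IoU loss for boxes, precision/recall, greedy box
matching at an IoU threshold, average precision (AP50), Dice and IoU
for masks with their loss forms, and the least-squares reliability fit
(R^2, RMSE) used to compare automated outputs against manual
measurements.

Note on precision and recall: they are implemented in their universal
forms P = TP/(TP+FP), R = TP/(TP+FN).  Undefined denominators yield
NaN plus an explicit warning, never a silent zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as _scistats

from .io import BoundingBox

__all__ = ["MatchCounts", "RankedDetections", "ReliabilityFit", "box_iou", "giou", "giou_loss",
           "precision_recall", "match_detections", "ap50", "dice", "iou", "dice_loss",
           "fit_reliability"]


@dataclass(frozen=True)
class MatchCounts:
    """True/false positives and false negatives of one evaluation."""

    TP: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.FN) < 0:
            raise ValueError("counts must be nonnegative")


@dataclass(frozen=True)
class RankedDetections:
    """Confidence-ranked detections: (confidence, is_match) pairs plus the
    number of ground-truth objects."""

    ranked: list[tuple[float, bool]]
    n_truth: int

    def __post_init__(self) -> None:
        if self.n_truth < 0:
            raise ValueError("n_truth must be nonnegative")
        if sum(m for _, m in self.ranked) > self.n_truth:
            raise ValueError("more matches than ground-truth objects")


# ---------------------------------------------------------------------------
# boxes


def box_iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection-over-union of two half-open pixel boxes."""
    ix = max(0, min(a.x1, b.x1) - max(a.x0, b.x0))
    iy = max(0, min(a.y1, b.y1) - max(a.y0, b.y0))
    inter = ix * iy
    union = a.area + b.area - inter
    return inter / union if union else 0.0


def giou(pred: BoundingBox, target: BoundingBox) -> float:
    """Generalized IoU: IoU minus the fraction of the smallest enclosing
    box not covered by the union.  Ranges over (-1, 1]."""
    if pred.area == 0 or target.area == 0:
        raise ValueError("degenerate (zero-area) box")
    ix = max(0, min(pred.x1, target.x1) - max(pred.x0, target.x0))
    iy = max(0, min(pred.y1, target.y1) - max(pred.y0, target.y0))
    inter = ix * iy
    union = pred.area + target.area - inter
    zx = max(pred.x1, target.x1) - min(pred.x0, target.x0)
    zy = max(pred.y1, target.y1) - min(pred.y0, target.y0)
    z = zx * zy
    return inter / union - (z - union) / z


def giou_loss(pred: BoundingBox, target: BoundingBox) -> float:
    """Box regression loss 1 - GIoU, in [0, 2)."""
    return 1.0 - giou(pred, target)


# ---------------------------------------------------------------------------
# precision / recall / AP


def precision_recall(c: MatchCounts) -> tuple[float, float]:
    """(P, R) = (TP/(TP+FP), TP/(TP+FN)); NaN with a warning if undefined."""
    if c.TP + c.FP > 0:
        p = c.TP / (c.TP + c.FP)
    else:
        warnings.warn("precision undefined: no predictions (TP+FP = 0)", stacklevel=2)
        p = float("nan")
    if c.TP + c.FN > 0:
        r = c.TP / (c.TP + c.FN)
    else:
        warnings.warn("recall undefined: no ground-truth objects (TP+FN = 0)", stacklevel=2)
        r = float("nan")
    return p, r


def match_detections(
    pred: list[BoundingBox],
    truth: list[BoundingBox],
    iou_threshold: float = 0.5,
) -> tuple[MatchCounts, RankedDetections]:
    """Greedy 1-1 matching of predictions to ground truth.

    Predictions are visited in descending confidence (missing confidence
    counts as 1.0; ties keep input order).  Each prediction takes the
    unconsumed truth box of highest IoU >= ``iou_threshold``, breaking
    IoU ties toward the lower truth index.  Every truth box is consumed
    at most once.
    """
    order = sorted(range(len(pred)), key=lambda i: (-(pred[i].confidence if pred[i].confidence is not None else 1.0), i))
    taken = [False] * len(truth)
    ranked: list[tuple[float, bool]] = []
    tp = 0
    for i in order:
        best_j, best_iou = -1, iou_threshold
        for j, t in enumerate(truth):
            if taken[j]:
                continue
            v = box_iou(pred[i], t)
            if v > best_iou or (v == best_iou and v > 0 and best_j == -1):
                best_j, best_iou = j, v
        matched = best_j >= 0 and best_iou >= iou_threshold
        if matched:
            taken[best_j] = True
            tp += 1
        conf = pred[i].confidence if pred[i].confidence is not None else 1.0
        ranked.append((conf, matched))
    counts = MatchCounts(TP=tp, FP=len(pred) - tp, FN=len(truth) - tp)
    return counts, RankedDetections(ranked, len(truth))


def ap50(r: RankedDetections, n_interp: int | None = None) -> float:
    """Average precision: area under the interpolated P-R curve.

    All-point interpolation by default (the integral form of the P-R
    staircase); pass ``n_interp=101`` for the 101-point COCO variant.
    Invariant under any uniform monotone rescaling of confidences.  With
    zero truths and zero predictions the score is defined as 1 (perfect
    agreement on absence) with a warning.
    """
    if r.n_truth == 0:
        if not r.ranked:
            warnings.warn("AP of an empty problem (no truths, no predictions) defined as 1", stacklevel=2)
            return 1.0
        return 0.0
    ranked = sorted(r.ranked, key=lambda t: -t[0])
    tp = np.cumsum([m for _, m in ranked])
    k = np.arange(1, len(ranked) + 1)
    recall = tp / r.n_truth
    precision = tp / k
    # precision envelope: max precision at recall >= r
    env = np.maximum.accumulate(precision[::-1])[::-1]
    if n_interp is not None:
        grid = np.linspace(0.0, 1.0, n_interp)
        pg = np.zeros_like(grid)
        for i, g in enumerate(grid):
            sel = recall >= g
            pg[i] = env[sel][0] if sel.any() else 0.0
        return float(pg.mean())
    ap = 0.0
    prev_r = 0.0
    for i in range(len(ranked)):
        if ranked[i][1]:  # recall increases only at matched detections
            ap += (recall[i] - prev_r) * env[i]
            prev_r = recall[i]
    return float(ap)


# ---------------------------------------------------------------------------
# masks


def _check_pair(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, bool)
    y = np.asarray(y, bool)
    if x.shape != y.shape:
        raise ValueError(f"mask shapes differ: {x.shape} vs {y.shape}")
    return x, y


def dice(x: np.ndarray, y: np.ndarray) -> float:
    """Dice coefficient 2|X n Y| / (|X| + |Y|); both-empty pairs score 1."""
    x, y = _check_pair(x, y)
    sx, sy = int(x.sum()), int(y.sum())
    if sx + sy == 0:
        warnings.warn("Dice of two empty masks defined as 1 (agreement on absence)", stacklevel=2)
        return 1.0
    return 2.0 * int((x & y).sum()) / (sx + sy)


def iou(x: np.ndarray, y: np.ndarray) -> float:
    """Jaccard index |X n Y| / |X u Y|; both-empty pairs score 1."""
    x, y = _check_pair(x, y)
    union = int((x | y).sum())
    if union == 0:
        warnings.warn("IoU of two empty masks defined as 1 (agreement on absence)", stacklevel=2)
        return 1.0
    return int((x & y).sum()) / union


def dice_loss(x: np.ndarray, y: np.ndarray) -> float:
    """Segmentation loss 1 - Dice."""
    return 1.0 - dice(x, y)


# ---------------------------------------------------------------------------
# reliability fit


@dataclass(frozen=True)
class ReliabilityFit:
    """Automated-vs-manual agreement: OLS fit plus raw-pair RMSE."""

    r2: float
    rmse: float
    slope: float
    intercept: float
    n: int


def fit_reliability(x: np.ndarray, y: np.ndarray) -> ReliabilityFit:
    """Fit manual values y on automated values x by ordinary least squares.

    R^2 is the coefficient of determination of the simple OLS fit
    (identically the squared Pearson correlation); RMSE is computed on
    the raw pairs, sqrt(mean((x_i - y_i)^2)), i.e. the direct
    automated-vs-manual discrepancy rather than the fit residual.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in input")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x: fit undefined")
    fit = _scistats.linregress(x, y)
    rmse = float(np.sqrt(np.mean((x - y) ** 2)))
    return ReliabilityFit(r2=float(fit.rvalue ** 2), rmse=rmse,
                          slope=float(fit.slope), intercept=float(fit.intercept), n=len(x))
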