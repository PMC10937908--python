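"""Instance-segmentation scoring: IoU matching and Average Precision.

Predicted instances are matched one-to-one against ground-truth
instances at an IoU threshold; a matched pair is a true positive, an
unmatched prediction a false positive, an unmatched ground-truth
instance a false negative, and the per-image score is the unranked
Average Precision

    AP = TP / (TP + FP + FN).

Matching maximizes the number of matches (optimal assignment over pairs
with IoU >= threshold), breaking ties toward larger total IoU. The
threshold comparison is inclusive so pixel-identical instances match at
threshold 1.0. A greedy-by-IoU matcher is available as an alternative
backend; the optimal matcher is the default and the tested contract.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .masks_io import LabelMask, PairingError

DEFAULT_THRESHOLDS: tuple[float, ...] = tuple(np.round(np.arange(0.50, 1.001, 0.05), 2))

__all__ = [
    "IoUMatrix",
    "MatchResult",
    "APCurve",
    "iou_matrix",
    "match_at_threshold",
    "match_greedy",
    "average_precision",
    "ap_curve",
    "DEFAULT_THRESHOLDS",
]


@dataclass(frozen=True)
class IoUMatrix:
    """Pairwise IoU between predicted (rows) and ground-truth (cols) instances."""

    pred_labels: tuple[int, ...]
    gt_labels: tuple[int, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.pred_labels), len(self.gt_labels)):
            raise ValueError("IoU matrix shape does not match label lists")
        if v.size and (v.min() < 0 or v.max() > 1):
            raise ValueError("IoU values must lie in [0, 1]")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class MatchResult:
    """One-to-one matching outcome at a single IoU threshold."""

    threshold: float
    matches: tuple[tuple[int, int, float], ...]  # (pred_label, gt_label, iou)
    tp: int
    fp: int
    fn: int


@dataclass(frozen=True)
class APCurve:
    """Per-image AP across a threshold grid, with mean and SD per threshold."""

    thresholds: tuple[float, ...]
    per_image_ap: pd.DataFrame  # rows = images, cols = thresholds
    mean_ap: np.ndarray
    sd_ap: np.ndarray


def iou_matrix(pred: LabelMask, gt: LabelMask) -> IoUMatrix:
    """Pairwise IoU computed on pixel sets; background excluded.

    Uses a joint label histogram, so cost is one pass over the images
    regardless of instance count.
    """
    if pred.shape != gt.shape:
        raise PairingError(f"prediction shape {pred.shape} != ground-truth shape {gt.shape}")
    p = pred.labels.ravel()
    g = gt.labels.ravel()
    pred_ids = pred.label_ids()
    gt_ids = gt.label_ids()
    if pred_ids.size == 0 or gt_ids.size == 0:
        return IoUMatrix(
            pred_labels=tuple(int(i) for i in pred_ids),
            gt_labels=tuple(int(i) for i in gt_ids),
            values=np.zeros((pred_ids.size, gt_ids.size)),
        )
    # compact labels to 0..n, then joint histogram via bincount
    p_idx = np.searchsorted(pred_ids, p)
    p_idx[p == 0] = pred_ids.size  # background sentinel
    g_idx = np.searchsorted(gt_ids, g)
    g_idx[g == 0] = gt_ids.size
    np_, ng = pred_ids.size + 1, gt_ids.size + 1
    joint = np.bincount(p_idx * ng + g_idx, minlength=np_ * ng).reshape(np_, ng)
    inter = joint[:-1, :-1].astype(float)
    pred_areas = joint[:-1, :].sum(axis=1).astype(float)
    gt_areas = joint[:, :-1].sum(axis=0).astype(float)
    union = pred_areas[:, None] + gt_areas[None, :] - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        iou = np.where(union > 0, inter / union, 0.0)
    return IoUMatrix(
        pred_labels=tuple(int(i) for i in pred_ids),
        gt_labels=tuple(int(i) for i in gt_ids),
        values=iou,
    )


def match_at_threshold(m: IoUMatrix, threshold: float) -> MatchResult:
    """Optimal one-to-one matching over pairs with IoU >= threshold.

    The assignment maximizes the match count first and the total IoU of
    the matched pairs second (the IoU term is scaled below 1/(n+1) so it
    can never trade away a match).
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must lie in (0, 1], got {threshold}")
    n_pred, n_gt = m.values.shape
    eligible = m.values >= threshold
    if not eligible.any():
        return MatchResult(threshold=threshold, matches=(), tp=0, fp=n_pred, fn=n_gt)
    n = max(n_pred, n_gt)
    weight = np.where(eligible, 1.0 + m.values / (n + 1.0), 0.0)
    rows, cols = linear_sum_assignment(weight, maximize=True)
    matches = []
    for r, c in zip(rows, cols):
        if eligible[r, c]:
            matches.append((m.pred_labels[r], m.gt_labels[c], float(m.values[r, c])))
    matches.sort()
    tp = len(matches)
    return MatchResult(
        threshold=threshold,
        matches=tuple(matches),
        tp=tp,
        fp=n_pred - tp,
        fn=n_gt - tp,
    )


def match_greedy(m: IoUMatrix, threshold: float) -> MatchResult:
    """Greedy matcher: repeatedly take the highest remaining eligible IoU.

    Simpler than the optimal assignment and usually identical on clean
    data; provided for cross-checking, not the default contract.
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must lie in (0, 1], got {threshold}")
    n_pred, n_gt = m.values.shape
    if m.values.size == 0:
        return MatchResult(threshold=threshold, matches=(), tp=0, fp=n_pred, fn=n_gt)
    used_p: set[int] = set()
    used_g: set[int] = set()
    order = np.dstack(np.unravel_index(np.argsort(-m.values, axis=None, kind="stable"), m.values.shape))[0]
    matches = []
    for r, c in order:
        if m.values[r, c] < threshold:
            break
        if r in used_p or c in used_g:
            continue
        used_p.add(int(r))
        used_g.add(int(c))
        matches.append((m.pred_labels[r], m.gt_labels[c], float(m.values[r, c])))
    matches.sort()
    tp = len(matches)
    return MatchResult(threshold=threshold, matches=tuple(matches), tp=tp, fp=n_pred - tp, fn=n_gt - tp)


def average_precision(r: MatchResult) -> float:
    """AP = TP/(TP+FP+FN); an empty prediction of an empty image scores 1."""
    denom = r.tp + r.fp + r.fn
    if denom == 0:
        return 1.0
    return r.tp / denom


def ap_curve(
    pairs: Sequence[tuple[LabelMask, LabelMask]],
    thresholds: Iterable[float] = DEFAULT_THRESHOLDS,
    image_ids: Sequence[str] | None = None,
) -> APCurve:
    """Per-image AP at each threshold, with mean and sample SD across images.

    SD uses the n-1 denominator and is 0 for a single image.
    """
    thresholds = tuple(float(t) for t in thresholds)
    if not pairs:
        raise ValueError("ap_curve requires at least one (pred, gt) pair")
    for t in thresholds:
        if not 0 < t <= 1:
            raise ValueError(f"threshold must lie in (0, 1], got {t}")
    if image_ids is None:
        image_ids = [f"image_{i}" for i in range(len(pairs))]
    table = np.zeros((len(pairs), len(thresholds)))
    for i, (pred, gt) in enumerate(pairs):
        m = iou_matrix(pred, gt)
        for j, t in enumerate(thresholds):
            table[i, j] = average_precision(match_at_threshold(m, t))
    df = pd.DataFrame(table, index=list(image_ids), columns=[f"{t:.2f}" for t in thresholds])
    mean = table.mean(axis=0)
    sd = table.std(axis=0, ddof=1) if len(pairs) > 1 else np.zeros(len(thresholds))
    return APCurve(thresholds=thresholds, per_image_ap=df, mean_ap=mean, sd_ap=sd)
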