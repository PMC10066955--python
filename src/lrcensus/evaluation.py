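"""Detection and counting metrics, plus the repeated k-fold harness.

Detection side: greedy score-descending instance matching at a mask-IoU
threshold gives TP/FP/FN, hence precision = TP/(TP+FP), recall = TP/(TP+FN)
and their harmonic mean F1 = 2pr/(p+r); average precision at IoU 0.5 uses
the COCO 101-point interpolated precision-recall curve, and average recall
averages recall over IoU thresholds 0.50:0.05:0.95.

Counting side, over per-image (truth t_i, predicted p_i) pairs::

    MAE  = (1/n) sum |t_i - p_i|
    Acc  = (1 - (1/n) sum |t_i - p_i| / t_i) * 100%
    R^2  = 1 - sum (t_i - p_i)^2 / sum (t_i - tbar)^2
    RMSE = sqrt( (1/n) sum (t_i - p_i)^2 )

Images with t_i = 0 are excluded from the Acc sum (the relative-error term
is undefined there) but still count in MAE/RMSE/R^2.

The cross-validation harness randomly assigns tiles to k folds (default 4),
repeats the experiment several times (default 5), scores each held-out fold,
and averages fold values arithmetically — the same aggregation arithmetic
that produces published per-site "Average" rows and cross-site means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .utils import round_half_up

__all__ = [
    "MatchResult",
    "CountEval",
    "CVReport",
    "CountRegression",
    "mask_iou_matrix",
    "instances_from_labels",
    "match_instances",
    "precision_recall_f1",
    "average_precision_50",
    "mean_average_recall",
    "counting_metrics",
    "aggregate_folds",
    "aggregate_sites",
    "cross_validate",
    "count_regression",
]

COCO_IOU_THRESHOLDS = np.arange(0.50, 0.96, 0.05)


# ---------------------------------------------------------------------------
# instance matching


@dataclass(frozen=True)
class MatchResult:
    tp: int
    fp: int
    fn: int
    pairs: list[tuple[int, int, float]]  # (pred idx, truth idx, IoU)


def _as_index_sets(masks) -> list[np.ndarray]:
    """Normalise masks to sorted flat-index arrays (accepts bool rasters too)."""
    out = []
    for m in masks:
        m = np.asarray(m)
        if m.dtype == bool:
            out.append(np.flatnonzero(m.ravel()))
        else:
            out.append(np.sort(m.astype(np.int64).ravel()))
    return out


def instances_from_labels(label_raster: np.ndarray) -> list[np.ndarray]:
    """Flat-index pixel sets for every positive label, ordered by label id."""
    label_raster = np.asarray(label_raster)
    flat = label_raster.ravel()
    out = []
    for k in np.unique(flat):
        if k > 0:
            out.append(np.flatnonzero(flat == k))
    return out


def mask_iou_matrix(preds, truths) -> np.ndarray:
    """Pairwise IoU between prediction and truth pixel sets."""
    p_sets = _as_index_sets(preds)
    t_sets = _as_index_sets(truths)
    iou = np.zeros((len(p_sets), len(t_sets)))
    for i, p in enumerate(p_sets):
        for j, t in enumerate(t_sets):
            inter = np.intersect1d(p, t, assume_unique=True).size
            if inter:
                iou[i, j] = inter / (p.size + t.size - inter)
    return iou


def match_instances(
    preds,
    truths,
    iou_threshold: float = 0.5,
    scores=None,
) -> MatchResult:
    """Greedy one-to-one matching of predictions to ground-truth instances.

    Predictions are visited in score-descending order (stable: ties keep
    input order); each takes the highest-IoU unmatched truth with
    IoU >= threshold, ties broken toward the lower truth id.  Deterministic.
    """
    if not 0 < iou_threshold <= 1:
        raise ValueError("iou_threshold must lie in (0, 1]")
    iou = mask_iou_matrix(preds, truths)
    n_pred, n_truth = iou.shape
    if scores is None:
        order = range(n_pred)
    else:
        scores = np.asarray(scores, dtype=float)
        order = sorted(range(n_pred), key=lambda i: (-scores[i], i))
    matched_truth: set[int] = set()
    pairs: list[tuple[int, int, float]] = []
    for i in order:
        best_j, best_iou = -1, iou_threshold - 1e-12
        for j in range(n_truth):
            if j in matched_truth:
                continue
            if iou[i, j] >= iou_threshold and iou[i, j] > best_iou:
                best_j, best_iou = j, iou[i, j]
        if best_j >= 0:
            matched_truth.add(best_j)
            pairs.append((i, best_j, float(iou[i, best_j])))
    tp = len(pairs)
    return MatchResult(tp=tp, fp=n_pred - tp, fn=n_truth - tp, pairs=pairs)


def precision_recall_f1(match: MatchResult) -> tuple[float, float, float]:
    """precision = TP/(TP+FP), recall = TP/(TP+FN), F1 = 2pr/(p+r)."""
    if match.tp + match.fp == 0:
        warnings.warn("no predictions: precision defined as 0", stacklevel=2)
        precision = 0.0
    else:
        precision = match.tp / (match.tp + match.fp)
    recall = match.tp / (match.tp + match.fn) if match.tp + match.fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f1


# ---------------------------------------------------------------------------
# COCO-style AP / AR


def average_precision_50(preds, scores, truths, iou_threshold: float = 0.5) -> float:
    """AP at one IoU threshold via the 101-point interpolated PR curve.

    Predictions are swept in score-descending order; each is a TP if it
    claims an unmatched truth at IoU >= threshold, else an FP.  Interpolated
    precision at recall r is the maximum precision at any recall >= r,
    sampled at 101 evenly spaced recall points.
    """
    truths = list(truths)
    if len(truths) == 0:
        raise ValueError("AP undefined without ground-truth instances")
    scores = np.asarray(scores, dtype=float)
    match = match_instances(preds, truths, iou_threshold, scores=scores)
    matched_preds = {i for i, _, _ in match.pairs}
    order = sorted(range(len(scores)), key=lambda i: (-scores[i], i))
    tp_cum, fp_cum = 0, 0
    precisions, recalls = [], []
    for i in order:
        if i in matched_preds:
            tp_cum += 1
        else:
            fp_cum += 1
        precisions.append(tp_cum / (tp_cum + fp_cum))
        recalls.append(tp_cum / len(truths))
    precisions = np.asarray(precisions)
    recalls = np.asarray(recalls)
    ap = 0.0
    for r in np.linspace(0, 1, 101):
        mask = recalls >= r - 1e-12
        ap += precisions[mask].max() if mask.any() else 0.0
    return ap / 101.0


def mean_average_recall(preds, scores, truths, thresholds=None) -> float:
    """Recall averaged over IoU thresholds 0.50:0.05:0.95."""
    truths = list(truths)
    if len(truths) == 0:
        raise ValueError("AR undefined without ground-truth instances")
    thresholds = COCO_IOU_THRESHOLDS if thresholds is None else thresholds
    recalls = []
    for t in thresholds:
        match = match_instances(preds, truths, float(t), scores=scores)
        recalls.append(match.tp / len(truths))
    return float(np.mean(recalls))


# ---------------------------------------------------------------------------
# counting metrics


@dataclass(frozen=True)
class CountEval:
    per_image: list[tuple[float, float]]  # (truth, predicted)
    mae: float
    acc: float  # percent; nan when every image has zero truth count
    r_squared: float  # nan when truth counts have zero variance
    rmse: float


def counting_metrics(truth_counts, predicted_counts) -> CountEval:
    """MAE, relative accuracy, R^2 and RMSE over per-image count pairs."""
    t = np.asarray(truth_counts, dtype=float)
    p = np.asarray(predicted_counts, dtype=float)
    if t.size == 0 or t.shape != p.shape:
        raise ValueError("need equal-length, non-empty truth and prediction vectors")
    err = np.abs(t - p)
    mae = float(err.mean())
    rmse = float(np.sqrt((err**2).mean()))
    pos = t > 0
    if pos.any():
        acc = float((1.0 - (err[pos] / t[pos]).mean()) * 100.0)
    else:
        acc = float("nan")
    ss_tot = float(((t - t.mean()) ** 2).sum())
    if ss_tot == 0:
        r2 = float("nan")
    else:
        r2 = float(1.0 - ((t - p) ** 2).sum() / ss_tot)
    return CountEval(
        per_image=list(zip(t.tolist(), p.tolist())), mae=mae, acc=acc, r_squared=r2, rmse=rmse
    )


def aggregate_folds(values, ndigits: int = 2) -> float:
    """Arithmetic mean of fold values, rounded half-up for reporting."""
    values = np.asarray(list(values), dtype=float)
    if values.size == 0:
        raise ValueError("cannot aggregate an empty sequence")
    return round_half_up(float(values.mean()), ndigits)


def aggregate_sites(values, ndigits: int = 2) -> float:
    """Arithmetic mean across sites (same arithmetic as fold averaging)."""
    return aggregate_folds(values, ndigits)


# ---------------------------------------------------------------------------
# cross-validation harness


@dataclass
class CVReport:
    """Repeated k-fold counting evaluation.

    ``folds`` holds one :class:`CountEval` per held-out fold (k x repeats in
    total); ``fold_assignments`` records which tile indices each fold held
    out, per repeat.
    """

    k: int
    repeats: int
    folds: list[CountEval] = field(default_factory=list)
    fold_assignments: list[list[np.ndarray]] = field(default_factory=list)

    def average(self, metric: str, ndigits: int = 2) -> float:
        return aggregate_folds([getattr(f, metric) for f in self.folds], ndigits)

    @property
    def fold_average(self) -> dict:
        return {
            "acc": self.average("acc"),
            "mae": self.average("mae", 3),
            "r_squared": self.average("r_squared", 3),
            "rmse": self.average("rmse", 3),
        }


def cross_validate(
    tiles,
    truth_counts,
    backend,
    k: int = 4,
    repeats: int = 5,
    seed: int = 0,
    score_threshold: float = 0.0,
    min_pixels: int = 1,
) -> CVReport:
    """Repeated k-fold counting evaluation of a segmentation backend.

    Tiles are randomly assigned to k disjoint folds; each fold is scored as a
    held-out set (predicted count per tile = detections surviving the score
    and size filters), and the whole assignment is repeated with fresh
    randomness.  Seeded and reproducible.
    """
    from .segmentation import filter_detections

    n = len(tiles)
    truth_counts = np.asarray(truth_counts, dtype=float)
    if k < 1 or k > n:
        raise ValueError("need 1 <= k <= number of tiles")
    rng = np.random.default_rng(seed)
    report = CVReport(k=k, repeats=repeats)
    for _ in range(repeats):
        perm = rng.permutation(n)
        folds = np.array_split(perm, k)
        report.fold_assignments.append(folds)
        for fold in folds:
            preds = []
            for i in fold:
                dets = backend.segment(tiles[i], int(i))
                preds.append(len(filter_detections(dets, score_threshold, min_pixels)))
            report.folds.append(counting_metrics(truth_counts[fold], preds))
    return report


# ---------------------------------------------------------------------------
# matched-pair count regression (manual vs automatic counts)


@dataclass(frozen=True)
class CountRegression:
    slope: float
    intercept: float
    r_squared: float  # identity-line R^2, same formula as counting_metrics
    rmse: float
    frac_above_identity: float  # fraction of points with predicted > truth


def count_regression(truth_counts, predicted_counts) -> CountRegression:
    """OLS of automatic on manual counts plus identity-line diagnostics.

    The reported R^2 and RMSE are computed against the identity line y = x
    (the same formulas as :func:`counting_metrics`), so systematic over- or
    under-counting lowers them even when the OLS fit is tight; the fraction
    of points above y = x flags the direction of the bias.
    """
    t = np.asarray(truth_counts, dtype=float)
    p = np.asarray(predicted_counts, dtype=float)
    if t.size < 3:
        raise ValueError("need at least 3 count pairs")
    if np.ptp(t) == 0:
        raise ValueError("truth counts have zero variance")
    fit = stats.linregress(t, p)
    ce = counting_metrics(t, p)
    return CountRegression(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=ce.r_squared,
        rmse=ce.rmse,
        frac_above_identity=float((p > t).mean()),
    )
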