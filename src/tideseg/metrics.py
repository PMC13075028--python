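"""Region and boundary evaluation metrics.

Region metrics (mIoU, F1, precision, recall) come from pixel confusion
counts; binary mIoU averages the foreground and background IoU, and a class
absent from both prediction and ground truth contributes IoU = 1 so all-water
tiles are not penalised (configurable).

Boundary metrics operate on contour pixel sets extracted with the same
morphological gradient used for supervision labels:

* BF-score: a predicted contour pixel matches if a ground-truth contour pixel
  lies within Euclidean distance delta (default 3 px, inclusive), and
  symmetrically for recall; the score is the harmonic mean.
* Hausdorff distance: max over both directions of the nearest-neighbour
  Euclidean distance between the two contour sets.

Dataset aggregation pools confusion counts for region metrics and averages
BF-score and HD per image (HD only over images where both contours exist).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import ConfigError, InputError, ShapeError
from .supervision import morphological_gradient

__all__ = [
    "ConfusionCounts", "BoundaryPixelSet", "MetricReport",
    "confusion", "region_metrics", "extract_boundary", "bf_score",
    "hausdorff", "evaluate_pair", "aggregate", "report_frame",
]

DELTA_DEFAULT = 3.0


@dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest pixel tallies for the algae (foreground) class."""
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.fn + other.fn, self.tn + other.tn)


@dataclass(frozen=True)
class BoundaryPixelSet:
    pixels: frozenset
    delta: float = DELTA_DEFAULT

    def __post_init__(self):
        if self.delta <= 0:
            raise ConfigError("delta must be positive")

    def __len__(self) -> int:
        return len(self.pixels)

    def coords(self) -> np.ndarray:
        if not self.pixels:
            return np.empty((0, 2))
        return np.array(sorted(self.pixels), dtype=float)


@dataclass
class MetricReport:
    miou: float
    f1: float
    precision: float
    recall: float
    bf_score: float
    precision_b: float = float("nan")
    recall_b: float = float("nan")
    hd: float = float("nan")
    n_images: int = 1
    n_hd_excluded: int = 0
    extras: dict = field(default_factory=dict)


def _binary(mask: np.ndarray, name: str) -> np.ndarray:
    mask = np.asarray(mask)
    if not np.isin(mask, (0, 1)).all():
        raise InputError(f"{name} must be binary")
    return mask.astype(bool)


def confusion(pred: np.ndarray, gt: np.ndarray) -> ConfusionCounts:
    p = _binary(pred, "pred")
    g = _binary(gt, "gt")
    if p.shape != g.shape:
        raise ShapeError(f"pred {p.shape} vs gt {g.shape}")
    tp = int(np.sum(p & g))
    fp = int(np.sum(p & ~g))
    fn = int(np.sum(~p & g))
    tn = int(np.sum(~p & ~g))
    return ConfusionCounts(tp, fp, fn, tn)


def region_metrics(counts: ConfusionCounts, k: int = 1,
                   absent_class_iou: float = 1.0) -> tuple[float, float, float, float]:
    """(mIoU, F1, precision, recall) for binary segmentation.

    mIoU averages foreground IoU (tp / (tp+fp+fn)) and background IoU
    (tn / (tn+fn+fp)); a class with empty union contributes
    ``absent_class_iou``. F1/precision/recall are foreground-class scores,
    with the 0/0 convention = 0.
    """
    if k != 1:
        raise ConfigError("only binary segmentation (K=1) is supported")
    c = counts
    fg_union = c.tp + c.fp + c.fn
    bg_union = c.tn + c.fn + c.fp
    iou_fg = c.tp / fg_union if fg_union else absent_class_iou
    iou_bg = c.tn / bg_union if bg_union else absent_class_iou
    miou = 0.5 * (iou_fg + iou_bg)
    precision = c.tp / (c.tp + c.fp) if (c.tp + c.fp) else 0.0
    recall = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else 0.0
    f1 = (2 * precision * recall / (precision + recall)) if (precision + recall) else 0.0
    return miou, f1, precision, recall


def extract_boundary(mask: np.ndarray, delta: float = DELTA_DEFAULT) -> BoundaryPixelSet:
    """Contour pixel set of a binary mask via the 3x3 morphological gradient."""
    grad = morphological_gradient(mask)
    rows, cols = np.nonzero(grad)
    return BoundaryPixelSet(frozenset(zip(rows.tolist(), cols.tolist())), delta)


def _match_fraction(source: np.ndarray, reference: np.ndarray, delta: float) -> float:
    """Fraction of ``source`` points with a reference point within delta."""
    tree = cKDTree(reference)
    d, _ = tree.query(source, k=1)
    return float(np.mean(d <= delta))


def bf_score(bp: BoundaryPixelSet, bg: BoundaryPixelSet,
             delta: float | None = None) -> tuple[float, float, float]:
    """(precision_b, recall_b, BF) with inclusive delta-tolerance matching.

    Conventions: both contours empty -> (1, 1, 1); exactly one empty -> the
    undefined side is taken as 0 and the score is 0.
    """
    if delta is None:
        delta = bp.delta
    if delta <= 0:
        raise ConfigError("delta must be positive")
    p_pts, g_pts = bp.coords(), bg.coords()
    if len(p_pts) == 0 and len(g_pts) == 0:
        return 1.0, 1.0, 1.0
    if len(p_pts) == 0 or len(g_pts) == 0:
        return 0.0, 0.0, 0.0
    precision_b = _match_fraction(p_pts, g_pts, delta)
    recall_b = _match_fraction(g_pts, p_pts, delta)
    denom = precision_b + recall_b
    bf = 2 * precision_b * recall_b / denom if denom else 0.0
    return precision_b, recall_b, bf


def hausdorff(bp: BoundaryPixelSet, bg: BoundaryPixelSet) -> float:
    """Symmetric Hausdorff distance between two contour pixel sets.

    Both sets empty -> 0. Exactly one empty -> NaN (undefined; callers
    exclude such images from aggregation).
    """
    p_pts, g_pts = bp.coords(), bg.coords()
    if len(p_pts) == 0 and len(g_pts) == 0:
        return 0.0
    if len(p_pts) == 0 or len(g_pts) == 0:
        return float("nan")
    d_pg, _ = cKDTree(g_pts).query(p_pts, k=1)
    d_gp, _ = cKDTree(p_pts).query(g_pts, k=1)
    return float(max(d_pg.max(), d_gp.max()))


def evaluate_pair(pred: np.ndarray, gt: np.ndarray,
                  delta: float = DELTA_DEFAULT) -> tuple[MetricReport, ConfusionCounts]:
    """Full per-image metric report for one prediction/ground-truth pair."""
    counts = confusion(pred, gt)
    miou, f1, prec, rec = region_metrics(counts)
    bp = extract_boundary(pred, delta)
    bg = extract_boundary(gt, delta)
    pb, rb, bf = bf_score(bp, bg, delta)
    hd = hausdorff(bp, bg)
    rep = MetricReport(miou=miou, f1=f1, precision=prec, recall=rec,
                       bf_score=bf, precision_b=pb, recall_b=rb, hd=hd)
    return rep, counts


def aggregate(reports: list[MetricReport],
              counts: list[ConfusionCounts],
              pool_region: bool = True) -> MetricReport:
    """Dataset-level report.

    Region metrics are recomputed from pooled confusion counts (or averaged
    per image when ``pool_region`` is False); BF-score is the per-image mean;
    HD is the mean over images where it is defined.
    """
    if not reports or len(reports) != len(counts):
        raise InputError("need matching non-empty report and count lists")
    if pool_region:
        pooled = counts[0]
        for c in counts[1:]:
            pooled = pooled + c
        miou, f1, prec, rec = region_metrics(pooled)
    else:
        miou = float(np.mean([r.miou for r in reports]))
        f1 = float(np.mean([r.f1 for r in reports]))
        prec = float(np.mean([r.precision for r in reports]))
        rec = float(np.mean([r.recall for r in reports]))
    bf = float(np.mean([r.bf_score for r in reports]))
    pb = float(np.mean([r.precision_b for r in reports]))
    rb = float(np.mean([r.recall_b for r in reports]))
    hds = [r.hd for r in reports if np.isfinite(r.hd)]
    hd = float(np.mean(hds)) if hds else float("nan")
    return MetricReport(miou=miou, f1=f1, precision=prec, recall=rec,
                        bf_score=bf, precision_b=pb, recall_b=rb, hd=hd,
                        n_images=len(reports),
                        n_hd_excluded=len(reports) - len(hds))


def report_frame(reports: list[MetricReport], index=None) -> pd.DataFrame:
    """Tabulate reports in the conventional column order."""
    rows = [{"mIoU": r.miou, "F1": r.f1, "Precision": r.precision,
             "Recall": r.recall, "BFScore": r.bf_score, "HD": r.hd}
            for r in reports]
    return pd.DataFrame(rows, index=index)
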