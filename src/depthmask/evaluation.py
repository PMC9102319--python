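"""Segmentation accuracy and the fully automatic benchmark.

Accuracy between a predicted mask A and ground truth G is the product of
precision and recall,

    a = |A ∩ G| / |A|  ×  |A ∩ G| / |G|,

a value in [0, 1] that is 1 only for a perfect mask and punishes both
leakage (low precision, e.g. a cluster bleeding into the background) and
under-segmentation (low recall).

The automatic benchmark asks: given only a ground-truth mask, how well
does seeded box clustering reproduce it?  The seed is the ground-truth
point nearest the ground-truth centroid (a click "near the middle of the
object"); growth stops when no more points can be added or when the
cluster has reached 90% of the ground-truth size (the pass that trips the
cap is kept whole, so the final size may overshoot).  Integer margins
b = 1..9 are swept and the best accuracy wins, ties to the smaller b.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .clustering import cluster_expanding_box
from .errors import ContractError
from .filtering import BilateralParams, bilateral_filter
from .io import DepthFrame, MaskFrame, Point3D, frame_to_points
from .kdtree import build_tree, reset_removal

logger = logging.getLogger(__name__)

HISTOGRAM_BIN_WIDTH = 0.04


def accuracy(pred: MaskFrame, truth: MaskFrame) -> float:
    """Precision x recall overlap between two masks.

    Empty-vs-nonempty scores 0; both empty scores 1 by convention (the
    degenerate case is logged, since no pixels were compared).
    """
    if (pred.width, pred.height) != (truth.width, truth.height):
        raise ContractError("mask dimensions differ")
    a = int(pred.bits.sum())
    g = int(truth.bits.sum())
    if a == 0 and g == 0:
        logger.info("accuracy of two empty masks: 1.0 by convention")
        return 1.0
    if a == 0 or g == 0:
        return 0.0
    inter = int((pred.bits & truth.bits).sum())
    return (inter / a) * (inter / g)


@dataclass
class AutoBenchmarkResult:
    best_b: float
    best_accuracy: float
    per_b: dict[float, float] = field(default_factory=dict)
    cluster_sizes: dict[float, int] = field(default_factory=dict)


def _centroid_seed(points: list[Point3D],
                   gt_pixels: set[tuple[int, int]]) -> Optional[Point3D]:
    """The ground-truth cloud point nearest the ground-truth centroid."""
    gt_points = [p for p in points if (p.px, p.py) in gt_pixels]
    if not gt_points:
        return None
    cx = sum(p.x for p in gt_points) / len(gt_points)
    cy = sum(p.y for p in gt_points) / len(gt_points)
    cz = sum(p.z for p in gt_points) / len(gt_points)
    return min(gt_points, key=lambda p: ((p.x - cx) ** 2 + (p.y - cy) ** 2
                                         + (p.z - cz) ** 2, p.py, p.px))


def auto_benchmark(frame: DepthFrame, truth: MaskFrame,
                   b_range: Sequence[float] = tuple(range(1, 10)),
                   params: Optional[BilateralParams] = None,
                   stop_fraction: float = 0.9) -> AutoBenchmarkResult:
    """Sweep margins over seeded expanding-box clustering against ``truth``.

    For each b the cluster grows from the centroid seed until natural
    termination or until its size reaches ``stop_fraction`` of the
    ground-truth point count, checked after each productive pass.
    """
    if not b_range:
        raise ContractError("b_range must be non-empty")
    gt_pixels = truth.pixel_set()
    if not gt_pixels:
        raise ContractError("ground truth mask is empty")
    filtered = bilateral_filter(frame, params) if params is not None else frame
    points = frame_to_points(filtered)
    tree = build_tree(points)
    seed = _centroid_seed(points, gt_pixels)
    if seed is None:
        raise ContractError("ground truth covers no valid depth pixels")
    gt_size = sum(1 for p in points if (p.px, p.py) in gt_pixels)
    cap = stop_fraction * gt_size

    result = AutoBenchmarkResult(best_b=b_range[0], best_accuracy=-1.0)
    for b in b_range:
        reset_removal(tree)
        cluster = cluster_expanding_box(tree, seed, b,
                                        stop=lambda size: size >= cap,
                                        halfspace=True)
        pred = MaskFrame.from_pixels(truth.width, truth.height,
                                     cluster.pixel_set)
        acc = accuracy(pred, truth)
        result.per_b[b] = acc
        result.cluster_sizes[b] = len(cluster)
        if acc > result.best_accuracy:
            result.best_accuracy = acc
            result.best_b = b
    return result


@dataclass
class AccuracyReport:
    """Per-frame accuracies of a predicted mask sequence."""

    per_frame: list[dict] = field(default_factory=list)
    mean: float = 0.0
    median: float = 0.0
    histogram: list[int] = field(default_factory=list)
    bin_width: float = HISTOGRAM_BIN_WIDTH

    def to_json(self) -> dict:
        return {"per_frame": self.per_frame, "mean": self.mean,
                "median": self.median, "histogram": self.histogram,
                "bin_width": self.bin_width}


def evaluate_sequence(pred_masks: Sequence[MaskFrame],
                      gt_masks: Sequence[MaskFrame]) -> AccuracyReport:
    """Per-frame accuracy, mean/median, and a fixed-width histogram.

    The histogram bins [0, 1] at width 0.04 (25 bins; a value of exactly
    1.0 falls in the last bin), so counts sum to the frame count.
    """
    if len(pred_masks) != len(gt_masks):
        raise ContractError("mask sequences differ in length")
    values = []
    per_frame = []
    for i, (pred, truth) in enumerate(zip(pred_masks, gt_masks)):
        a = accuracy(pred, truth)
        values.append(a)
        per_frame.append({"frame_index": i, "accuracy": a})
    arr = np.asarray(values, dtype=float)
    nbins = int(round(1.0 / HISTOGRAM_BIN_WIDTH))
    hist, _ = np.histogram(arr, bins=nbins, range=(0.0, 1.0))
    return AccuracyReport(per_frame=per_frame,
                          mean=float(arr.mean()) if len(arr) else 0.0,
                          median=float(np.median(arr)) if len(arr) else 0.0,
                          histogram=hist.tolist())


def benchmark_sequence(frames: Sequence[DepthFrame],
                       gt_masks: Sequence[MaskFrame],
                       b_range: Sequence[float] = tuple(range(1, 10)),
                       params: Optional[BilateralParams] = None
                       ) -> AccuracyReport:
    """Run the automatic benchmark on every frame of a sequence.

    Each frame is segmented from its own ground-truth centroid seed with
    the b sweep of :func:`auto_benchmark`; the report records the best b
    and accuracy per frame alongside the aggregate statistics.
    """
    if len(frames) != len(gt_masks):
        raise ContractError("frame and mask sequences differ in length")
    values = []
    per_frame = []
    for i, (frame, truth) in enumerate(zip(frames, gt_masks)):
        res = auto_benchmark(frame, truth, b_range, params)
        values.append(res.best_accuracy)
        per_frame.append({"frame_index": i, "best_b": res.best_b,
                          "accuracy": res.best_accuracy})
    arr = np.asarray(values, dtype=float)
    nbins = int(round(1.0 / HISTOGRAM_BIN_WIDTH))
    hist, _ = np.histogram(arr, bins=nbins, range=(0.0, 1.0))
    return AccuracyReport(per_frame=per_frame,
                          mean=float(arr.mean()) if len(arr) else 0.0,
                          median=float(np.median(arr)) if len(arr) else 0.0,
                          histogram=hist.tolist())
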