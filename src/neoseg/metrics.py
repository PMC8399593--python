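"""Segmentation and patch-classification evaluation.

Six metrics are derived from pixel- (or tile-) level confusion counts with
Neo as the positive class: accuracy, sensitivity, specificity, precision,
Jaccard and Dice.  A metric whose denominator is zero is *undefined* — a
distinguished value, rendered as "-" in reports and excluded from
averages, never coerced to 0 or 1.  With tp = 0 but fp + fn > 0 the
overlap metrics (precision, Jaccard, Dice) are a defined 0.

The patch-classification view tiles a segmented mask into fixed-size
rectangles and calls a tile positive iff it contains at least one Neo
pixel, applied identically to prediction and ground truth.
"""

from __future__ import annotations

import decimal
import math
from dataclasses import dataclass

import numpy as np

from .preprocess import PatchGrid

__all__ = [
    "UNDEFINED",
    "is_defined",
    "ConfusionCounts",
    "MetricsRecord",
    "EvaluationReport",
    "segment_probabilities",
    "confusion",
    "compute_metrics",
    "patch_classify",
    "aggregate_report",
    "round_half_up",
]

#: Distinguished "undefined metric" value (zero denominator).
UNDEFINED = float("nan")

METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "precision", "jaccard", "dice")


def is_defined(value: float) -> bool:
    return not math.isnan(value)


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN tallies over pixels or tiles (Neo = positive)."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.tn + other.tn,
            self.fp + other.fp, self.fn + other.fn,
        )


@dataclass(frozen=True)
class MetricsRecord:
    """The six derived metrics; undefined entries are NaN."""

    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    jaccard: float
    dice: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def segment_probabilities(probs: np.ndarray) -> np.ndarray:
    """Per-pixel decision from (2, H, W) or (H, W, 2) class probabilities.

    Class order (NotNeo, Neo); a pixel is Neo iff p(Neo) > 0.5, so an
    exact tie goes to NotNeo.  Returns a {0, 255} uint8 mask.
    """
    probs = np.asarray(probs, dtype=float)
    if probs.ndim != 3:
        raise ValueError("expected a 3-d probability raster")
    if probs.shape[0] == 2:
        p_neo = probs[1]
    elif probs.shape[2] == 2:
        p_neo = probs[:, :, 1]
    else:
        raise ValueError("probability raster must have a 2-class axis")
    return np.where(p_neo > 0.5, 255, 0).astype(np.uint8)


def confusion(prediction: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Per-unit tally of a predicted mask against ground truth."""
    pred = np.asarray(prediction) > 0
    true = np.asarray(truth) > 0
    if pred.shape != true.shape:
        raise ValueError(f"masks are misaligned: {pred.shape} vs {true.shape}")
    tp = int(np.count_nonzero(pred & true))
    tn = int(np.count_nonzero(~pred & ~true))
    fp = int(np.count_nonzero(pred & ~true))
    fn = int(np.count_nonzero(~pred & true))
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def _ratio(num: int, den: int) -> float:
    return num / den if den else UNDEFINED


def compute_metrics(c: ConfusionCounts) -> MetricsRecord:
    """Derive the six metrics; any zero denominator yields UNDEFINED."""
    if c.total == 0:
        raise ValueError("cannot compute metrics over zero units")
    return MetricsRecord(
        accuracy=_ratio(c.tp + c.tn, c.total),
        sensitivity=_ratio(c.tp, c.tp + c.fn),
        specificity=_ratio(c.tn, c.tn + c.fp),
        precision=_ratio(c.tp, c.tp + c.fp),
        jaccard=_ratio(c.tp, c.tp + c.fp + c.fn),
        dice=_ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn),
    )


def patch_classify(
    prediction: np.ndarray,
    truth: np.ndarray,
    tile_height: int = 200,
    tile_width: int = 296,
) -> ConfusionCounts:
    """Tile-level confusion: a tile is positive iff it holds a Neo pixel."""
    pred = np.asarray(prediction)
    true = np.asarray(truth)
    if pred.shape != true.shape:
        raise ValueError("prediction and truth masks are misaligned")
    grid = PatchGrid(tile_height, tile_width, mode="exact")
    n_rows, n_cols = grid.shape_for(pred.shape[0], pred.shape[1])
    ph, pw = tile_height, tile_width
    pred_tiles = (pred > 0).reshape(n_rows, ph, n_cols, pw).any(axis=(1, 3))
    true_tiles = (true > 0).reshape(n_rows, ph, n_cols, pw).any(axis=(1, 3))
    return confusion(pred_tiles, true_tiles)


@dataclass(frozen=True)
class EvaluationReport:
    """Per-image metrics plus the two average rows.

    Each average is the arithmetic mean over the images where the metric
    is defined; a metric undefined everywhere averages to UNDEFINED.
    """

    per_image: tuple[MetricsRecord, ...]
    segmentation_average: MetricsRecord
    patch_classification_average: MetricsRecord | None = None

    def to_csv(self) -> str:
        header = "image," + ",".join(METRIC_NAMES)
        lines = [header]
        for i, rec in enumerate(self.per_image, start=1):
            lines.append(f"{i}," + ",".join(_fmt(v) for v in rec.as_dict().values()))
        lines.append(
            "segmentation_average,"
            + ",".join(_fmt(v) for v in self.segmentation_average.as_dict().values())
        )
        if self.patch_classification_average is not None:
            lines.append(
                "patch_classification_average,"
                + ",".join(
                    _fmt(v) for v in self.patch_classification_average.as_dict().values()
                )
            )
        return "\n".join(lines) + "\n"


def round_half_up(value: float, decimals: int = 4) -> float:
    """Report rounding: half-way cases away from zero, as in printed tables.

    Decimal-based so that e.g. 0.74745 rounds to 0.7475 despite its binary
    representation falling a hair below the half-way point.
    """
    q = decimal.Decimal(1).scaleb(-decimals)
    return float(
        decimal.Decimal(repr(float(value))).quantize(q, rounding=decimal.ROUND_HALF_UP)
    )


def _fmt(v: float) -> str:
    return "-" if not is_defined(v) else f"{round_half_up(v):.4f}"


def aggregate_report(
    records: list[MetricsRecord],
    patch_counts: ConfusionCounts | None = None,
) -> EvaluationReport:
    """Average per-image records, excluding undefined entries per metric.

    ``patch_counts``, when given, are the tile-level confusion counts
    pooled over every test image; the patch-classification row is derived
    from that pool (e.g. "97% of the 400 tiles correctly classified").
    """
    if not records:
        raise ValueError("cannot aggregate an empty record list")

    def mean_record(recs: list[MetricsRecord]) -> MetricsRecord:
        values = {}
        for name in METRIC_NAMES:
            defined = [getattr(r, name) for r in recs if is_defined(getattr(r, name))]
            values[name] = float(np.mean(defined)) if defined else UNDEFINED
        return MetricsRecord(**values)

    return EvaluationReport(
        per_image=tuple(records),
        segmentation_average=mean_record(records),
        patch_classification_average=(
            compute_metrics(patch_counts) if patch_counts is not None else None
        ),
    )
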