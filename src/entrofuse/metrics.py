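"""Segmentation evaluation metrics from a single confusion-count core.

Every scalar metric (Jaccard foreground/background, mean IoU, Dice,
pixel accuracy, error rate, precision, recall/TPR, TNR) is a ratio of
exact integer voxel counts; AUROC is the tie-corrected rank (Mann–
Whitney) statistic on per-voxel scores.  Counts are accumulated as
integers, never as floating sums of indicators, so results are
bit-exact at any volume size.

Empty-set convention: a similarity metric whose denominator is zero
(e.g. foreground Jaccard when both prediction and truth are empty)
returns 1.0, and such undefined per-class terms are excluded from
per-slice averages.  This keeps per-slice means defined on slices with
no foreground objects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import (
    NonBinaryMaskError,
    ShapeMismatchError,
    UndefinedAUROCError,
    UnknownMetricError,
)
from .volio import GroundTruth, ModelPrediction, VoxelGrid

#: All metric names understood by :func:`metric_vector`.
SUPPORTED_METRICS = (
    "JI_F",
    "JI_B",
    "m_IoU",
    "DSC",
    "accuracy",
    "precision",
    "recall",
    "TPR",
    "TNR",
    "AUROC",
)

#: The seven-metric set reported per model and used by default to
#: calibrate ensemble weights.
DEFAULT_CALIBRATION_METRICS = (
    "JI_F",
    "JI_B",
    "m_IoU",
    "DSC",
    "accuracy",
    "precision",
    "recall",
)


@dataclass(frozen=True)
class ConfusionCounts:
    """Voxelwise TP/FP/FN/TN tallies for one prediction–truth pair."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class MetricVector:
    """Ordered metric-name -> value map for one model."""

    model_id: str
    entries: Dict[str, float]

    def values(self) -> np.ndarray:
        return np.array(list(self.entries.values()), dtype=np.float64)


def _binary_data(grid: VoxelGrid, what: str) -> np.ndarray:
    arr = grid.data
    if grid.role == "mask":
        return arr.astype(bool)
    uniq = np.unique(arr)
    if not np.isin(uniq, (0, 1)).all():
        raise NonBinaryMaskError(f"{what} grid is not binary (values {uniq[:5]})")
    return arr.astype(bool)


def _check_shapes(pred: ModelPrediction, truth: GroundTruth) -> None:
    if pred.grid.shape != truth.grid.shape:
        raise ShapeMismatchError(
            f"prediction {pred.model_id!r} shape {pred.grid.shape} != "
            f"truth shape {truth.grid.shape}"
        )


def confusion_counts(pred: ModelPrediction, truth: GroundTruth) -> ConfusionCounts:
    """Count TP/FP/FN/TN voxels for a binary prediction against truth."""
    _check_shapes(pred, truth)
    p = _binary_data(pred.grid, "prediction")
    t = _binary_data(truth.grid, "truth")
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = int(np.count_nonzero(~p & ~t))
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def slicewise_confusion_counts(
    pred: ModelPrediction, truth: GroundTruth
) -> list[ConfusionCounts]:
    """Per-z-slice confusion counts, in slice order."""
    _check_shapes(pred, truth)
    p = _binary_data(pred.grid, "prediction")
    t = _binary_data(truth.grid, "truth")
    out = []
    for z in range(p.shape[0]):
        ps, ts = p[z], t[z]
        out.append(
            ConfusionCounts(
                tp=int(np.count_nonzero(ps & ts)),
                fp=int(np.count_nonzero(ps & ~ts)),
                fn=int(np.count_nonzero(~ps & ts)),
                tn=int(np.count_nonzero(~ps & ~ts)),
            )
        )
    return out


def _ratio(num: int, den: int, empty: float = 1.0) -> float:
    return num / den if den > 0 else empty


def pixel_accuracy(cc: ConfusionCounts) -> float:
    """Fraction of voxels classified correctly: (TP + TN) / total."""
    if cc.total == 0:
        raise ValueError("pixel_accuracy undefined on an empty volume")
    return (cc.tp + cc.tn) / cc.total


def error_rate(cc: ConfusionCounts) -> float:
    """Fraction of voxels misclassified: (FP + FN) / total = 1 - accuracy."""
    if cc.total == 0:
        raise ValueError("error_rate undefined on an empty volume")
    return (cc.fp + cc.fn) / cc.total


def jaccard(cc: ConfusionCounts, target_class: str = "foreground") -> float:
    """Per-class Jaccard index (IoU); 1.0 when the class is empty in both."""
    if target_class == "foreground":
        return _ratio(cc.tp, cc.tp + cc.fp + cc.fn)
    if target_class == "background":
        return _ratio(cc.tn, cc.tn + cc.fp + cc.fn)
    raise ValueError(f"target_class must be foreground/background, got {target_class!r}")


def dice(cc: ConfusionCounts) -> float:
    """Dice similarity coefficient 2·TP / (2·TP + FP + FN)."""
    return _ratio(2 * cc.tp, 2 * cc.tp + cc.fp + cc.fn)


def precision_recall_tnr(cc: ConfusionCounts) -> tuple[float, float, float]:
    """(precision, recall/TPR, TNR) with the empty-set convention."""
    precision = _ratio(cc.tp, cc.tp + cc.fp)
    recall = _ratio(cc.tp, cc.tp + cc.fn)
    tnr = _ratio(cc.tn, cc.tn + cc.fp)
    return precision, recall, tnr


def _slice_miou(cc: ConfusionCounts) -> Optional[float]:
    """Mean of the per-class IoUs that are defined on this slice."""
    terms = []
    if cc.tp + cc.fp + cc.fn > 0:
        terms.append(cc.tp / (cc.tp + cc.fp + cc.fn))
    if cc.tn + cc.fp + cc.fn > 0:
        terms.append(cc.tn / (cc.tn + cc.fp + cc.fn))
    if not terms:
        return None
    return float(np.mean(terms))


def mean_iou(
    cc: Union[ConfusionCounts, Sequence[ConfusionCounts]],
    mode: str = "global",
) -> float:
    """Mean of foreground and background IoU.

    ``global`` (default) averages the two class IoUs computed on
    whole-volume counts.  ``per_slice`` expects the output of
    :func:`slicewise_confusion_counts` and averages the slicewise means,
    excluding per-class terms whose denominator is zero on that slice.
    """
    if mode == "global":
        if not isinstance(cc, ConfusionCounts):
            raise TypeError("global mode expects a single ConfusionCounts")
        return (jaccard(cc, "foreground") + jaccard(cc, "background")) / 2
    if mode == "per_slice":
        if isinstance(cc, ConfusionCounts):
            raise TypeError("per_slice mode expects a sequence of slicewise counts")
        vals = [m for m in (_slice_miou(s) for s in cc) if m is not None]
        if not vals:
            raise ValueError("no slice has a defined IoU")
        return float(np.mean(vals))
    raise ValueError(f"mode must be global/per_slice, got {mode!r}")


def auroc(pred: ModelPrediction, truth: GroundTruth) -> float:
    """Area under the ROC curve via the tie-corrected rank statistic.

    Equals the probability that a random positive voxel scores higher
    than a random negative one, ties counted half (Mann–Whitney U /
    (P·N)).  For binary scores this reduces to (TPR + TNR) / 2.
    """
    _check_shapes(pred, truth)
    t = _binary_data(truth.grid, "truth").ravel()
    scores = np.asarray(pred.grid.data, dtype=np.float64).ravel()
    n_pos = int(t.sum())
    n_neg = t.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise UndefinedAUROCError(
            f"AUROC undefined: truth has {n_pos} positives, {n_neg} negatives"
        )
    ranks = rankdata(scores)  # average ranks handle ties exactly
    u = ranks[t].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def metric_vector(
    pred: ModelPrediction,
    truth: GroundTruth,
    metric_names: Sequence[str] = DEFAULT_CALIBRATION_METRICS,
) -> MetricVector:
    """Evaluate an ordered set of named metrics for one model.

    Confusion-based metrics require a binary prediction; AUROC accepts
    scores or masks.  Entry order follows ``metric_names``.
    """
    unknown = [m for m in metric_names if m not in SUPPORTED_METRICS]
    if unknown:
        raise UnknownMetricError(
            f"unknown metric(s) {unknown}; supported: {list(SUPPORTED_METRICS)}"
        )
    needs_cc = any(m != "AUROC" for m in metric_names)
    cc = confusion_counts(pred, truth) if needs_cc else None
    entries: Dict[str, float] = {}
    for name in metric_names:
        if name == "AUROC":
            entries[name] = auroc(pred, truth)
            continue
        assert cc is not None
        if name == "JI_F":
            entries[name] = jaccard(cc, "foreground")
        elif name == "JI_B":
            entries[name] = jaccard(cc, "background")
        elif name == "m_IoU":
            entries[name] = mean_iou(cc, "global")
        elif name == "DSC":
            entries[name] = dice(cc)
        elif name == "accuracy":
            entries[name] = pixel_accuracy(cc)
        elif name == "precision":
            entries[name] = precision_recall_tnr(cc)[0]
        elif name in ("recall", "TPR"):
            entries[name] = precision_recall_tnr(cc)[1]
        elif name == "TNR":
            entries[name] = precision_recall_tnr(cc)[2]
    return MetricVector(model_id=pred.model_id, entries=entries)


def report_table(vectors: Sequence[MetricVector]) -> pd.DataFrame:
    """Rows = models, columns = metrics, in the vectors' declared order."""
    if not vectors:
        raise ValueError("no metric vectors to report")
    rows = {mv.model_id: mv.entries for mv in vectors}
    columns = list(vectors[0].entries)
    return pd.DataFrame.from_dict(rows, orient="index", columns=columns)


def write_report(
    table: pd.DataFrame,
    csv_path=None,
    text_path=None,
    float_format: str = "%.4f",
) -> None:
    """Write the metric table as CSV and/or aligned plain text."""
    if csv_path is not None:
        table.to_csv(csv_path, float_format=float_format)
    if text_path is not None:
        ndec = int(float_format.rsplit(".", 1)[-1].rstrip("f") or 4)
        text = table.to_string(float_format=lambda v: f"{v:.{ndec}f}")
        with open(text_path, "w") as fh:
            fh.write(text + "\n")
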