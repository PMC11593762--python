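"""Entropy-weighted ensemble fusion of segmentation predictions.

The core idea: each model's quality is summarized by a vector of
calibration metrics (Jaccard, Dice, accuracy, ...).  The vector is
normalized to a probability distribution and scored by Shannon entropy;
a more *peaked* (lower-entropy) metric profile indicates a more
discriminative model and earns a larger weight.  Weights are

    w_j = (1 - H_j) / sum_k (1 - H_k),

renormalized to sum to one (the identity whenever the denominator is
non-degenerate), and the fused score volume is the voxelwise convex
combination  P = sum_j w_j * m_j  of the models' predictions, finally
binarized at an inclusive threshold.

Two entropy conventions are provided.  ``normalized`` (default) divides
by log2(L) for L metrics so H is in [0, 1] and every 1 - H term is
non-negative.  ``raw_bits`` keeps H in bits; with more than two metrics
a near-uniform vector can then push H above 1 and make weights
negative, so the degenerate-denominator fallback (uniform weights)
guards that mode.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple, Union

import numpy as np

from .errors import InvalidMetricVectorError, ShapeMismatchError, WeightError
from .metrics import DEFAULT_CALIBRATION_METRICS, MetricVector, metric_vector
from .volio import GroundTruth, ModelPrediction, VoxelGrid, assert_compatible

ENTROPY_CONVENTIONS = ("normalized", "raw_bits")

#: Degeneracy tolerance for |sum_k (1 - H_k)|.
DEFAULT_EPSILON = 1e-9


@dataclass
class EntropyWeight:
    """Per-model entropy and the weights derived from it."""

    model_id: str
    entropy: float
    raw_weight: float
    normalized_weight: float
    degenerate: bool = False


@dataclass
class FusionResult:
    """Fused score grid, its binarization, and the weights used."""

    fused_scores: VoxelGrid
    fused_mask: VoxelGrid
    weights: list[EntropyWeight]
    threshold: float

    def weight_report(self) -> list[dict]:
        return [
            {
                "model_id": w.model_id,
                "entropy": w.entropy,
                "raw_weight": w.raw_weight,
                "normalized_weight": w.normalized_weight,
                "degenerate": w.degenerate,
            }
            for w in self.weights
        ]

    def write_weight_report(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.weight_report(), fh, indent=2)
            fh.write("\n")


def shannon_entropy(
    mv: Union[MetricVector, Sequence[float]],
    convention: str = "normalized",
) -> float:
    """Shannon entropy of a metric vector's induced distribution.

    Values are normalized to probabilities p_i = v_i / sum(v) (hence the
    result is invariant to rescaling all metrics by c > 0), and
    H = -sum p_i log2 p_i with 0·log 0 = 0.  The ``normalized``
    convention divides by log2(L) so H lies in [0, 1]; a single-metric
    vector has H = 0 under both conventions.
    """
    if convention not in ENTROPY_CONVENTIONS:
        raise ValueError(f"convention must be one of {ENTROPY_CONVENTIONS}")
    values = mv.values() if isinstance(mv, MetricVector) else np.asarray(
        mv, dtype=np.float64
    )
    if values.size == 0:
        raise InvalidMetricVectorError("empty metric vector")
    if not np.isfinite(values).all():
        raise InvalidMetricVectorError("metric vector contains non-finite values")
    if (values < 0).any():
        raise InvalidMetricVectorError("metric vector contains negative values")
    total = values.sum()
    if total <= 0:
        raise InvalidMetricVectorError("all-zero metric vector has no distribution")
    p = values / total
    nz = p[p > 0]
    h = float(-(nz * np.log2(nz)).sum())
    if convention == "normalized":
        L = values.size
        return h / np.log2(L) if L > 1 else 0.0
    return h


def entropy_weights(
    entropies: Sequence[Tuple[str, float]],
    epsilon: float = DEFAULT_EPSILON,
) -> list[EntropyWeight]:
    """Turn per-model entropies into normalized ensemble weights.

    raw_weight_j = (1 - H_j) / sum_k (1 - H_k); the normalized weight
    renormalizes the raw weights (idempotent when they already sum to
    one).  When |sum_k (1 - H_k)| <= epsilon the division is
    ill-conditioned: all models fall back to uniform weights and are
    flagged degenerate.
    """
    if len(entropies) < 2:
        raise WeightError("an ensemble needs at least 2 models")
    hs = np.array([h for _, h in entropies], dtype=np.float64)
    if not np.isfinite(hs).all():
        raise WeightError("non-finite entropy")
    denom = float((1.0 - hs).sum())
    n = len(entropies)
    if abs(denom) <= epsilon:
        return [
            EntropyWeight(mid, float(h), 1.0 / n, 1.0 / n, degenerate=True)
            for (mid, _), h in zip(entropies, hs)
        ]
    raw = (1.0 - hs) / denom
    norm = raw / raw.sum()  # identity up to rounding: raw sums to 1 by construction
    return [
        EntropyWeight(mid, float(h), float(r), float(w))
        for (mid, _), h, r, w in zip(entropies, hs, raw, norm)
    ]


def fuse(
    preds: Sequence[ModelPrediction],
    weights: Sequence[EntropyWeight],
    tol: float = 1e-6,
) -> VoxelGrid:
    """Voxelwise weighted average P = sum_j w_j * m_j of the predictions.

    The weights must cover exactly the predictions' model ids and their
    normalized values must sum to 1 within ``tol``.  Output scores are
    clipped to [0, 1] (only reachable with negative raw-bits weights).
    """
    if len(preds) < 2:
        raise WeightError("fusion needs at least 2 predictions")
    wmap = {w.model_id: w.normalized_weight for w in weights}
    pids = [p.model_id for p in preds]
    if set(wmap) != set(pids) or len(set(pids)) != len(pids):
        raise WeightError(
            f"weights cover {sorted(wmap)} but predictions are {pids}"
        )
    total = sum(wmap.values())
    if abs(total - 1.0) > tol:
        raise WeightError(f"normalized weights sum to {total}, expected 1")
    assert_compatible([p.grid for p in preds])
    fused = np.zeros(preds[0].grid.shape, dtype=np.float64)
    for p in preds:
        fused += wmap[p.model_id] * np.asarray(p.grid.data, dtype=np.float64)
    np.clip(fused, 0.0, 1.0, out=fused)
    return VoxelGrid(fused, "score")


def binarize(scores: VoxelGrid, threshold: float = 0.5, rule: str = "ge") -> VoxelGrid:
    """Threshold a score grid: mask = 1 where score >= threshold (inclusive)."""
    if rule != "ge":
        raise ValueError(f"only the inclusive 'ge' rule is supported, got {rule!r}")
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"threshold must lie in (0, 1], got {threshold}")
    data = np.asarray(scores.data, dtype=np.float64)
    return VoxelGrid((data >= threshold).astype(np.uint8), "mask")


def calibrate_and_fuse(
    calibration: Sequence[Tuple[ModelPrediction, GroundTruth]],
    targets: Sequence[ModelPrediction],
    metric_names: Sequence[str] = DEFAULT_CALIBRATION_METRICS,
    threshold: float = 0.5,
    convention: str = "normalized",
    epsilon: float = DEFAULT_EPSILON,
) -> FusionResult:
    """Full pipeline: metric vectors -> entropies -> weights -> fusion.

    ``calibration`` holds one (prediction, truth) pair per ensemble
    model, evaluated to a metric vector that determines the model's
    weight; ``targets`` holds the same models' predictions on the volume
    actually being fused.  Which labeled data plays the calibration role
    is the caller's contract.
    """
    calib_ids = [p.model_id for p, _ in calibration]
    target_ids = [p.model_id for p in targets]
    if set(calib_ids) != set(target_ids):
        raise WeightError(
            f"calibration models {sorted(calib_ids)} do not match "
            f"target models {sorted(target_ids)}"
        )
    entropies = []
    for pred, truth in calibration:
        mv = metric_vector(pred, truth, metric_names)
        entropies.append((pred.model_id, shannon_entropy(mv, convention)))
    weights = entropy_weights(entropies, epsilon)
    fused_scores = fuse(targets, weights)
    fused_mask = binarize(fused_scores, threshold)
    return FusionResult(
        fused_scores=fused_scores,
        fused_mask=fused_mask,
        weights=weights,
        threshold=threshold,
    )
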