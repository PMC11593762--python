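"""Synthetic phantoms: mitochondria-like truth volumes and degraded predictions.

Ground-truth phantoms contain disjoint oval (ellipsoid) and tube-like
(dilated random-walk) foreground objects, mimicking the two dominant
mitochondrial morphologies seen in FIB-SEM volumes.  Degradations
emulate the failure modes of real segmentation models:

* whole-object drops — detection-style false negatives, where an
  entire organelle is absent from one model's output;
* boundary erosion/dilation — systematic under-/over-segmentation;
* false-positive blobs placed off the true foreground;
* i.i.d. voxel flips — incoherent salt-and-pepper disagreement.

Every generator is a pure function of its spec: the random stream is
derived from (seed, operation-name), so repeat calls are bit-identical
and independent of call order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage
from skimage.morphology import ball

from .errors import InvalidSpecError, PlacementError
from .volio import GroundTruth, ModelPrediction, VoxelGrid

#: 26-connectivity structuring element for 3D component labeling.
STRUCT_26 = np.ones((3, 3, 3), dtype=bool)

_RETRIES_PER_OBJECT = 200
_RETRIES_PER_BLOB = 50


def _stream(seed: int, op_name: str) -> np.random.Generator:
    """One seeded stream per (seed, operation), independent of call order."""
    return np.random.default_rng([seed % (2**31), zlib.crc32(op_name.encode())])


@dataclass(frozen=True)
class PhantomSpec:
    """Ground-truth phantom parameters.

    ``shape_mix`` is the probability that an object is tube-like rather
    than oval; radii and tube lengths are in voxels.  ``min_gap`` >= 1
    guarantees objects stay distinct 26-connected components.
    """

    shape: Tuple[int, int, int] = (32, 64, 64)
    n_objects: int = 6
    shape_mix: float = 0.5
    radius_range: Tuple[int, int] = (2, 5)
    tube_length_range: Tuple[int, int] = (8, 20)
    min_gap: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or min(self.shape) < 1:
            raise InvalidSpecError(f"invalid shape {self.shape}")
        if self.n_objects < 0:
            raise InvalidSpecError("n_objects must be >= 0")
        if not 0.0 <= self.shape_mix <= 1.0:
            raise InvalidSpecError("shape_mix must be in [0, 1]")
        if not 1 <= self.radius_range[0] <= self.radius_range[1]:
            raise InvalidSpecError(f"invalid radius_range {self.radius_range}")
        if not 1 <= self.tube_length_range[0] <= self.tube_length_range[1]:
            raise InvalidSpecError(
                f"invalid tube_length_range {self.tube_length_range}"
            )
        if self.min_gap < 1:
            raise InvalidSpecError("min_gap must be >= 1")


@dataclass(frozen=True)
class DegradationSpec:
    """How one simulated model corrupts the truth."""

    object_drop_prob: float = 0.0
    boundary_radius: int = 0  # negative = erode, positive = dilate
    fp_blob_rate: float = 0.0  # Poisson mean blobs per volume
    fp_blob_radius_range: Tuple[int, int] = (1, 3)
    voxel_flip_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("object_drop_prob", "voxel_flip_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidSpecError(f"{name} must be in [0, 1], got {v}")
        if self.fp_blob_rate < 0:
            raise InvalidSpecError("fp_blob_rate must be >= 0")
        if not 1 <= self.fp_blob_radius_range[0] <= self.fp_blob_radius_range[1]:
            raise InvalidSpecError(
                f"invalid fp_blob_radius_range {self.fp_blob_radius_range}"
            )


def _ellipsoid(shape, center, radii) -> np.ndarray:
    """Boolean volume of an axis-aligned ellipsoid (clipped to bounds)."""
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    cz, cy, cx = center
    rz, ry, rx = radii
    return (
        ((zz - cz) / rz) ** 2 + ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2
    ) <= 1.0


def _tube(shape, rng, radius: int, length: int) -> Optional[np.ndarray]:
    """Dilated random-walk centerline; None if the walk cannot stay inside."""
    margin = radius + 1
    lo = np.array([margin] * 3, dtype=np.float64)
    hi = np.array(shape, dtype=np.float64) - 1 - margin
    if (hi < lo).any():
        return None
    pos = rng.uniform(lo, hi)
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    core = np.zeros(shape, dtype=bool)
    steps = 0
    for _ in range(length):
        idx = tuple(np.round(pos).astype(int))
        core[idx] = True
        steps += 1
        direction = direction + rng.normal(scale=0.35, size=3)
        direction /= np.linalg.norm(direction)
        nxt = pos + direction
        if (nxt < lo).any() or (nxt > hi).any():
            direction = -direction  # bounce back off the safe boundary
            nxt = pos + direction
            if (nxt < lo).any() or (nxt > hi).any():
                break
        pos = nxt
    if steps < max(2, length // 2):
        return None
    return ndimage.binary_dilation(core, structure=ball(radius))


def generate_ground_truth(spec: PhantomSpec) -> GroundTruth:
    """Generate a binary phantom with exactly ``n_objects`` components.

    Objects are placed sequentially with rejection sampling: a candidate
    must fit inside the volume and keep at least ``min_gap`` voxels of
    clearance from all previously placed objects (checked against a
    26-connected dilation of the current foreground), so the final
    volume has exactly n_objects 26-connected components.
    """
    rng = _stream(spec.seed, "generate_ground_truth")
    fg = np.zeros(spec.shape, dtype=bool)
    forbidden = np.zeros(spec.shape, dtype=bool)
    placed = 0
    for _ in range(spec.n_objects):
        ok = False
        for _attempt in range(_RETRIES_PER_OBJECT):
            make_tube = rng.random() < spec.shape_mix
            if make_tube:
                radius = int(rng.integers(spec.radius_range[0], spec.radius_range[1] + 1))
                length = int(
                    rng.integers(spec.tube_length_range[0], spec.tube_length_range[1] + 1)
                )
                cand = _tube(spec.shape, rng, radius, length)
                if cand is None:
                    continue
            else:
                radii = rng.integers(
                    spec.radius_range[0], spec.radius_range[1] + 1, size=3
                )
                lo = radii.astype(np.float64)
                hi = np.array(spec.shape, dtype=np.float64) - 1 - radii
                if (hi < lo).any():
                    continue
                # integer centers keep equal-radius ovals voxel-identical
                center = np.round(rng.uniform(lo, hi)).astype(int)
                cand = _ellipsoid(spec.shape, center, radii)
            if not cand.any() or (cand & forbidden).any():
                continue
            fg |= cand
            forbidden = ndimage.binary_dilation(
                fg, structure=STRUCT_26, iterations=spec.min_gap
            )
            placed += 1
            ok = True
            break
        if not ok:
            raise PlacementError(
                f"could not place object {placed + 1}/{spec.n_objects} in "
                f"{spec.shape} after {_RETRIES_PER_OBJECT} attempts"
            )
    return GroundTruth(VoxelGrid(fg.astype(np.uint8), "mask"))


def degrade(
    truth: GroundTruth,
    spec: DegradationSpec,
    model_id: Optional[str] = None,
) -> ModelPrediction:
    """Corrupt a truth volume into one simulated model prediction.

    Pipeline order: whole-object drops, boundary erosion/dilation,
    false-positive blobs (never touching the true foreground), then
    independent voxel flips.  Deterministic given ``spec.seed``.
    """
    rng = _stream(spec.seed, "degrade")
    t = truth.grid.data.astype(bool)
    labels, ncomp = ndimage.label(t, structure=STRUCT_26)
    pred = t.copy()

    if ncomp > 0 and spec.object_drop_prob > 0:
        drop = rng.random(ncomp) < spec.object_drop_prob
        if drop.any():
            dropped_ids = np.flatnonzero(drop) + 1
            pred[np.isin(labels, dropped_ids)] = False

    if spec.boundary_radius < 0:
        pred = ndimage.binary_erosion(pred, structure=ball(-spec.boundary_radius))
    elif spec.boundary_radius > 0:
        pred = ndimage.binary_dilation(pred, structure=ball(spec.boundary_radius))

    if spec.fp_blob_rate > 0:
        n_blobs = int(rng.poisson(spec.fp_blob_rate))
        if n_blobs > 0:
            # blobs must stay clear of the truth foreground so FP counts
            # in tests are unambiguous
            forbidden = ndimage.binary_dilation(t, structure=STRUCT_26)
            shape = np.array(truth.grid.shape)
            for _ in range(n_blobs):
                for _attempt in range(_RETRIES_PER_BLOB):
                    radius = int(
                        rng.integers(
                            spec.fp_blob_radius_range[0],
                            spec.fp_blob_radius_range[1] + 1,
                        )
                    )
                    center = rng.uniform(np.zeros(3), shape - 1)
                    blob = _ellipsoid(truth.grid.shape, center, (radius,) * 3)
                    if blob.any() and not (blob & forbidden).any():
                        pred |= blob
                        break

    if spec.voxel_flip_prob > 0:
        flips = rng.random(truth.grid.shape) < spec.voxel_flip_prob
        pred ^= flips

    mid = model_id if model_id is not None else f"degraded-{spec.seed}"
    return ModelPrediction(mid, VoxelGrid(pred.astype(np.uint8), "mask"))


def scenario_complementary_fn(
    truth: GroundTruth,
    n_missed_per_model: int,
    seed: int = 0,
    model_ids: Tuple[str, str] = ("model_a", "model_b"),
) -> Tuple[ModelPrediction, ModelPrediction]:
    """Two otherwise-perfect predictions missing disjoint whole objects.

    Each prediction equals the truth minus ``n_missed_per_model`` whole
    components; the two missed sets are disjoint, so the voxelwise
    union of the predictions reconstructs the truth exactly.  This is
    the canonical complementary-false-negative scenario that weighted
    fusion is designed to repair.
    """
    if n_missed_per_model < 0:
        raise InvalidSpecError("n_missed_per_model must be >= 0")
    t = truth.grid.data.astype(bool)
    labels, ncomp = ndimage.label(t, structure=STRUCT_26)
    if ncomp < 2 * n_missed_per_model:
        raise ValueError(
            f"need >= {2 * n_missed_per_model} components, truth has {ncomp}"
        )
    rng = _stream(seed, "scenario_complementary_fn")
    order = rng.permutation(ncomp) + 1
    miss_a = order[:n_missed_per_model]
    miss_b = order[n_missed_per_model : 2 * n_missed_per_model]
    pred_a = t & ~np.isin(labels, miss_a)
    pred_b = t & ~np.isin(labels, miss_b)
    return (
        ModelPrediction(model_ids[0], VoxelGrid(pred_a.astype(np.uint8), "mask")),
        ModelPrediction(model_ids[1], VoxelGrid(pred_b.astype(np.uint8), "mask")),
    )
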