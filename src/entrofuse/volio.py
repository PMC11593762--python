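"""Volume I/O and the canonical in-memory grid.

Every stage of the pipeline works on a :class:`VoxelGrid`: a 3D numpy
array in (z, y, x) axis order with a declared *role* — ``intensity`` for
raw image data, ``score`` for per-voxel probabilities in [0, 1], and
``mask`` for binary labels in {0, 1}.  Readers normalize the common
on-disk encodings (multi-page TIFF, HDF5, directories of 2D slices;
masks stored as {0, 255} or {0, 1}) into that one representation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import h5py
import imageio.v3 as iio
import numpy as np
import tifffile

from .errors import (
    MissingPathError,
    MixedSliceShapesError,
    NonBinaryMaskError,
    NonVolumeDatasetError,
    ShapeMismatchError,
    UnreadableFormatError,
    UnsupportedFormatError,
    VolumeIOError,
)

ROLES = ("intensity", "score", "mask")

_SLICE_SUFFIXES = {".png", ".tif", ".tiff", ".bmp", ".jpg", ".jpeg"}
_HDF5_SUFFIXES = {".h5", ".hdf5", ".hdf"}
_TIFF_SUFFIXES = {".tif", ".tiff"}

#: Default HDF5 dataset keys probed in order when none is given,
#: matching common 3D segmentation tooling ("raw" images, "label" masks).
DEFAULT_H5_KEYS = ("raw", "label", "data", "volume")


@dataclass
class VoxelGrid:
    """A 3D scalar grid in (z, y, x) order with 0-based indices.

    Parameters
    ----------
    data:
        3D array of finite scalars.  Masks are stored as uint8 {0, 1};
        scores as floats in [0, 1].
    role:
        One of ``intensity``, ``score``, ``mask``.
    """

    data: np.ndarray
    role: str = "intensity"

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise NonVolumeDatasetError(
                f"VoxelGrid requires a 3D array, got ndim={arr.ndim}"
            )
        if min(arr.shape) < 1:
            raise NonVolumeDatasetError(f"empty volume with shape {arr.shape}")
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}, got {self.role!r}")
        if np.issubdtype(arr.dtype, np.floating) and not np.isfinite(arr).all():
            raise ValueError("VoxelGrid contains non-finite values")
        if self.role == "mask":
            uniq = np.unique(arr)
            if not np.isin(uniq, (0, 1)).all():
                raise NonBinaryMaskError(
                    f"mask grid has values outside {{0, 1}}: {uniq[:5]}"
                )
            arr = arr.astype(np.uint8, copy=False)
        elif self.role == "score":
            arr = np.asarray(arr, dtype=np.float64)
            if arr.min() < 0.0 or arr.max() > 1.0:
                raise ValueError(
                    f"score grid outside [0, 1]: min={arr.min()}, max={arr.max()}"
                )
        self.data = arr

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)  # type: ignore[return-value]

    def astype_role(self, role: str) -> "VoxelGrid":
        """Reinterpret the same data under a different role (revalidates)."""
        return VoxelGrid(self.data, role)


@dataclass
class GroundTruth:
    """Expert-annotated binary reference volume."""

    grid: VoxelGrid

    def __post_init__(self) -> None:
        if self.grid.role != "mask":
            raise NonBinaryMaskError("ground truth must be a mask grid")


@dataclass
class ModelPrediction:
    """One model's predicted volume: a binary mask or a score map."""

    model_id: str
    grid: VoxelGrid

    def __post_init__(self) -> None:
        if not self.model_id:
            raise ValueError("model_id must be a non-empty string")
        if self.grid.role not in ("mask", "score"):
            raise ValueError("prediction grid role must be 'mask' or 'score'")


def natural_key(name: str) -> list:
    """Sort key treating digit runs numerically, so s2 < s10 and s001 == s1."""
    return [
        int(tok) if tok.isdigit() else tok.lower()
        for tok in re.split(r"(\d+)", name)
    ]


def _normalize_mask(arr: np.ndarray) -> np.ndarray:
    """Map a two-valued array {a, b}, a < b, to {0, 1} (255 -> 1 etc.)."""
    uniq = np.unique(arr)
    if uniq.size > 2:
        raise NonBinaryMaskError(
            f"cannot read as mask: {uniq.size} distinct values (first: {uniq[:5]})"
        )
    if uniq.size == 2:
        return (arr == uniq[1]).astype(np.uint8)
    # single-valued volume: anything positive is foreground
    return (arr > 0).astype(np.uint8)


def _infer_role(arr: np.ndarray) -> str:
    uniq = np.unique(arr)
    is_label_coded = np.isin(uniq, (0, 1, 255)).all() or np.issubdtype(
        arr.dtype, np.integer
    )
    if uniq.size <= 2 and is_label_coded:
        return "mask"
    if np.issubdtype(arr.dtype, np.floating) and 0.0 <= arr.min() and arr.max() <= 1.0:
        return "score"
    return "intensity"


def _coerce(arr: np.ndarray, role: str) -> VoxelGrid:
    if role == "auto":
        role = _infer_role(arr)
    if role == "mask":
        return VoxelGrid(_normalize_mask(arr), "mask")
    if role == "score":
        arr = np.asarray(arr, dtype=np.float64)
        if arr.max() > 1.0:  # 8-bit encoded probabilities
            arr = arr / 255.0
        return VoxelGrid(arr, "score")
    return VoxelGrid(arr, "intensity")


def _infer_format(path: Path) -> str:
    if path.is_dir():
        return "slice_dir"
    suffix = path.suffix.lower()
    if suffix in _HDF5_SUFFIXES:
        return "hdf5"
    if suffix in _TIFF_SUFFIXES:
        return "tiff_stack"
    raise UnsupportedFormatError(f"cannot infer volume format from {path.name!r}")


def _read_tiff(path: Path) -> np.ndarray:
    try:
        arr = tifffile.imread(path)
    except (tifffile.TiffFileError, ValueError) as exc:
        raise UnreadableFormatError(f"cannot decode TIFF {path}: {exc}") from exc
    if arr.ndim == 2:
        arr = arr[np.newaxis]
    if arr.ndim != 3:
        raise NonVolumeDatasetError(
            f"TIFF {path} has ndim={arr.ndim}; expected a stack of 2D pages"
        )
    return arr


def _read_hdf5(path: Path, dataset_key: Optional[str]) -> np.ndarray:
    with h5py.File(path, "r") as fh:
        if dataset_key is not None:
            if dataset_key not in fh:
                raise UnreadableFormatError(
                    f"dataset {dataset_key!r} not found in {path}"
                )
            dset = fh[dataset_key]
        else:
            dset = None
            for key in DEFAULT_H5_KEYS:
                if key in fh and isinstance(fh[key], h5py.Dataset):
                    dset = fh[key]
                    break
            if dset is None:
                dsets = [k for k in fh if isinstance(fh[k], h5py.Dataset)]
                if len(dsets) != 1:
                    raise UnreadableFormatError(
                        f"no dataset_key given and no unique dataset in {path} "
                        f"(found {dsets})"
                    )
                dset = fh[dsets[0]]
        if not isinstance(dset, h5py.Dataset) or dset.ndim != 3:
            raise NonVolumeDatasetError(
                f"{path}:{dset.name} is not a 3D dataset"
            )
        return dset[()]


def _read_slice_dir(path: Path) -> np.ndarray:
    files = sorted(
        (p for p in path.iterdir() if p.suffix.lower() in _SLICE_SUFFIXES),
        key=lambda p: natural_key(p.name),
    )
    if not files:
        raise UnreadableFormatError(f"no slice images found in {path}")
    slices = []
    for fp in files:
        try:
            img = np.asarray(iio.imread(fp))
        except (OSError, ValueError) as exc:
            raise UnreadableFormatError(f"cannot decode slice {fp}: {exc}") from exc
        if img.ndim == 3:
            if img.shape[-1] in (3, 4) and np.all(img[..., :3] == img[..., :1]):
                img = img[..., 0]
            else:
                raise UnreadableFormatError(
                    f"slice {fp} is not grayscale (shape {img.shape})"
                )
        if img.ndim != 2:
            raise NonVolumeDatasetError(f"slice {fp} has ndim={img.ndim}")
        slices.append(img)
    shapes = {s.shape for s in slices}
    if len(shapes) > 1:
        raise MixedSliceShapesError(
            f"slices in {path} have mixed shapes: {sorted(shapes)}"
        )
    return np.stack(slices, axis=0)


def read_volume(
    path,
    format_hint: Optional[str] = None,
    dataset_key: Optional[str] = None,
    role: str = "auto",
) -> VoxelGrid:
    """Read a volume from disk into the canonical (z, y, x) grid.

    Parameters
    ----------
    path:
        Multi-page TIFF file, HDF5 file, or directory of 2D slices.
    format_hint:
        One of ``tiff_stack``, ``slice_dir``, ``hdf5``; inferred from the
        path when omitted.
    dataset_key:
        HDF5 dataset name; when omitted, common keys ("raw", "label", ...)
        are probed, falling back to a unique dataset.
    role:
        ``auto`` (default) infers: two-valued volumes become masks (the
        lower value maps to 0, the higher to 1, so {0, 255} and {0, 1}
        encodings coincide), floats within [0, 1] become scores, anything
        else intensity.  Pass an explicit role to override.
    """
    path = Path(path)
    if not path.exists():
        raise MissingPathError(f"no such path: {path}")
    fmt = format_hint or _infer_format(path)
    if fmt == "tiff_stack":
        arr = _read_tiff(path)
    elif fmt == "hdf5":
        arr = _read_hdf5(path, dataset_key)
    elif fmt == "slice_dir":
        arr = _read_slice_dir(path)
    else:
        raise UnsupportedFormatError(f"unknown format hint {fmt!r}")
    return _coerce(arr, role)


def write_volume(
    grid: VoxelGrid,
    path,
    format: Optional[str] = None,
    dataset_key: Optional[str] = None,
) -> None:
    """Write a grid to a multi-page TIFF or an HDF5 file.

    Masks are stored 8-bit as {0, 255}; scores as float32.  Round-trip
    through :func:`read_volume` is exact for masks and within float32
    precision for scores.
    """
    path = Path(path)
    if not path.parent.exists():
        raise MissingPathError(f"parent directory does not exist: {path.parent}")
    if format is None:
        suffix = path.suffix.lower()
        if suffix in _TIFF_SUFFIXES:
            format = "tiff_stack"
        elif suffix in _HDF5_SUFFIXES:
            format = "hdf5"
        else:
            raise UnsupportedFormatError(
                f"cannot infer output format from {path.name!r}"
            )
    if grid.role == "mask":
        out = (grid.data.astype(np.uint8) * 255)
    elif grid.role == "score":
        out = grid.data.astype(np.float32)
    else:
        out = grid.data
    if format == "tiff_stack":
        try:
            # explicit photometric keeps small stacks from being guessed as RGB
            tifffile.imwrite(path, out, photometric="minisblack")
        except OSError as exc:
            raise VolumeIOError(f"cannot write {path}: {exc}") from exc
    elif format == "hdf5":
        key = dataset_key or ("label" if grid.role == "mask" else "raw")
        try:
            with h5py.File(path, "w") as fh:
                fh.create_dataset(key, data=out)
        except OSError as exc:
            raise VolumeIOError(f"cannot write {path}: {exc}") from exc
    else:
        raise UnsupportedFormatError(f"unsupported output format {format!r}")


def assert_compatible(grids: Sequence[VoxelGrid]) -> None:
    """Check that all grids share one shape; name offenders otherwise."""
    if len(grids) < 2:
        raise ValueError("assert_compatible needs at least two grids")
    ref = grids[0].shape
    bad = [
        (i, g.shape) for i, g in enumerate(grids) if g.shape != ref
    ]
    if bad:
        raise ShapeMismatchError(
            f"grid 0 has shape {ref}; mismatching grids: "
            + ", ".join(f"#{i}={s}" for i, s in bad)
        )
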