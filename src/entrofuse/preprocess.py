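"""Slicewise preprocessing applied before segmentation.

Two stages, both operating independently on each 2D z-slice (their
parameters — an 8x8 tile grid, a 3x3 kernel — are 2D notions):

1. CLAHE (contrast-limited adaptive histogram equalization) with a
   clip limit of 2 and an 8x8 tile grid, to even out contrast across
   an image stack without over-amplifying noise.
2. A 3x3 Gaussian blur to suppress residual high-frequency noise.

The clip limit follows the common OpenCV convention (multiples of the
average histogram bin height); it is mapped to scikit-image's
normalized clip (``clip / nbins``) internally.  The Gaussian sigma for
a k x k kernel follows the derive-from-kernel-size convention
sigma = 0.3*((k-1)/2 - 1) + 0.8, i.e. 0.8 for k = 3.  Slice borders
are reflect-padded to avoid dark rims.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy import ndimage
from skimage import exposure

from .errors import InvalidSpecError
from .volio import VoxelGrid

_CLAHE_NBINS = 256


@dataclass(frozen=True)
class PreprocessSpec:
    """Parameters of the preprocessing stage."""

    clahe_clip_limit: float = 2.0
    clahe_tile_grid: Tuple[int, int] = (8, 8)
    blur_kernel: int = 3

    def __post_init__(self) -> None:
        if self.clahe_clip_limit <= 0:
            raise InvalidSpecError("clahe_clip_limit must be > 0")
        rows, cols = self.clahe_tile_grid
        if rows < 1 or cols < 1:
            raise InvalidSpecError("clahe_tile_grid dims must be >= 1")
        if self.blur_kernel < 1 or self.blur_kernel % 2 == 0:
            raise InvalidSpecError("blur_kernel must be odd and >= 1")


def _intensity_domain(arr: np.ndarray) -> float:
    """Range ceiling of the declared intensity domain: 1.0 or 255.0."""
    if np.issubdtype(arr.dtype, np.floating) and arr.max() <= 1.0:
        return 1.0
    return 255.0


def clahe_slicewise(vol: VoxelGrid, spec: PreprocessSpec = PreprocessSpec()) -> VoxelGrid:
    """Apply 2D CLAHE independently to each z-slice.

    Deterministic for a fixed spec; output stays within the input's
    intensity domain (8-bit [0, 255] or normalized [0, 1]) and keeps
    the input dtype.
    """
    arr = np.asarray(vol.data)
    domain = _intensity_domain(arr)
    rows, cols = spec.clahe_tile_grid
    out = np.empty(arr.shape, dtype=np.float64)
    clip_norm = spec.clahe_clip_limit / _CLAHE_NBINS
    for z in range(arr.shape[0]):
        sl = arr[z].astype(np.float64) / domain
        h, w = sl.shape
        kernel = (max(1, math.ceil(h / rows)), max(1, math.ceil(w / cols)))
        out[z] = exposure.equalize_adapthist(
            sl, kernel_size=kernel, clip_limit=clip_norm, nbins=_CLAHE_NBINS
        )
    out *= domain
    if np.issubdtype(arr.dtype, np.integer):
        out = np.rint(out).astype(arr.dtype)
    return VoxelGrid(out, "intensity")


def gaussian_kernel_2d(size: int) -> np.ndarray:
    """Normalized size x size Gaussian kernel, sigma from the size convention."""
    sigma = 0.3 * ((size - 1) * 0.5 - 1) + 0.8
    half = size // 2
    x = np.arange(-half, half + 1, dtype=np.float64)
    g = np.exp(-(x**2) / (2 * sigma**2))
    g /= g.sum()
    return np.outer(g, g)


def gaussian_blur(vol: VoxelGrid, spec: PreprocessSpec = PreprocessSpec()) -> VoxelGrid:
    """Convolve each z-slice with the normalized k x k Gaussian kernel.

    Linear and shift-invariant; reflect border handling, so constant
    slices are reproduced exactly.  Returns a float64 grid.
    """
    kernel = gaussian_kernel_2d(spec.blur_kernel)
    arr = np.asarray(vol.data, dtype=np.float64)
    # a (1, k, k) kernel convolved in 3D is exactly slicewise 2D convolution
    out = ndimage.convolve(arr, kernel[np.newaxis, :, :], mode="reflect")
    return VoxelGrid(out, "intensity")


def align_slices(vol: VoxelGrid, spec: PreprocessSpec = PreprocessSpec()) -> VoxelGrid:
    """Slice-alignment hook; currently the identity.

    A geometric inter-slice alignment step belongs here conceptually,
    but no transform model is fixed, so this hook passes the volume
    through unchanged and exists so pipelines can name the stage.
    """
    return vol


def preprocess(vol: VoxelGrid, spec: PreprocessSpec = PreprocessSpec()) -> VoxelGrid:
    """CLAHE, then Gaussian blur, then the (identity) alignment hook."""
    return align_slices(gaussian_blur(clahe_slicewise(vol, spec), spec), spec)
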