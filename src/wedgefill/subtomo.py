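"""Sliding-window sub-tomogram extraction and overlap-averaged reassembly.

The grid clamps the last window of each axis to the boundary so every voxel
is covered at least once; reassembly averages all windows covering a voxel
with uniform weights, which makes extract -> reassemble the identity on any
volume.  An intensity-based content mask plus a minimum-fill filter can
restrict fitting to windows that actually contain sample.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage

from .core import GridPosition, ParameterError, SubTomoPair, Volume

__all__ = [
    "plan_grid",
    "content_mask",
    "filter_positions",
    "extract_pairs",
    "reassemble",
]


def _axis_corners(dim: int, cube: int, stride: int) -> list[int]:
    corners = list(range(0, dim - cube + 1, stride))
    if corners[-1] != dim - cube:
        corners.append(dim - cube)  # clamp last window to the boundary
    return corners


def plan_grid(vol_shape: tuple[int, int, int], cube_size: int,
              overlap: int) -> list[GridPosition]:
    """Corner positions of overlapping cubes fully covering ``vol_shape``."""
    if not 0 <= overlap < cube_size:
        raise ParameterError("overlap must satisfy 0 <= overlap < cube_size")
    if any(cube_size > d for d in vol_shape):
        raise ParameterError("cube_size exceeds a volume dimension")
    stride = cube_size - overlap
    axes = [_axis_corners(d, cube_size, stride) for d in vol_shape]
    return [GridPosition(z, y, x) for z in axes[0] for y in axes[1] for x in axes[2]]


def content_mask(vol: Volume, smooth_sigma: float = 2.0,
                 percentile: float = 70.0) -> Volume:
    """Binary mask of non-empty regions.

    Gaussian-smooths ``|vol - median|`` and thresholds at the given
    percentile of the smoothed values.  Invariant to affine intensity
    rescaling of the input.  A constant volume yields an all-zero mask (with
    a warning).
    """
    if not 0.0 < percentile < 100.0:
        raise ParameterError("percentile must lie in (0, 100)")
    data = vol.data
    if np.ptp(data) == 0:
        warnings.warn("constant volume: content mask is empty", stacklevel=2)
        return Volume(np.zeros_like(data), vol.voxel_size_A)
    dev = np.abs(data - np.median(data))
    smooth = ndimage.gaussian_filter(dev, smooth_sigma)
    thr = np.percentile(smooth, percentile)
    return Volume((smooth > thr).astype(np.float32), vol.voxel_size_A)


def filter_positions(positions: list[GridPosition], mask: Volume,
                     min_fraction: float, cube_size: int) -> list[GridPosition]:
    """Keep positions whose cube contains at least ``min_fraction`` sample."""
    if not 0.0 <= min_fraction <= 1.0:
        raise ParameterError("min_fraction must lie in [0, 1]")
    kept = []
    s = cube_size
    for p in positions:
        frac = float(mask.data[p.z0:p.z0 + s, p.y0:p.y0 + s, p.x0:p.x0 + s].mean())
        if frac >= min_fraction:
            kept.append(p)
    return kept


def _check_positions(positions: list[GridPosition], cube: int,
                     shape: tuple[int, int, int]) -> None:
    for p in positions:
        c = p.as_tuple()
        if any(o < 0 or o + cube > d for o, d in zip(c, shape)):
            raise ParameterError(f"position {c} out of bounds for shape {shape}")


def extract_pairs(vol0: Volume, vol1: Volume, positions: list[GridPosition],
                  cube_size: int) -> list[SubTomoPair]:
    """Copy out cubic sub-tomogram pairs; per-pair standardization stats are
    computed from ``v0`` (the half whose wedge gets updated during fitting)."""
    if vol0.shape != vol1.shape:
        raise ParameterError("half-volumes must share a shape")
    _check_positions(positions, cube_size, vol0.shape)
    pairs = []
    s = cube_size
    for p in positions:
        sl = (slice(p.z0, p.z0 + s), slice(p.y0, p.y0 + s), slice(p.x0, p.x0 + s))
        c0 = vol0.data[sl].copy()
        c1 = vol1.data[sl].copy()
        std = float(c0.std())
        stats = (float(c0.mean()), std if std > 0 else 1.0)
        pairs.append(SubTomoPair(c0, c1, p, stats))
    return pairs


def reassemble(cubes: list[np.ndarray], positions: list[GridPosition],
               out_shape: tuple[int, int, int]) -> Volume:
    """Average overlapping cubes back into a full volume.

    Every voxel must be covered by at least one cube; voxels covered exactly
    once take that cube's value unchanged.
    """
    if len(cubes) != len(positions):
        raise ParameterError("cubes and positions must pair up")
    if not cubes:
        raise ParameterError("no cubes to reassemble")
    s = cubes[0].shape[0]
    if any(c.shape != (s, s, s) for c in cubes):
        raise ParameterError("all cubes must share one cubic shape")
    _check_positions(positions, s, out_shape)
    acc = np.zeros(out_shape, dtype=np.float64)
    cnt = np.zeros(out_shape, dtype=np.int64)
    for cube, p in zip(cubes, positions):
        sl = (slice(p.z0, p.z0 + s), slice(p.y0, p.y0 + s), slice(p.x0, p.x0 + s))
        acc[sl] += cube
        cnt[sl] += 1
    if cnt.min() == 0:
        raise ParameterError("grid does not cover the volume")
    single = cnt == 1
    out = (acc / cnt).astype(np.float32)
    # voxels covered once must be bit-identical to their cube
    out[single] = acc[single].astype(np.float32)
    return Volume(out)
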