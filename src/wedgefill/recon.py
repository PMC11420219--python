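"""Tilt-series splitting and filtered back-projection.

The even/odd split partitions a tilt series by acquisition order into two
sub-series with disjoint angles and independent noise; the frame-based split
averages even and odd movie frames at each tilt, so both halves keep the
full angular sampling.  Either pair of halves is reconstructed with
stacked-2D filtered back-projection (single-axis geometry: each y-slice of
the tomogram depends only on the matching row of every projection).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .core import ParameterError, TiltScheme, TiltSeries, Volume

__all__ = ["SplitPair", "split_even_odd", "split_frames", "fbp"]

FilterKind = Literal["ramp", "hamming"]


@dataclass
class SplitPair:
    half0: TiltSeries
    half1: TiltSeries
    mode: Literal["even_odd", "frame_based"]


def split_even_odd(ts: TiltSeries) -> SplitPair:
    """Partition a tilt series into even- and odd-index acquisitions."""
    if len(ts) < 2:
        raise ParameterError("need at least two projections to split")
    angles = np.asarray(ts.scheme.angles_deg)
    h0 = TiltSeries(ts.images[0::2], TiltScheme(tuple(angles[0::2])), ts.pixel_size_A)
    h1 = TiltSeries(ts.images[1::2], TiltScheme(tuple(angles[1::2])), ts.pixel_size_A)
    return SplitPair(h0, h1, "even_odd")


def split_frames(frames: np.ndarray, scheme: TiltScheme,
                 pixel_size_A: float = 1.0) -> SplitPair:
    """Average even/odd movie frames at each tilt into two half series.

    ``frames`` has shape ``(P, F, ny, nx)`` with ``F >= 2`` frames per tilt.
    Both halves keep the full tilt scheme.
    """
    frames = np.asarray(frames, dtype=np.float32)
    if frames.ndim != 4:
        raise ParameterError("frames must have shape (P, F, ny, nx)")
    if frames.shape[0] != len(scheme):
        raise ParameterError("frame stack count must match the tilt scheme")
    if frames.shape[1] < 2:
        raise ParameterError("every tilt needs at least two frames")
    h0 = frames[:, 0::2].mean(axis=1)
    h1 = frames[:, 1::2].mean(axis=1)
    return SplitPair(TiltSeries(h0, scheme, pixel_size_A),
                     TiltSeries(h1, scheme, pixel_size_A), "frame_based")


def _filter_rows(images: np.ndarray, kind: FilterKind) -> np.ndarray:
    """Apply a 1D frequency filter along the x axis of every projection row."""
    n = images.shape[-1]
    npad = 2 * n  # zero-padding suppresses wrap-around of the ramp
    freqs = np.fft.fftfreq(npad)
    resp = np.abs(freqs)
    if kind == "hamming":
        f_nyq = 0.5
        resp = resp * (0.54 + 0.46 * np.cos(np.pi * freqs / f_nyq))
    elif kind != "ramp":
        raise ParameterError(f"unknown filter kind: {kind!r}")
    spec = np.fft.fft(images, n=npad, axis=-1)
    out = np.fft.ifft(spec * resp, axis=-1).real[..., :n]
    return out.astype(np.float32)


def fbp(ts: TiltSeries, out_shape: tuple[int, int, int],
        filter_kind: FilterKind = "ramp") -> Volume:
    """Filtered back-projection of a single-axis tilt series.

    ``out_shape`` is (nz, ny, nx); ny and nx must match the projection
    images.  The output is scaled by the classical ``pi / (2 K)``
    normalization so a dense full-range scheme approximates the original
    intensity scale.
    """
    nz, ny, nx = out_shape
    if (ny, nx) != ts.images.shape[1:]:
        raise ParameterError("out_shape (ny, nx) must match the projection images")
    filtered = _filter_rows(ts.images, filter_kind)

    cz, cx = (nz - 1) / 2.0, (nx - 1) / 2.0
    z = np.arange(nz, dtype=np.float32)[:, None] - cz
    x = np.arange(nx, dtype=np.float32)[None, :] - cx
    recon = np.zeros(out_shape, dtype=np.float32)
    for k, alpha in enumerate(ts.scheme.angles_deg):
        a = np.deg2rad(alpha)
        # detector coordinate of voxel (z, x); inverse of the projector rays
        u = x * np.cos(a) - z * np.sin(a) + cx
        u0 = np.floor(u).astype(np.int64)
        w = (u - u0).astype(np.float32)
        valid0 = (u0 >= 0) & (u0 <= nx - 1)
        valid1 = (u0 + 1 >= 0) & (u0 + 1 <= nx - 1)
        i0 = np.clip(u0, 0, nx - 1)
        i1 = np.clip(u0 + 1, 0, nx - 1)
        rows = filtered[k]  # (ny, nx)
        contrib = (rows[:, i0] * np.where(valid0, 1.0 - w, 0.0)[None]
                   + rows[:, i1] * np.where(valid1, w, 0.0)[None])
        recon += contrib.transpose(1, 0, 2)  # (ny, nz, nx) -> (nz, ny, nx)
    # angular-spacing normalization: a dense full-range scheme then
    # approximates the original intensity scale
    angles = np.asarray(ts.scheme.angles_deg, dtype=np.float64)
    if len(angles) > 1:
        dalpha = np.deg2rad((angles[-1] - angles[0]) / (len(angles) - 1))
    else:
        dalpha = np.pi
    recon *= np.float32(dalpha)
    return Volume(recon, ts.pixel_size_A)
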