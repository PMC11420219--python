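"""Evaluation metrics: correlation coefficients and Fourier shell correlation.

The normalized correlation coefficient is the mean-subtracted inner product
over the product of norms.  Wedge-restricted variants apply a missing-wedge
filter before correlating (isolating denoising performance) or restrict the
FSC shell sums to wedge voxels (isolating inpainting performance).  The
0.143 FSC crossing converts to a resolution in Angstroms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import ParameterError, Volume
from .fourier import apply_mask, wedge_mask

__all__ = ["FSCCurve", "cc", "cc_outside_wedge", "fsc", "fsc_resolution",
           "fsc_inside_wedge"]


@dataclass
class FSCCurve:
    """Shell-wise correlation: ``freqs`` in cycles/voxel (up to Nyquist 0.5),
    ``values`` per shell with NaN marking empty/undefined shells."""

    freqs: np.ndarray
    values: np.ndarray
    voxel_size_A: float = 1.0

    def __post_init__(self) -> None:
        if len(self.freqs) != len(self.values):
            raise ParameterError("freqs and values must align")


def _as_array(v: Volume | np.ndarray) -> np.ndarray:
    return v.data if isinstance(v, Volume) else np.asarray(v)


def cc(a: Volume | np.ndarray, b: Volume | np.ndarray) -> float:
    """Normalized correlation coefficient between two volumes."""
    x = _as_array(a).astype(np.float64).ravel()
    y = _as_array(b).astype(np.float64).ravel()
    if x.shape != y.shape:
        raise ParameterError("volumes must share a shape")
    x = x - x.mean()
    y = y - y.mean()
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0 or ny == 0:
        raise ParameterError("correlation undefined for constant volumes")
    return float(np.dot(x, y) / (nx * ny))


def cc_outside_wedge(a: Volume | np.ndarray, b: Volume | np.ndarray,
                     alpha_max_deg: float) -> float:
    """CC after applying the same missing-wedge filter to both volumes."""
    av = a if isinstance(a, Volume) else Volume(np.asarray(a))
    bv = b if isinstance(b, Volume) else Volume(np.asarray(b))
    mask = wedge_mask(av.shape, alpha_max_deg)
    return cc(apply_mask(av, mask), apply_mask(bv, mask))


def _shell_index(shape: tuple[int, int, int]) -> np.ndarray:
    grids = np.meshgrid(*((np.arange(n) - n // 2) for n in shape), indexing="ij")
    r = np.sqrt(sum(g.astype(np.float64) ** 2 for g in grids))
    return np.rint(r).astype(np.int64)


def _fsc_from_spectra(fa: np.ndarray, fb: np.ndarray, shells: np.ndarray,
                      n_shells: int, weights: np.ndarray | None,
                      voxel_size_A: float) -> FSCCurve:
    flat = shells.ravel()
    cross = (fa * np.conj(fb)).real.ravel()
    pa = (np.abs(fa) ** 2).ravel()
    pb = (np.abs(fb) ** 2).ravel()
    total_a, total_b = float(pa.sum()), float(pb.sum())
    if weights is not None:
        w = weights.ravel()
        cross, pa, pb = cross * w, pa * w, pb * w
        counts = np.bincount(flat, weights=w, minlength=n_shells)[:n_shells]
    else:
        counts = np.bincount(flat, minlength=n_shells)[:n_shells]
    num = np.bincount(flat, weights=cross, minlength=n_shells)[:n_shells]
    da = np.bincount(flat, weights=pa, minlength=n_shells)[:n_shells]
    db = np.bincount(flat, weights=pb, minlength=n_shells)[:n_shells]
    values = np.full(n_shells, np.nan)
    # shells whose denominator energy is numerical residue relative to the
    # volume's full spectrum are undefined, e.g. a zeroed-out wedge
    tiny = np.finfo(np.float64).tiny
    ok = ((counts > 0) & (da > 1e-12 * max(total_a, tiny))
          & (db > 1e-12 * max(total_b, tiny)))
    values[ok] = num[ok] / np.sqrt(da[ok] * db[ok])
    n = min(fa.shape)
    freqs = np.arange(n_shells, dtype=np.float64) / n
    return FSCCurve(freqs, values, voxel_size_A)


def fsc(a: Volume | np.ndarray, b: Volume | np.ndarray) -> FSCCurve:
    """Fourier shell correlation with shell width 1 frequency voxel."""
    x = _as_array(a)
    y = _as_array(b)
    if x.shape != y.shape or len(set(x.shape)) != 1:
        raise ParameterError("fsc requires two cubic volumes of equal shape")
    vox = a.voxel_size_A if isinstance(a, Volume) else 1.0
    fa = np.fft.fftshift(np.fft.fftn(x))
    fb = np.fft.fftshift(np.fft.fftn(y))
    shells = _shell_index(x.shape)
    n_shells = x.shape[0] // 2 + 1
    shells = np.minimum(shells, n_shells)  # bin Nyquist-corner excess together
    curve = _fsc_from_spectra(fa, fb, shells, n_shells, None, vox)
    return curve


def fsc_inside_wedge(a: Volume | np.ndarray, b: Volume | np.ndarray,
                     alpha_max_deg: float) -> FSCCurve:
    """FSC with shell sums restricted to missing-wedge Fourier voxels."""
    x = _as_array(a)
    y = _as_array(b)
    if x.shape != y.shape or len(set(x.shape)) != 1:
        raise ParameterError("fsc requires two cubic volumes of equal shape")
    vox = a.voxel_size_A if isinstance(a, Volume) else 1.0
    mask = wedge_mask(x.shape, alpha_max_deg)
    fa = np.fft.fftshift(np.fft.fftn(x))
    fb = np.fft.fftshift(np.fft.fftn(y))
    shells = _shell_index(x.shape)
    n_shells = x.shape[0] // 2 + 1
    shells = np.minimum(shells, n_shells)
    return _fsc_from_spectra(fa, fb, shells, n_shells, mask.complement(), vox)


def fsc_resolution(curve: FSCCurve, threshold: float = 0.143) -> float:
    """Resolution (A) at the first shell whose FSC drops below ``threshold``.

    Identical volumes never cross, giving the Nyquist resolution
    ``2 * voxel size``.
    """
    for freq, value in zip(curve.freqs[1:], curve.values[1:]):
        if math.isnan(value):
            continue
        if value < threshold:
            return float(curve.voxel_size_A / freq)
    return float(2.0 * curve.voxel_size_A)
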