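"""Synthetic single-axis tilt-series simulator.

Implements the CTF-free parallel-beam forward model used for all desk-scale
experiments: a projection at tilt angle alpha is the line integral of the
volume along the beam after rotating the sample by alpha about the tilt (y)
axis.  In Fourier space each projection is a central slice of the volume's
3D transform, which is what limited tilt ranges turn into a missing wedge.

Noise is pixel-wise independent zero-mean Gaussian.  The SNR convention is

    SNR = Var(clean projection stack, pooled) / Var(noise),

so e.g. ``snr=0.25`` adds noise with four times the pooled signal variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import ParameterError, TiltScheme, TiltSeries, Volume

__all__ = [
    "PhantomSpec",
    "make_tilt_scheme",
    "make_phantom",
    "project",
    "add_noise",
    "simulate_frames",
]


def make_tilt_scheme(min_deg: float, max_deg: float, step_deg: float) -> TiltScheme:
    """Uniform tilt scheme ``min, min+step, ...`` inclusive of ``max``.

    The endpoint is included when ``max - min`` is an integer multiple of
    ``step`` (e.g. -60..+60 at 3 deg gives 41 angles).
    """
    if step_deg <= 0:
        raise ParameterError("step_deg must be positive")
    if not min_deg < max_deg:
        raise ParameterError("min_deg must be smaller than max_deg")
    n = int(np.floor((max_deg - min_deg) / step_deg + 1e-9)) + 1
    angles = min_deg + step_deg * np.arange(n)
    return TiltScheme(tuple(angles.tolist()))


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for a random geometric phantom: spheres, rods and shells on a
    zero background, kept inside a margin so that rotations up to ~70 deg do
    not push content out of the field of view."""

    shape: tuple[int, int, int] = (64, 96, 96)
    n_spheres: int = 12
    n_rods: int = 4
    n_shells: int = 3
    intensity_range: tuple[float, float] = (0.5, 1.0)
    radius_range: tuple[float, float] = (3.0, 8.0)
    margin_fraction: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_spheres, self.n_rods, self.n_shells) < 0:
            raise ParameterError("object counts must be >= 0")
        if min(self.shape) < 8:
            raise ParameterError("phantom dimensions must all be >= 8")


def make_phantom(spec: PhantomSpec) -> Volume:
    """Deterministic (per seed) random phantom volume."""
    rng = np.random.default_rng(spec.seed)
    shape = spec.shape
    data = np.zeros(shape, dtype=np.float32)
    zz, yy, xx = np.meshgrid(*(np.arange(n, dtype=np.float32) for n in shape),
                             indexing="ij")

    margins = [max(2.0, spec.margin_fraction * n) for n in shape]
    max_r = min(spec.radius_range[1], min(shape) / 2.0 - max(margins))
    if spec.n_spheres + spec.n_rods + spec.n_shells > 0 and max_r < 1.0:
        raise ParameterError("phantom shape too small for the requested objects")
    r_lo = min(spec.radius_range[0], max_r)

    def _center() -> np.ndarray:
        return np.array([rng.uniform(m + max_r, n - m - max_r)
                         for n, m in zip(shape, margins)])

    def _intensity() -> float:
        return float(rng.uniform(*spec.intensity_range))

    for _ in range(spec.n_spheres):
        c, r, a = _center(), rng.uniform(r_lo, max_r), _intensity()
        d2 = (zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2
        data[d2 <= r * r] += a

    for _ in range(spec.n_rods):
        c, a = _center(), _intensity()
        r = rng.uniform(1.5, max(1.5, 0.4 * max_r))
        length = rng.uniform(2 * max_r, 4 * max_r)
        axis = rng.standard_normal(3)
        axis /= np.linalg.norm(axis)
        rel = np.stack([zz - c[0], yy - c[1], xx - c[2]])
        t = np.einsum("i,i...->...", axis, rel)
        d2 = np.sum(rel * rel, axis=0) - t * t
        data[(d2 <= r * r) & (np.abs(t) <= length / 2)] += a

    for _ in range(spec.n_shells):
        c, a = _center(), _intensity()
        r = rng.uniform(max(2.0, 0.6 * max_r), max_r)
        thick = rng.uniform(1.0, 2.0)
        d = np.sqrt((zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2)
        data[np.abs(d - r) <= thick / 2] += a

    return Volume(data)


def project(vol: Volume, scheme: TiltScheme) -> TiltSeries:
    """Parallel-beam projections of ``vol`` for every angle in ``scheme``.

    Image k is the sum along the beam (z) axis of the volume rotated by
    ``-alpha_k`` about the tilt (y) axis, i.e. the line integral along rays
    at angle ``alpha_k`` in the (z, x) plane.  Linear in the input; trilinear
    interpolation with zero fill outside the grid.
    """
    if len(scheme) == 0:  # pragma: no cover - TiltScheme forbids this
        raise ParameterError("empty tilt scheme")
    if any(abs(a) >= 90.0 for a in scheme.angles_deg):
        raise ParameterError("projection angles must lie in (-90, 90)")
    data = vol.data.astype(np.float32)
    nz, ny, nx = data.shape
    center = np.array([(nz - 1) / 2.0, (nx - 1) / 2.0])
    images = np.empty((len(scheme), ny, nx), dtype=np.float32)
    for k, alpha in enumerate(scheme.angles_deg):
        a = np.deg2rad(alpha)
        ca, sa = np.cos(a), np.sin(a)
        # output coords (t, u): input z = t*ca - u*sa, x = t*sa + u*ca
        mat = np.array([[ca, 0.0, -sa], [0.0, 1.0, 0.0], [sa, 0.0, ca]])
        full_center = np.array([(nz - 1) / 2.0, 0.0, (nx - 1) / 2.0])
        offset = full_center - mat @ full_center
        rot = ndimage.affine_transform(data, mat, offset=offset, order=1,
                                       mode="constant", cval=0.0,
                                       output=np.float32)
        images[k] = rot.sum(axis=0)
    return TiltSeries(images, scheme, vol.voxel_size_A)


def add_noise(ts: TiltSeries, snr: float, seed: int) -> TiltSeries:
    """Add pixel-wise i.i.d. zero-mean Gaussian noise at the requested SNR.

    Noise variance is ``Var(clean stack) / snr`` with the variance pooled
    over the whole projection stack.  Deterministic per seed; different
    seeds give independent noise realizations.
    """
    if snr <= 0:
        raise ParameterError("snr must be positive")
    rng = np.random.default_rng(seed)
    sigma = float(np.std(ts.images)) / np.sqrt(snr)
    noisy = ts.images + rng.standard_normal(ts.images.shape).astype(np.float32) * sigma
    return TiltSeries(noisy, ts.scheme, ts.pixel_size_A)


def simulate_frames(ts: TiltSeries, snr: float, n_frames: int, seed: int) -> np.ndarray:
    """Per-tilt dose-fractionated frames whose average has the requested SNR.

    Returns an array of shape ``(P, n_frames, ny, nx)``.  Each frame carries
    ``n_frames`` times the per-tilt noise variance, so averaging the frames
    of a tilt reproduces the single-exposure noise level.
    """
    if snr <= 0:
        raise ParameterError("snr must be positive")
    if n_frames < 2:
        raise ParameterError("need at least two frames per tilt")
    rng = np.random.default_rng(seed)
    sigma_frame = float(np.std(ts.images)) / np.sqrt(snr) * np.sqrt(n_frames)
    shape = (len(ts), n_frames) + ts.images.shape[1:]
    noise = rng.standard_normal(shape).astype(np.float32) * sigma_frame
    return ts.images[:, None] + noise
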