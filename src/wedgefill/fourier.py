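"""Fourier-domain machinery: wedge masks, rotations, mask application.

With the tilt axis along y and the beam along z, a tilt range limited to
``|alpha| <= alpha_max`` leaves the Fourier region

    |k_z| > tan(alpha_max) * |k_x|

unmeasured (independent of k_y): the missing wedge.  Masks are binary,
fftshift-centered (DC at the center voxel) and point-symmetric so that
masking keeps real volumes real.  Boundary points with
``|k_z| = tan(alpha_max)|k_x|`` count as measured.

Rotated wedge masks are evaluated analytically on rotated frequency
coordinates rather than by resampling a binary grid, which would smear the
discontinuity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation

from .core import ParameterError, Volume

__all__ = [
    "EulerAngles",
    "WedgeMask",
    "wedge_mask",
    "rotated_wedge_mask",
    "apply_mask",
    "sample_rotation",
    "rotate_volume",
]


@dataclass(frozen=True)
class EulerAngles:
    """Intrinsic z-y-z Euler angles in radians."""

    phi1: float
    theta: float
    phi2: float

    @classmethod
    def identity(cls) -> "EulerAngles":
        return cls(0.0, 0.0, 0.0)

    def as_matrix_xyz(self) -> np.ndarray:
        """Rotation matrix acting on (x, y, z) coordinate vectors."""
        return Rotation.from_euler("ZYZ", [self.phi1, self.theta, self.phi2]).as_matrix()

    def as_matrix_zyx(self) -> np.ndarray:
        """Same rotation expressed in (z, y, x) index coordinates."""
        p = np.array([[0, 0, 1], [0, 1, 0], [1, 0, 0]], dtype=float)
        return p @ self.as_matrix_xyz() @ p


@dataclass
class WedgeMask:
    """Binary, fftshift-centered 3D Fourier mask (1 = measured)."""

    data: np.ndarray
    alpha_max_deg: float
    orientation: EulerAngles

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def complement(self) -> np.ndarray:
        return 1.0 - self.data


def _centered_freq_grids(shape: tuple[int, int, int]) -> tuple[np.ndarray, ...]:
    # fftshift-centered integer frequency indices; DC sits at n // 2
    return tuple(
        (np.arange(n) - n // 2).astype(np.float64).reshape(
            [-1 if i == j else 1 for j in range(3)]
        )
        for i, n in enumerate(shape)
    )


def _wedge_measured(kz: np.ndarray, kx: np.ndarray, alpha_max_deg: float) -> np.ndarray:
    t = np.tan(np.deg2rad(alpha_max_deg))
    return np.abs(kz) <= t * np.abs(kx) + 1e-9


def wedge_mask(shape: tuple[int, int, int], alpha_max_deg: float) -> WedgeMask:
    """Missing-wedge mask for a tilt range of ``+/- alpha_max_deg``."""
    if not 0.0 < alpha_max_deg < 90.0:
        raise ParameterError("alpha_max_deg must lie in (0, 90)")
    kz, _, kx = _centered_freq_grids(shape)
    data = _wedge_measured(kz + np.zeros(shape), np.zeros(shape) + kx,
                           alpha_max_deg).astype(np.float32)
    return WedgeMask(data, alpha_max_deg, EulerAngles.identity())


def rotated_wedge_mask(shape: tuple[int, int, int], alpha_max_deg: float,
                       phi: EulerAngles) -> WedgeMask:
    """Wedge mask rotated by ``phi``: the wedge inequality evaluated at
    ``R_phi^{-1} k`` (identity rotation reproduces :func:`wedge_mask`
    bit-for-bit)."""
    if not 0.0 < alpha_max_deg < 90.0:
        raise ParameterError("alpha_max_deg must lie in (0, 90)")
    kz, ky, kx = _centered_freq_grids(shape)
    rot_inv = phi.as_matrix_zyx().T  # orthogonal
    kz_r = rot_inv[0, 0] * kz + rot_inv[0, 1] * ky + rot_inv[0, 2] * kx
    kx_r = rot_inv[2, 0] * kz + rot_inv[2, 1] * ky + rot_inv[2, 2] * kx
    data = _wedge_measured(kz_r, kx_r, alpha_max_deg).astype(np.float32)
    return WedgeMask(data, alpha_max_deg, phi)


def _apply_mask_array(data: np.ndarray, mask: np.ndarray) -> np.ndarray:
    spec = np.fft.fftn(data)
    spec *= np.fft.ifftshift(mask)
    return np.fft.ifftn(spec).real.astype(np.float32)


def apply_mask(vol: Volume, mask: WedgeMask) -> Volume:
    """Real part of ``F^-1 (mask * F vol)``; idempotent for binary masks."""
    if vol.shape != mask.shape:
        raise ParameterError("volume and mask shapes differ")
    return Volume(_apply_mask_array(vol.data, mask.data), vol.voxel_size_A)


def sample_rotation(rng: np.random.Generator) -> EulerAngles:
    """Haar-uniform rotation on SO(3) as intrinsic z-y-z Euler angles."""
    rot = Rotation.random(rng=rng)
    a = rot.as_euler("ZYZ")
    return EulerAngles(float(a[0]), float(a[1]), float(a[2]))


def rotate_volume(vol: Volume, phi: EulerAngles, fill: str = "mean") -> Volume:
    """Rotate a cubic volume about its center (trilinear resampling).

    ``fill`` controls out-of-cube samples: ``"mean"`` uses the volume mean,
    ``"zero"`` uses 0.
    """
    s = vol.shape
    if not (s[0] == s[1] == s[2]):
        raise ParameterError("rotate_volume requires a cubic volume")
    if fill == "mean":
        cval = float(vol.data.mean())
    elif fill == "zero":
        cval = 0.0
    else:
        raise ParameterError(f"unknown fill mode: {fill!r}")
    mat = phi.as_matrix_zyx().T  # output -> input coordinates
    center = (np.asarray(s, dtype=float) - 1.0) / 2.0
    offset = center - mat @ center
    out = ndimage.affine_transform(vol.data, mat, offset=offset, order=1,
                                   mode="constant", cval=cval, output=np.float32)
    return Volume(out, vol.voxel_size_A)
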