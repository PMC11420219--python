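"""Core containers shared by every stage of the pipeline.

A tomogram (or sub-tomogram) is a real-valued 3D grid indexed ``(z, y, x)``
with the optical/beam axis along ``z`` and the tilt axis along ``y``; a tilt
series is an ordered stack of ``(y, x)`` projection images together with its
tilt scheme (angles in degrees about the tilt axis).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class ParameterError(ValueError):
    """Raised when an operation is called with invalid parameters."""


@dataclass(frozen=True)
class TiltScheme:
    """Ordered set of tilt angles, in degrees, about the y (tilt) axis."""

    angles_deg: tuple[float, ...]

    def __post_init__(self) -> None:
        angles = tuple(float(a) for a in self.angles_deg)
        if len(angles) == 0:
            raise ParameterError("tilt scheme must contain at least one angle")
        if any(abs(a) > 90.0 for a in angles):
            raise ParameterError("tilt angles must satisfy |angle| <= 90 deg")
        if any(b <= a for a, b in zip(angles, angles[1:])):
            raise ParameterError("tilt angles must be strictly increasing")
        object.__setattr__(self, "angles_deg", angles)

    def __len__(self) -> int:
        return len(self.angles_deg)


@dataclass
class TiltSeries:
    """Stack of 2D projections, one per tilt angle, as a (P, ny, nx) array."""

    images: np.ndarray
    scheme: TiltScheme
    pixel_size_A: float = 1.0

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=np.float32)
        if self.images.ndim != 3:
            raise ParameterError("tilt series images must form a (P, ny, nx) stack")
        if len(self.images) != len(self.scheme):
            raise ParameterError(
                f"{len(self.images)} images but {len(self.scheme)} tilt angles"
            )
        if self.pixel_size_A <= 0:
            raise ParameterError("pixel size must be positive")
        if not np.all(np.isfinite(self.images)):
            raise ParameterError("tilt series contains non-finite values")

    def __len__(self) -> int:
        return len(self.images)


@dataclass
class Volume:
    """Real-valued 3D grid indexed (z, y, x) with an isotropic voxel size."""

    data: np.ndarray
    voxel_size_A: float = 1.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ParameterError("volume data must be 3D")
        if min(self.data.shape) < 1:
            raise ParameterError("volume dimensions must all be >= 1")
        if self.voxel_size_A <= 0:
            raise ParameterError("voxel size must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ParameterError("volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def copy(self) -> "Volume":
        return Volume(self.data.copy(), self.voxel_size_A)


@dataclass(frozen=True)
class GridPosition:
    """Corner offsets (z0, y0, x0) of a cubic window, 0-based, half-open."""

    z0: int
    y0: int
    x0: int

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.z0, self.y0, self.x0)


@dataclass
class SubTomoPair:
    """Two same-position cubic sub-tomograms with independent noise.

    ``v0`` is mutable (its missing wedge is refreshed during fitting);
    ``v1`` is treated as immutable.  ``norm_stats`` holds the (mean, std)
    used to standardize both cubes, computed from ``v0``.
    """

    v0: np.ndarray
    v1: np.ndarray
    pos: GridPosition
    norm_stats: tuple[float, float] = field(default=(0.0, 1.0))

    def __post_init__(self) -> None:
        if self.v0.shape != self.v1.shape:
            raise ParameterError("sub-tomogram pair members must share a shape")
        s = self.v0.shape
        if not (s[0] == s[1] == s[2]):
            raise ParameterError("sub-tomograms must be cubic")
        if self.norm_stats[1] <= 0:
            raise ParameterError("standardization std must be positive")
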