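"""MRC volume/stack and IMOD-dialect .tlt angle-file I/O (via gemmi).

Volumes are written as MRC2014/CCP4 float32 maps with the voxel size
encoded in the unit cell; tilt-series stacks are stored as 3D maps with the
projection index along the first axis.  Angle files hold one angle in
degrees per line.
"""

from __future__ import annotations

from pathlib import Path

import gemmi
import numpy as np

from .core import ParameterError, TiltScheme, TiltSeries, Volume

__all__ = ["read_mrc", "write_mrc", "read_tlt", "write_tlt",
           "read_tilt_series", "write_tilt_series"]


def write_mrc(path: str | Path, data: np.ndarray, voxel_size_A: float = 1.0) -> None:
    arr = np.ascontiguousarray(np.asarray(data, dtype=np.float32))
    if arr.ndim != 3:
        raise ParameterError("MRC writer expects a 3D array")
    mrc = gemmi.Ccp4Map()
    mrc.grid = gemmi.FloatGrid(arr)
    mrc.grid.unit_cell = gemmi.UnitCell(
        arr.shape[0] * voxel_size_A, arr.shape[1] * voxel_size_A,
        arr.shape[2] * voxel_size_A, 90.0, 90.0, 90.0)
    mrc.update_ccp4_header()
    mrc.write_ccp4_map(str(path))


def read_mrc(path: str | Path) -> tuple[np.ndarray, float]:
    """Returns (data, voxel_size_A)."""
    mrc = gemmi.read_ccp4_map(str(path))
    data = np.array(mrc.grid, copy=True).astype(np.float32)
    cell = mrc.grid.unit_cell
    voxel = cell.a / data.shape[0] if data.shape[0] else 1.0
    return data, float(voxel)


def write_volume(path: str | Path, vol: Volume) -> None:
    write_mrc(path, vol.data, vol.voxel_size_A)


def read_volume(path: str | Path) -> Volume:
    data, voxel = read_mrc(path)
    return Volume(data, voxel)


def write_tlt(path: str | Path, scheme: TiltScheme) -> None:
    Path(path).write_text("".join(f"{a:.2f}\n" for a in scheme.angles_deg))


def read_tlt(path: str | Path) -> TiltScheme:
    angles = [float(line) for line in Path(path).read_text().split()]
    return TiltScheme(tuple(angles))


def write_tilt_series(mrc_path: str | Path, tlt_path: str | Path,
                      ts: TiltSeries) -> None:
    write_mrc(mrc_path, ts.images, ts.pixel_size_A)
    write_tlt(tlt_path, ts.scheme)


def read_tilt_series(mrc_path: str | Path, tlt_path: str | Path) -> TiltSeries:
    data, voxel = read_mrc(mrc_path)
    scheme = read_tlt(tlt_path)
    return TiltSeries(data, scheme, voxel)
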