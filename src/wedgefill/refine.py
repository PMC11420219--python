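"""Final tomogram refinement.

Applies the fitted model to the *original* (never wedge-updated)
sub-tomograms of both half-reconstructions, reassembles each half with
overlap averaging, and averages the two results.  Cubes are standardized
before the model and de-standardized after, so the output stays on the
intensity scale of the inputs.
"""

from __future__ import annotations

import numpy as np

from .core import ParameterError, Volume
from .model import UNet3D
from .subtomo import plan_grid, reassemble

__all__ = ["refine_tomogram"]


def _refine_half(vol: Volume, model: UNet3D, positions, cube_size: int,
                 batch_size: int) -> Volume:
    cubes = []
    s = cube_size
    for p in positions:
        c = vol.data[p.z0:p.z0 + s, p.y0:p.y0 + s, p.x0:p.x0 + s]
        cubes.append(np.asarray(c, dtype=np.float32))
    out_cubes: list[np.ndarray] = []
    for start in range(0, len(cubes), batch_size):
        batch = cubes[start:start + batch_size]
        mu = np.array([c.mean() for c in batch], dtype=np.float32)
        sd = np.array([c.std() or 1.0 for c in batch], dtype=np.float32)
        x = (np.stack(batch) - mu[:, None, None, None]) / sd[:, None, None, None]
        y = model.forward(x, train=False)
        y = y * sd[:, None, None, None] + mu[:, None, None, None]
        out_cubes.extend(np.asarray(y, dtype=np.float32))
    return reassemble(out_cubes, positions, vol.shape)


def refine_tomogram(vol0: Volume, vol1: Volume, model: UNet3D, cube_size: int,
                    overlap: int, batch_size: int = 4) -> Volume:
    """Denoised, wedge-filled tomogram from the two half-reconstructions.

    The grid covers the full volume (no content filtering) and the output
    is the symmetric average of the two refined halves.
    """
    if vol0.shape != vol1.shape:
        raise ParameterError("half-volumes must share a shape")
    positions = plan_grid(vol0.shape, cube_size, overlap)
    r0 = _refine_half(vol0, model, positions, cube_size, batch_size)
    r1 = _refine_half(vol1, model, positions, cube_size, batch_size)
    return Volume((r0.data + r1.data) / 2.0, vol0.voxel_size_A)
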