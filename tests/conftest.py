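import numpy as np
import pytest

from wedgefill import (PhantomSpec, TiltScheme, Volume, add_noise, cc,
                       make_phantom, make_tilt_scheme, project,
                       split_even_odd)
from wedgefill.estimator import MissingWedgeRestorer
from wedgefill.recon import fbp


@pytest.fixture(scope="session")
def blob_volume() -> Volume:
    """Smooth sum-of-Gaussians phantom, 48^3 (fast, differentiable content)."""
    rng = np.random.default_rng(0)
    zz, yy, xx = np.meshgrid(*(np.arange(48),) * 3, indexing="ij")
    blob = np.zeros((48, 48, 48))
    for _ in range(5):
        c = rng.uniform(16, 32, 3)
        s = rng.uniform(2, 4)
        blob += np.exp(-(((zz - c[0]) ** 2 + (yy - c[1]) ** 2
                          + (xx - c[2]) ** 2) / (2 * s * s)))
    return Volume(blob.astype(np.float32))


@pytest.fixture(scope="session")
def desk_run():
    """The pinned desk-scale end-to-end study.

    Phantom 64x96x96, +/-60 deg tilt range at 2 deg increments, pixel-wise
    Gaussian noise at SNR 1/4, even/odd split, ramp-filtered back-projection,
    32-voxel cubes, 16-channel two-level network, 30 epochs at the default
    learning rate, all seeds fixed.  Session-scoped: this is the expensive
    fixture every end-to-end assertion shares.
    """
    phantom = make_phantom(PhantomSpec(shape=(64, 96, 96), seed=7))
    scheme = make_tilt_scheme(-60, 60, 2)
    noisy = add_noise(project(phantom, scheme), snr=0.25, seed=8)
    halves = split_even_odd(noisy)
    shape = (64, 96, 96)
    v0 = fbp(halves.half0, shape, "ramp")
    v1 = fbp(halves.half1, shape, "ramp")
    fbp_full = fbp(noisy, shape, "ramp")

    est = MissingWedgeRestorer(
        alpha_max_deg=60.0, cube_size=32, overlap=0, epochs=30, batch_size=4,
        learning_rate=4e-4, seed=11, base_channels=16, depth=2,
        convs_per_stage=2, head_convs=0)
    refined = est.fit_transform(v0, v1)
    return {
        "phantom": phantom, "v0": v0, "v1": v1, "fbp_full": fbp_full,
        "refined": refined, "estimator": est, "history": est.history_,
        "model": est.model_,
    }
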