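"""Self-supervised fitting loop for joint denoising and wedge inpainting.

Each epoch: (1) draw a fresh Haar-uniform rotation per sub-tomogram pair and
build a model input by rotating the (wedge-updated) ``v0`` cube and zeroing
an artificial missing wedge with the fixed mask M, and a target by rotating
the ``v1`` cube; (2) run one full Adam pass over the pairs, minimizing the
masked Fourier loss

    l = || (M M_phi + 2 M^C M_phi) F (f(input) - target) ||^2

where ``M_phi`` is the wedge mask rotated along with the cubes and
``M^C = I - M``; (3) refresh the missing wedge of every ``v0`` cube with the
current model's prediction, keeping the measured region untouched.

The two summands of the loss act on orthogonal Fourier supports: the first
(overlap of both measured regions) is a noise-to-noise term that drives
denoising; the second (artificially removed but originally measured, with
weight 2 inside the squared norm) is the inpainting term that teaches the
network to fill wedges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import ParameterError, SubTomoPair, Volume
from .fourier import (EulerAngles, WedgeMask, _apply_mask_array,
                      rotated_wedge_mask, rotate_volume, sample_rotation,
                      wedge_mask)
from .model import UNet3D, UNetConfig, build_unet
from .nn import Adam

__all__ = ["FitConfig", "FitHistory", "make_epoch_samples", "per_sample_loss",
           "loss_and_input_grad", "update_wedges", "fit"]


@dataclass(frozen=True)
class FitConfig:
    """Hyperparameters of the fitting loop (defaults follow the reference
    training regime: Adam at a constant 4e-4, no dropout, per-epoch wedge
    updates)."""

    alpha_max_deg: float = 60.0
    cube_size: int = 96
    epochs: int = 100
    batch_size: int = 8
    learning_rate: float = 4e-4
    dropout_p: float = 0.0
    seed: int = 0
    wedge_update: bool = True
    rotation_fill: str = "mean"
    validation_fraction: float = 0.0
    unet: UNetConfig | None = None

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ParameterError("learning_rate must be >= 0")
        if self.epochs < 1:
            raise ParameterError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ParameterError("batch_size must be >= 1")
        if not 0.0 <= self.validation_fraction < 1.0:
            raise ParameterError("validation_fraction must lie in [0, 1)")


@dataclass
class FitHistory:
    """Per-epoch mean training loss (and validation loss when held out)."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)


def make_epoch_samples(pairs: list[SubTomoPair], mask: WedgeMask,
                       rng: np.random.Generator, fill: str = "mean",
                       ) -> list[tuple[np.ndarray, np.ndarray, EulerAngles]]:
    """Rotated, wedge-corrupted (input, target, phi) triplets, one per pair."""
    out = []
    for pair in pairs:
        phi = sample_rotation(rng)
        v0r = rotate_volume(Volume(pair.v0), phi, fill=fill).data
        v1r = rotate_volume(Volume(pair.v1), phi, fill=fill).data
        inp = _apply_mask_array(v0r, mask.data)
        out.append((inp, v1r, phi))
    return out


def _weight_field(mask: WedgeMask, phi: EulerAngles) -> np.ndarray:
    """The mask combination M*M_phi + 2*M^C*M_phi, fftshift-centered."""
    m_phi = rotated_wedge_mask(mask.shape, mask.alpha_max_deg, phi).data
    return (mask.data + 2.0 * mask.complement()) * m_phi


def per_sample_loss(pred: Volume | np.ndarray, target: Volume | np.ndarray,
                    mask: WedgeMask, mask_phi: WedgeMask) -> float:
    """Masked Fourier-domain squared error of one sample.

    Computed with a unitary FFT so Parseval holds: with all-ones masks the
    loss equals the image-domain squared L2 distance.
    """
    p = pred.data if isinstance(pred, Volume) else np.asarray(pred)
    t = target.data if isinstance(target, Volume) else np.asarray(target)
    if p.shape != t.shape or p.shape != mask.shape or p.shape != mask_phi.shape:
        raise ParameterError("pred/target/mask shapes must all match")
    w = (mask.data + 2.0 * mask.complement()) * mask_phi.data
    spec = np.fft.fftn(p - t, norm="ortho")
    spec *= np.fft.ifftshift(w)
    return float(np.sum(np.abs(spec) ** 2))


def loss_and_input_grad(pred: np.ndarray, target: np.ndarray,
                        w2_shifted: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Batched loss values and d(loss)/d(pred) for squared mask weights
    ``w2_shifted`` (ifftshifted, per sample).  Gradient of
    ``sum |w F d|^2`` for real ``d`` is ``2 Re F^-1 (w^2 F d)``."""
    d = pred - target
    spec = np.fft.fftn(d, axes=(-3, -2, -1), norm="ortho")
    losses = np.sum(w2_shifted * np.abs(spec) ** 2, axis=(-3, -2, -1))
    grad = 2.0 * np.fft.ifftn(w2_shifted * spec, axes=(-3, -2, -1),
                              norm="ortho").real
    return losses, grad.astype(pred.dtype)


def update_wedges(pairs: list[SubTomoPair], model: UNet3D,
                  mask: WedgeMask) -> None:
    """Insert the model's prediction into each v0 cube's missing wedge.

    The measured region (support of M) is preserved; only the complement is
    replaced: ``v0 <- F^-1 (M F v0 + M^C F f(v0))``.  ``v1`` cubes are never
    touched.
    """
    if not pairs:
        return
    m_shift = np.fft.ifftshift(mask.data)
    preds = model.forward(np.stack([p.v0 for p in pairs]), train=False)
    for pair, pred in zip(pairs, preds):
        spec = (m_shift * np.fft.fftn(pair.v0)
                + (1.0 - m_shift) * np.fft.fftn(pred))
        pair.v0[...] = np.fft.ifftn(spec).real.astype(np.float32)


def fit(pairs: list[SubTomoPair], cfg: FitConfig,
        model: UNet3D | None = None) -> tuple[UNet3D, FitHistory]:
    """Run the fitting loop on standardized sub-tomogram pairs.

    Pairs are standardized in place using their stored ``norm_stats``; the
    caller keeps the originals.  Deterministic for a fixed ``cfg.seed``.
    """
    if not pairs:
        raise ParameterError("need at least one sub-tomogram pair")
    size = pairs[0].v0.shape[0]
    if cfg.cube_size != size:
        raise ParameterError("cfg.cube_size must match the extracted cubes")
    if any(p.v0.shape != (size, size, size) for p in pairs):
        raise ParameterError("all pairs must share one cubic size")

    rng = np.random.default_rng(cfg.seed)
    seed_init, seed_rot, seed_shuffle = rng.integers(2 ** 31, size=3)
    rot_rng = np.random.default_rng(seed_rot)
    shuffle_rng = np.random.default_rng(seed_shuffle)

    if model is None:
        unet_cfg = cfg.unet or UNetConfig(dropout_p=cfg.dropout_p)
        model = build_unet(unet_cfg, seed=int(seed_init))

    # work on standardized copies; v0 is wedge-updated across epochs
    work: list[SubTomoPair] = []
    for p in pairs:
        mu, sd = p.norm_stats
        work.append(SubTomoPair((p.v0 - mu) / sd, (p.v1 - mu) / sd, p.pos,
                                (0.0, 1.0)))

    n_val = int(round(cfg.validation_fraction * len(work)))
    val = work[len(work) - n_val:] if n_val else []
    train = work[:len(work) - n_val]
    if not train:
        raise ParameterError("validation split leaves no training pairs")

    mask = wedge_mask((size,) * 3, cfg.alpha_max_deg)
    opt = Adam(model.params(), lr=cfg.learning_rate)
    history = FitHistory()

    for _ in range(cfg.epochs):
        samples = make_epoch_samples(train, mask, rot_rng, fill=cfg.rotation_fill)
        order = shuffle_rng.permutation(len(samples))
        epoch_losses: list[float] = []
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            inp = np.stack([samples[i][0] for i in idx])
            tgt = np.stack([samples[i][1] for i in idx])
            w2 = np.stack([np.fft.ifftshift(_weight_field(mask, samples[i][2]) ** 2)
                           for i in idx])
            if cfg.learning_rate > 0:
                pred = model.forward(inp, train=True)
                losses, gpred = loss_and_input_grad(pred, tgt, w2)
                model.backward(gpred / len(idx))
                opt.step()
                opt.zero_grad()
            else:
                pred = model.forward(inp, train=False)
                losses, _ = loss_and_input_grad(pred, tgt, w2)
            epoch_losses.extend(losses.tolist())
        history.train_loss.append(float(np.mean(epoch_losses)))

        if val:
            vsamples = make_epoch_samples(val, mask, rot_rng,
                                          fill=cfg.rotation_fill)
            vpred = model.forward(np.stack([s[0] for s in vsamples]), train=False)
            w2 = np.stack([np.fft.ifftshift(_weight_field(mask, s[2]) ** 2)
                           for s in vsamples])
            vloss, _ = loss_and_input_grad(vpred, np.stack([s[1] for s in vsamples]), w2)
            history.val_loss.append(float(np.mean(vloss)))

        if cfg.wedge_update:
            update_wedges(train, model, mask)

    return model, history
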