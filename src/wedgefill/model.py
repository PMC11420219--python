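"""Configurable volumetric U-Net used as the denoiser/inpainter.

The frozen default layout (64 first-level channels, three downsampling
levels) has three 3x3x3 convolutions per encoder and decoder stage with
channel doubling per level, a two-convolution bottleneck at 8x the base
width, kernel-2 transposed-convolution upsampling with skip concatenation,
a two-convolution full-resolution refinement head and a 1x1x1 output
projection - 27,260,865 trainable parameters, i.e. 27.3 M at the usual
reporting precision.  A lighter desk preset (16 channels, two levels, two
convolutions per stage, no head) is used for tests and CPU-scale runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .core import ParameterError
from .nn import Adam, Conv3d, ConvTranspose3d, Dropout, LeakyReLU, MaxPool3d, Param

__all__ = ["UNetConfig", "UNet3D", "build_unet", "count_params",
           "save_checkpoint", "load_checkpoint", "DESK_PRESET"]

# frozen block layout of the full-size default
_DEFAULT_CONVS_PER_STAGE = 3
_DEFAULT_HEAD_CONVS = 2
_BOTTLENECK_CONVS = 2


@dataclass(frozen=True)
class UNetConfig:
    """Architecture hyperparameters.

    ``base_channels`` is the first-level width, doubled at each of ``depth``
    downsampling levels.  Input cubes must have sides divisible by
    ``2**depth``.  ``dropout_p`` of 0 disables dropout (the default for
    self-supervised wedge fitting; 0.3 reproduces the heavier
    regularization regime of related restoration tools).
    """

    base_channels: int = 64
    depth: int = 3
    dropout_p: float = 0.0
    convs_per_stage: int = _DEFAULT_CONVS_PER_STAGE
    head_convs: int = _DEFAULT_HEAD_CONVS

    def __post_init__(self) -> None:
        if self.base_channels < 1 or self.depth < 1:
            raise ParameterError("base_channels and depth must be >= 1")
        if not 0.0 <= self.dropout_p < 1.0:
            raise ParameterError("dropout_p must lie in [0, 1)")
        if self.convs_per_stage < 1 or self.head_convs < 0:
            raise ParameterError("invalid block layout")


DESK_PRESET = UNetConfig(base_channels=16, depth=2, convs_per_stage=2, head_convs=0)


class UNet3D:
    """Encoder-decoder with skip connections, built from :mod:`wedgefill.nn`.

    Channels-last internally; the public :meth:`forward` accepts and returns
    ``(B, D, H, W)`` arrays of single-channel volumes.
    """

    def __init__(self, cfg: UNetConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        ch = [cfg.base_channels * 2 ** i for i in range(cfg.depth + 1)]
        self._drop_rng = np.random.default_rng(rng.integers(2 ** 31))

        def block(in_ch: int, out_ch: int, n: int) -> list:
            layers: list = []
            prev = in_ch
            for _ in range(n):
                layers += [Conv3d(prev, out_ch, 3, rng), LeakyReLU()]
                if cfg.dropout_p > 0:
                    layers.append(Dropout(cfg.dropout_p, self._drop_rng))
                prev = out_ch
            return layers

        self.enc_blocks = []
        prev = 1
        for d in range(cfg.depth):
            self.enc_blocks.append(block(prev, ch[d], cfg.convs_per_stage))
            prev = ch[d]
        self.pools = [MaxPool3d() for _ in range(cfg.depth)]
        self.bottleneck = block(prev, ch[cfg.depth], _BOTTLENECK_CONVS)
        self.ups = []
        self.dec_blocks = []
        prev = ch[cfg.depth]
        for d in reversed(range(cfg.depth)):
            self.ups.append(ConvTranspose3d(prev, ch[d], rng))
            self.dec_blocks.append(block(2 * ch[d], ch[d], cfg.convs_per_stage))
            prev = ch[d]
        self.head = block(ch[0], ch[0], cfg.head_convs)
        self.final = Conv3d(ch[0], 1, 1, rng)
        self._skip_ch = ch

    # -- parameter plumbing -------------------------------------------------
    def params(self) -> list[Param]:
        out: list[Param] = []
        for blk in (self.enc_blocks + [self.bottleneck] + self.dec_blocks
                    + [self.head]):
            for layer in blk:
                out.extend(layer.params())
        for up in self.ups:
            out.extend(up.params())
        out.extend(self.final.params())
        return out

    def get_weights(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        ps = self.params()
        if len(ps) != len(weights):
            raise ParameterError("weight list does not match the architecture")
        for p, w in zip(ps, weights):
            p.value[...] = w

    # -- forward / backward -------------------------------------------------
    def _check_side(self, side: int) -> None:
        if side % (2 ** self.cfg.depth) != 0:
            raise ParameterError(
                f"cube side {side} not divisible by 2**depth = {2 ** self.cfg.depth}")

    @staticmethod
    def _run_block(blk: list, x: np.ndarray, train: bool) -> np.ndarray:
        for layer in blk:
            x = layer.forward(x, train) if isinstance(layer, Dropout) else layer.forward(x)
        return x

    @staticmethod
    def _back_block(blk: list, g: np.ndarray) -> np.ndarray:
        for layer in reversed(blk):
            g = layer.backward(g)
        return g

    @property
    def dtype(self) -> np.dtype:
        return self.final.weight.value.dtype

    def astype(self, dtype) -> "UNet3D":
        """Cast all parameters in place (e.g. to float64 for gradient checks)."""
        for p in self.params():
            p.value = p.value.astype(dtype)
            p.grad = np.zeros_like(p.value)
        return self

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Apply the network to a batch of volumes ``(B, D, H, W)``."""
        x = np.asarray(x, dtype=self.dtype)
        squeeze = x.ndim == 3
        if squeeze:
            x = x[None]
        for side in x.shape[1:]:
            self._check_side(side)
        h = x[..., None]  # channels-last
        skips = []
        for blk, pool in zip(self.enc_blocks, self.pools):
            h = self._run_block(blk, h, train)
            skips.append(h)
            h = pool.forward(h)
        h = self._run_block(self.bottleneck, h, train)
        for up, blk, skip in zip(self.ups, self.dec_blocks, reversed(skips)):
            h = up.forward(h)
            h = np.concatenate([h, skip], axis=-1)
            h = self._run_block(blk, h, train)
        h = self._run_block(self.head, h, train)
        h = self.final.forward(h)
        out = h[..., 0]
        return out[0] if squeeze else out

    def backward(self, gy: np.ndarray, need_input_grad: bool = True) -> np.ndarray:
        """Backpropagate through the cached forward pass; returns d loss/d input."""
        g = np.asarray(gy, dtype=self.dtype)
        if g.ndim == 3:
            g = g[None]
        g = self.final.backward(g[..., None])
        g = self._back_block(self.head, g)
        gskips = []
        for up, blk in zip(reversed(self.ups), reversed(self.dec_blocks)):
            g = self._back_block(blk, g)
            ch = up.out_ch
            gskips.append(g[..., ch:])
            g = up.backward(g[..., :ch])
        g = self._back_block(self.bottleneck, g)
        for d, (blk, pool, gs) in enumerate(zip(reversed(self.enc_blocks),
                                                reversed(self.pools),
                                                reversed(gskips))):
            g = pool.backward(g)
            g = g + gs
            if need_input_grad or d < len(self.enc_blocks) - 1:
                g = self._back_block(blk, g)
            else:
                # shallowest block: skip the first conv's input gradient
                from .nn import Conv3d
                for layer in reversed(blk[1:]):
                    g = layer.backward(g)
                assert isinstance(blk[0], Conv3d)
                g = blk[0].backward(g, need_input_grad=False)
        if g is None:
            return None  # type: ignore[return-value]
        return g[..., 0]


def build_unet(cfg: UNetConfig, seed: int = 0) -> UNet3D:
    """Instantiate a U-Net with deterministic (seeded) initialization."""
    return UNet3D(cfg, seed=seed)


def count_params(model: UNet3D) -> int:
    """Total number of trainable scalar parameters."""
    return int(sum(p.value.size for p in model.params()))


def save_checkpoint(model: UNet3D, path: str) -> None:
    """Save weights plus the architecture config (JSON-embedded)."""
    arrays = {f"w{i}": w for i, w in enumerate(model.get_weights())}
    np.savez(path, config=json.dumps(asdict(model.cfg)), **arrays)


def load_checkpoint(path: str) -> UNet3D:
    with np.load(path if str(path).endswith(".npz") else str(path) + ".npz",
                 allow_pickle=False) as data:
        cfg = UNetConfig(**json.loads(str(data["config"])))
        model = UNet3D(cfg)
        model.set_weights([data[f"w{i}"] for i in range(len(model.params()))])
    return model
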