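"""Scikit-learn-style estimator wrapping the full restoration method.

``MissingWedgeRestorer`` is fit/transform shaped: :meth:`fit` trains the
denoising/inpainting network on sub-tomogram pairs extracted from two
half-reconstructions with independent noise; :meth:`transform` applies the
fitted network to both halves and averages them into the final tomogram.
It composes with sklearn tooling through ``get_params``/``set_params``.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .core import ParameterError, Volume
from .fit import FitConfig, fit as _fit
from .model import UNetConfig
from .subtomo import content_mask, extract_pairs, filter_positions, plan_grid

__all__ = ["MissingWedgeRestorer"]


class MissingWedgeRestorer(BaseEstimator):
    """Self-supervised joint denoiser and missing-wedge filler.

    Parameters
    ----------
    alpha_max_deg : float
        Half-angle of the tilt range; the missing wedge spans
        ``90 - alpha_max_deg`` degrees on either side of the beam axis.
    cube_size, overlap : int
        Sliding-window extraction geometry (voxels).
    epochs, batch_size, learning_rate, dropout_p, wedge_update, seed
        Fitting-loop hyperparameters; see :class:`wedgefill.fit.FitConfig`.
    base_channels, depth, convs_per_stage, head_convs
        Network architecture; see :class:`wedgefill.model.UNetConfig`.
    min_content_fraction : float
        Keep only fitting cubes containing at least this fraction of sample
        according to an intensity-based content mask (0 disables filtering).

    Attributes
    ----------
    model_ : UNet3D
        The fitted network.
    history_ : FitHistory
        Per-epoch training (and optional validation) losses.
    n_pairs_ : int
        Number of sub-tomogram pairs used for fitting.
    """

    def __init__(self, alpha_max_deg: float = 60.0, cube_size: int = 96,
                 overlap: int = 32, epochs: int = 100, batch_size: int = 8,
                 learning_rate: float = 4e-4, dropout_p: float = 0.0,
                 wedge_update: bool = True, seed: int = 0,
                 base_channels: int = 64, depth: int = 3,
                 convs_per_stage: int = 3, head_convs: int = 2,
                 min_content_fraction: float = 0.0,
                 validation_fraction: float = 0.0):
        self.alpha_max_deg = alpha_max_deg
        self.cube_size = cube_size
        self.overlap = overlap
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.dropout_p = dropout_p
        self.wedge_update = wedge_update
        self.seed = seed
        self.base_channels = base_channels
        self.depth = depth
        self.convs_per_stage = convs_per_stage
        self.head_convs = head_convs
        self.min_content_fraction = min_content_fraction
        self.validation_fraction = validation_fraction

    def _fit_config(self) -> FitConfig:
        unet = UNetConfig(base_channels=self.base_channels, depth=self.depth,
                          dropout_p=self.dropout_p,
                          convs_per_stage=self.convs_per_stage,
                          head_convs=self.head_convs)
        return FitConfig(alpha_max_deg=self.alpha_max_deg,
                         cube_size=self.cube_size, epochs=self.epochs,
                         batch_size=self.batch_size,
                         learning_rate=self.learning_rate,
                         dropout_p=self.dropout_p, seed=self.seed,
                         wedge_update=self.wedge_update,
                         validation_fraction=self.validation_fraction,
                         unet=unet)

    @staticmethod
    def _as_volume(v) -> Volume:
        return v if isinstance(v, Volume) else Volume(np.asarray(v))

    def fit(self, vol0, vol1=None):
        """Fit the network on sub-tomogram pairs from two half-volumes."""
        if vol1 is None:
            raise ParameterError("fit requires two half-reconstructions")
        v0, v1 = self._as_volume(vol0), self._as_volume(vol1)
        positions = plan_grid(v0.shape, self.cube_size, self.overlap)
        if self.min_content_fraction > 0:
            avg = Volume((v0.data + v1.data) / 2.0, v0.voxel_size_A)
            mask = content_mask(avg)
            positions = filter_positions(positions, mask,
                                         self.min_content_fraction,
                                         self.cube_size)
            if not positions:
                raise ParameterError("content filter removed every position")
        pairs = extract_pairs(v0, v1, positions, self.cube_size)
        self.model_, self.history_ = _fit(pairs, self._fit_config())
        self.n_pairs_ = len(pairs)
        return self

    def transform(self, vol0, vol1=None) -> Volume:
        """Refine two half-volumes into the final denoised tomogram."""
        if not hasattr(self, "model_"):
            raise ParameterError("estimator is not fitted yet")
        if vol1 is None:
            raise ParameterError("transform requires two half-reconstructions")
        from .refine import refine_tomogram

        v0, v1 = self._as_volume(vol0), self._as_volume(vol1)
        return refine_tomogram(v0, v1, self.model_, self.cube_size,
                               self.overlap, batch_size=self.batch_size)

    def fit_transform(self, vol0, vol1=None) -> Volume:
        return self.fit(vol0, vol1).transform(vol0, vol1)
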