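"""Fitting loop: epoch samples, masked Fourier loss, wedge updates."""

import numpy as np
import pytest

from wedgefill import (EulerAngles, FitConfig, ParameterError, SubTomoPair,
                       Volume, build_unet, per_sample_loss, update_wedges,
                       wedge_mask)
from wedgefill.core import GridPosition
from wedgefill.fit import (_weight_field, fit, loss_and_input_grad,
                           make_epoch_samples)
from wedgefill.fourier import WedgeMask, rotated_wedge_mask, sample_rotation
from wedgefill.model import UNetConfig


def _pairs(n=3, size=16, seed=0):
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        v0 = rng.standard_normal((size, size, size)).astype(np.float32)
        v1 = rng.standard_normal((size, size, size)).astype(np.float32)
        out.append(SubTomoPair(v0, v1, GridPosition(0, 0, 0),
                               (float(v0.mean()), float(v0.std()))))
    return out


def _ones_mask(n):
    return WedgeMask(np.ones((n, n, n), np.float32), 89.0,
                     EulerAngles.identity())


class TestEpochSamples:
    def test_input_has_no_energy_in_masked_wedge(self):
        pairs = _pairs(2)
        mask = wedge_mask((16, 16, 16), 60.0)
        samples = make_epoch_samples(pairs, mask, np.random.default_rng(0))
        for inp, _, _ in samples:
            spec = np.abs(np.fft.fftshift(np.fft.fftn(inp))) ** 2
            wedge = mask.data == 0
            assert spec[wedge].sum() < 1e-10 * spec.sum()

    def test_fresh_rotations_each_epoch(self):
        pairs = _pairs(2)
        mask = wedge_mask((16, 16, 16), 60.0)
        rng = np.random.default_rng(1)
        phis1 = [s[2] for s in make_epoch_samples(pairs, mask, rng)]
        phis2 = [s[2] for s in make_epoch_samples(pairs, mask, rng)]
        assert phis1 != phis2

    def test_identity_setup_reproduces_pair(self, monkeypatch):
        # all-ones mask and forced identity rotation: input == v0, target == v1
        import sys
        fit_mod = sys.modules["wedgefill.fit"]
        monkeypatch.setattr(fit_mod, "sample_rotation",
                            lambda rng: EulerAngles.identity())
        pairs = _pairs(1)
        samples = make_epoch_samples(pairs, _ones_mask(16),
                                     np.random.default_rng(0))
        inp, tgt, _ = samples[0]
        np.testing.assert_allclose(inp, pairs[0].v0, atol=1e-4)
        np.testing.assert_allclose(tgt, pairs[0].v1, atol=1e-4)


class TestPerSampleLoss:
    def test_zero_for_equal_volumes(self):
        rng = np.random.default_rng(0)
        v = rng.standard_normal((8, 8, 8))
        m = wedge_mask((8, 8, 8), 60.0)
        mp = rotated_wedge_mask((8, 8, 8), 60.0,
                                sample_rotation(np.random.default_rng(1)))
        assert per_sample_loss(v, v, m, mp) == 0.0

    def test_all_ones_masks_reduce_to_l2(self):
        rng = np.random.default_rng(1)
        a = rng.standard_normal((8, 8, 8))
        b = rng.standard_normal((8, 8, 8))
        val = per_sample_loss(a, b, _ones_mask(8), _ones_mask(8))
        assert val == pytest.approx(float(((a - b) ** 2).sum()), rel=1e-9)

    def test_matches_dense_dft_oracle(self):
        # brute-force evaluation with an explicit unitary DFT matrix
        n = 8
        rng = np.random.default_rng(2)
        pred = rng.standard_normal((n, n, n))
        targ = rng.standard_normal((n, n, n))
        m = wedge_mask((n, n, n), 60.0)
        mp = rotated_wedge_mask((n, n, n), 60.0,
                                sample_rotation(np.random.default_rng(3)))
        w1 = np.exp(-2j * np.pi * np.outer(np.arange(n), np.arange(n)) / n)
        w1 /= np.sqrt(n)
        dft = np.kron(np.kron(w1, w1), w1)
        w = np.fft.ifftshift((m.data + 2 * m.complement()) * mp.data).ravel()
        oracle = float(np.sum(np.abs(w * (dft @ (pred - targ).ravel())) ** 2))
        assert per_sample_loss(pred, targ, m, mp) == pytest.approx(oracle,
                                                                   rel=1e-6)

    def test_loss_decomposes_over_orthogonal_masks(self):
        n = 8
        rng = np.random.default_rng(4)
        pred = rng.standard_normal((n, n, n))
        targ = rng.standard_normal((n, n, n))
        m = wedge_mask((n, n, n), 60.0)
        phi = sample_rotation(np.random.default_rng(5))
        mp = rotated_wedge_mask((n, n, n), 60.0, phi)
        total = per_sample_loss(pred, targ, m, mp)
        spec = np.fft.fftshift(np.fft.fftn(pred - targ, norm="ortho"))
        n2n = float(np.sum(np.abs(m.data * mp.data * spec) ** 2))
        wedge = float(np.sum(np.abs(2 * m.complement() * mp.data * spec) ** 2))
        assert not (m.data * mp.data * m.complement() * mp.data).any()
        assert total == pytest.approx(n2n + wedge, rel=1e-9)

    def test_shape_mismatch(self):
        m = wedge_mask((8, 8, 8), 60.0)
        with pytest.raises(ParameterError):
            per_sample_loss(np.zeros((8, 8, 8)), np.zeros((4, 4, 4)), m, m)

    def test_gradient_matches_finite_difference(self):
        n = 8
        rng = np.random.default_rng(6)
        pred = rng.standard_normal((1, n, n, n))
        targ = rng.standard_normal((1, n, n, n))
        m = wedge_mask((n, n, n), 60.0)
        phi = sample_rotation(np.random.default_rng(7))
        w2 = np.fft.ifftshift(_weight_field(m, phi) ** 2)[None]
        _, grad = loss_and_input_grad(pred, targ, w2)
        eps = 1e-6
        i = (0, 2, 3, 4)
        pp, pm = pred.copy(), pred.copy()
        pp[i] += eps
        pm[i] -= eps
        lp, _ = loss_and_input_grad(pp, targ, w2)
        lm, _ = loss_and_input_grad(pm, targ, w2)
        assert grad[i] == pytest.approx(float(lp[0] - lm[0]) / (2 * eps),
                                        rel=1e-5)


class TestUpdateWedges:
    def _setup(self):
        pairs = _pairs(2, size=8)
        mask = wedge_mask((8, 8, 8), 60.0)
        model = build_unet(UNetConfig(base_channels=2, depth=1,
                                      convs_per_stage=1, head_convs=0), seed=0)
        return pairs, mask, model

    def test_identity_model_keeps_v0(self):
        pairs, mask, model = self._setup()

        class Identity:
            def forward(self, x, train=False):
                return x

        before = [p.v0.copy() for p in pairs]
        update_wedges(pairs, Identity(), mask)
        for b, p in zip(before, pairs):
            np.testing.assert_allclose(p.v0, b, atol=1e-5)

    def test_zero_model_applies_mask(self):
        pairs, mask, model = self._setup()

        class Zero:
            def forward(self, x, train=False):
                return np.zeros_like(x)

        before = [p.v0.copy() for p in pairs]
        update_wedges(pairs, Zero(), mask)
        for b, p in zip(before, pairs):
            expected = np.fft.ifftn(np.fft.fftn(b)
                                    * np.fft.ifftshift(mask.data)).real
            np.testing.assert_allclose(p.v0, expected, atol=1e-5)

    def test_measured_region_preserved_and_v1_untouched(self):
        pairs, mask, model = self._setup()
        before0 = [p.v0.copy() for p in pairs]
        before1 = [p.v1.copy() for p in pairs]
        update_wedges(pairs, model, mask)
        m_shift = np.fft.ifftshift(mask.data)
        for b, p in zip(before0, pairs):
            diff = np.fft.fftn(p.v0.astype(np.float64)
                               - b.astype(np.float64))
            assert np.abs(m_shift * diff).max() < 1e-5 * np.linalg.norm(b)
        for b, p in zip(before1, pairs):
            np.testing.assert_array_equal(p.v1, b)


class TestFit:
    def test_zero_learning_rate_keeps_initialization(self):
        pairs = _pairs(2, size=8)
        cfg = FitConfig(cube_size=8, epochs=1, learning_rate=0.0, seed=3,
                        batch_size=2,
                        unet=UNetConfig(base_channels=2, depth=1,
                                        convs_per_stage=1, head_convs=0))
        ref = build_unet(cfg.unet, seed=0)
        model, history = fit(pairs, cfg)
        assert len(history.train_loss) == 1
        fresh = build_unet(cfg.unet,
                           seed=int(np.random.default_rng(3).integers(2**31, size=3)[0]))
        for w, f in zip(model.get_weights(), fresh.get_weights()):
            np.testing.assert_array_equal(w, f)

    def test_caller_pairs_never_mutated(self):
        pairs = _pairs(2, size=8)
        snapshots = [(p.v0.copy(), p.v1.copy()) for p in pairs]
        cfg = FitConfig(cube_size=8, epochs=2, seed=4, batch_size=2,
                        wedge_update=True,
                        unet=UNetConfig(base_channels=2, depth=1,
                                        convs_per_stage=1, head_convs=0))
        fit(pairs, cfg)
        for (v0, v1), p in zip(snapshots, pairs):
            np.testing.assert_array_equal(p.v0, v0)
            np.testing.assert_array_equal(p.v1, v1)

    def test_deterministic_given_seed(self):
        cfg = FitConfig(cube_size=8, epochs=2, seed=5, batch_size=2,
                        unet=UNetConfig(base_channels=2, depth=1,
                                        convs_per_stage=1, head_convs=0))
        _, h1 = fit(_pairs(3, size=8), cfg)
        _, h2 = fit(_pairs(3, size=8), cfg)
        assert h1.train_loss == h2.train_loss

    def test_validation_history_recorded(self):
        cfg = FitConfig(cube_size=8, epochs=2, seed=6, batch_size=2,
                        validation_fraction=0.34,
                        unet=UNetConfig(base_channels=2, depth=1,
                                        convs_per_stage=1, head_convs=0))
        _, history = fit(_pairs(3, size=8), cfg)
        assert len(history.val_loss) == 2

    def test_mismatched_cube_size_rejected(self):
        cfg = FitConfig(cube_size=16, epochs=1)
        with pytest.raises(ParameterError):
            fit(_pairs(1, size=8), cfg)
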