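"""Oracles for the regularizer losses: curvature against the osculating
circle, the DFT against a direct O(N^2) sum, the BCE terms against scalar
loops, and the latent-ratio equivalence."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metaceeg import gan
from metaceeg.autodiff import Tensor
from metaceeg.mrm import (RegularizerWeights, amplitude_spectrum,
                          combined_generator_loss, fr_loss, sr_loss,
                          sr_ratio, squash_curvature, three_point_curvature,
                          tr_loss)


class TestCurvature:
    def test_collinear_is_exactly_zero(self):
        k = three_point_curvature(np.arange(10.0))
        assert np.all(k == 0.0)

    def test_parabola_triple_is_exactly_two(self):
        assert three_point_curvature(np.array([1.0, 0.0, 1.0]))[0] == 2.0

    @pytest.mark.parametrize("r", [0.5, 1.0, 5.0])
    def test_circle_curvature_converges_to_reciprocal_radius(self, r):
        """Arc of a circle resampled on a fine uniform x-grid -> k = 1/r."""
        h = r * 1e-3
        xs = np.arange(-0.2 * r, 0.2 * r, h)
        ys = np.sqrt(r * r - xs * xs)
        k = three_point_curvature(ys, dx=h)
        assert np.allclose(k, 1.0 / r, rtol=0.01)

    def test_constant_offset_leaves_curvature_unchanged(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=64)
        assert np.allclose(three_point_curvature(x),
                           three_point_curvature(x + 17.3))

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            three_point_curvature(np.array([1.0, 2.0]))


class TestSquash:
    def test_floor_and_midpoint(self):
        out = squash_curvature(np.array([0.0, 1.0]))
        assert out[0] == pytest.approx(1e-7)
        assert out[1] == 0.5

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            squash_curvature(np.array([-0.1]))

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(0, 1e6), min_size=2, max_size=20))
    def test_monotone(self, ks):
        ks = np.sort(np.array(ks))
        out = squash_curvature(ks)
        assert np.all(np.diff(out) >= 0)


def _bce_loop(target, pred):
    t, p = target.ravel(), pred.ravel()
    acc = 0.0
    for ti, pi in zip(t, p):
        acc -= ti * np.log(pi) + (1 - ti) * np.log(1 - pi)
    return acc / t.size


class TestTrLoss:
    def test_matches_scalar_loop_oracle(self):
        rng = np.random.default_rng(1)
        real = rng.normal(size=(3, 2, 32))
        fake = rng.normal(size=(3, 2, 32))
        k_r = squash_curvature(three_point_curvature(real))
        k_f = squash_curvature(three_point_curvature(fake))
        assert tr_loss(real, fake) == pytest.approx(_bce_loop(k_r, k_f),
                                                    abs=1e-9)

    def test_equal_curvature_half_gives_ln2(self):
        # traces whose squashed curvature is exactly 0.5 everywhere (k=1)
        x = np.zeros(16)
        x[1::2] = 0.5  # alternating: b2=0, b3=+-0.5 -> k=1 -> squash 0.5
        batch = np.tile(x, (2, 1, 1))
        assert tr_loss(batch, batch) == pytest.approx(np.log(2), abs=1e-12)

    def test_minimized_when_fake_matches_real(self):
        """BCE over the fake argument bottoms out at fake = real."""
        rng = np.random.default_rng(2)
        real = rng.normal(size=(2, 1, 24))
        base = tr_loss(real, real)
        for seed in range(5):
            other = rng.normal(size=real.shape)
            assert tr_loss(real, other) >= base - 1e-12

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            tr_loss(np.zeros((2, 1, 8)), np.zeros((3, 1, 8)))


class TestAmplitudeSpectrum:
    def test_constant_concentrates_in_dc(self):
        f = amplitude_spectrum(np.full(16, 3.0))
        assert f[0] == pytest.approx(48.0)
        assert np.allclose(f[1:], 0.0, atol=1e-10)

    def test_cosine_peaks_at_k0_and_mirror(self):
        n, k0 = 64, 5
        x = np.cos(2 * np.pi * k0 * np.arange(n) / n)
        f = amplitude_spectrum(x)
        assert f[k0] == pytest.approx(n / 2, rel=1e-9)
        assert f[n - k0] == pytest.approx(n / 2, rel=1e-9)

    def test_matches_direct_sum_dft(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            n = int(rng.integers(8, 128))
            x = rng.normal(size=n)
            direct = np.array([abs(sum(x[m] * np.exp(-2j * np.pi * k * m / n)
                                       for m in range(n)))
                               for k in range(n)])
            assert np.allclose(amplitude_spectrum(x), direct, rtol=1e-9,
                               atol=1e-9)

    def test_normalized_sums_to_one(self):
        rng = np.random.default_rng(4)
        f = amplitude_spectrum(rng.normal(size=(3, 2, 32)), normalize=True)
        assert np.allclose(f.sum(axis=-1), 1.0, atol=1e-9)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            amplitude_spectrum(np.array([1.0, np.nan]))


class TestFrLoss:
    def test_matches_scalar_loop_oracle(self):
        rng = np.random.default_rng(5)
        real = rng.normal(size=(4, 1, 16))
        fake = rng.normal(size=(4, 1, 16))
        fr = np.clip(amplitude_spectrum(real, normalize=True).mean(0),
                     1e-7, 1 - 1e-7)
        ff = np.clip(amplitude_spectrum(fake, normalize=True), 1e-7, 1 - 1e-7)
        oracle = _bce_loop(np.broadcast_to(fr, ff.shape).copy(), ff)
        assert fr_loss(real, fake) == pytest.approx(oracle, abs=1e-9)

    def test_fake_matching_mean_real_minimizes(self):
        rng = np.random.default_rng(6)
        real = rng.normal(size=(8, 1, 16))
        base = fr_loss(real, real)  # spectra near the real mean
        for seed in range(5):
            other = np.random.default_rng(seed).normal(size=real.shape) * 5
            assert fr_loss(real, other) >= base - 0.05

    def test_identical_single_trace_finite_and_symmetric(self):
        x = np.cos(2 * np.pi * 3 * np.arange(32) / 32)[None, None, :]
        v = fr_loss(x, x)
        assert np.isfinite(v) and v >= 0


class TestSrRatio:
    def test_identity_generator_gives_one(self):
        rng = np.random.default_rng(7)
        z1, z2 = rng.normal(size=8), rng.normal(size=8)
        assert sr_ratio(z1, z2, z1, z2) == pytest.approx(1.0)

    def test_constant_generator_gives_zero(self):
        rng = np.random.default_rng(8)
        z1, z2 = rng.normal(size=8), rng.normal(size=8)
        g = np.ones(16)
        assert sr_ratio(z1, z2, g, g) == pytest.approx(0.0, abs=1e-12)

    def test_cosine_equals_normalized_euclidean_form(self):
        rng = np.random.default_rng(9)
        for _ in range(200):
            z1, z2 = rng.normal(size=6), rng.normal(size=6)
            g1, g2 = rng.normal(size=12), rng.normal(size=12)
            zn1, zn2 = z1 / np.linalg.norm(z1), z2 / np.linalg.norm(z2)
            gn1, gn2 = g1 / np.linalg.norm(g1), g2 / np.linalg.norm(g2)
            euclid = (np.sum((gn1 - gn2) ** 2)
                      / np.sum((zn1 - zn2) ** 2))
            assert sr_ratio(z1, z2, g1, g2) == pytest.approx(euclid,
                                                             abs=1e-9)

    def test_degenerate_pair_rejected(self):
        z = np.ones(4)
        with pytest.raises(ValueError, match="degenerate"):
            sr_ratio(z, 2 * z, z, z)


class TestSrLoss:
    def test_modes(self):
        assert sr_loss([1.0], "reciprocal") == pytest.approx(1.0, rel=1e-6)
        assert sr_loss([1.0, 3.0], "negative") == -2.0
        assert sr_loss([1.0, 3.0], "literal") == 2.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            sr_loss([], "reciprocal")

    def test_reciprocal_step_raises_mean_ratio(self):
        """One gradient step on the reciprocal mode must push ratios up."""
        rng = np.random.default_rng(10)
        w = rng.normal(size=(6, 12)) * 0.1
        z = rng.standard_normal((8, 6))

        def mean_ratio(wm):
            fake = np.tanh(z @ wm)
            half = 4
            out = []
            for i in range(half):
                out.append(sr_ratio(z[i], z[half + i],
                                    fake[i], fake[half + i]))
            return np.mean(out)

        from metaceeg.gan import sr_loss_t
        from metaceeg import nn, autodiff as ad
        wt = Tensor(w)
        fake = ad.tanh(Tensor(z) @ wt)
        loss = sr_loss_t(z, ad.reshape(fake, (8, 1, 12)), "reciprocal")
        g = ad.grad(loss, wt).data
        stepped = w - 0.05 * g
        assert mean_ratio(stepped) > mean_ratio(w)


class TestCombinedLoss:
    def test_limits_and_selected_value(self):
        w = RegularizerWeights(lam=1 - 1e-12)
        out = combined_generator_loss(2.0, 1.0, 1.0, 3.0, w)
        assert out.L_G_final == pytest.approx(5.0, abs=1e-9)
        w = RegularizerWeights(lam=1e-12)
        out = combined_generator_loss(2.0, 1.0, 3.0, 9.0, w)
        assert out.L_G_final == pytest.approx(2.0 + 0.5 * 3.0 + 0.5 * 1.0,
                                              abs=1e-9)
        out = combined_generator_loss(0.0, 1.0, 1.0, 1.0,
                                      RegularizerWeights(lam=0.6))
        assert out.L_G_final == pytest.approx(1.0)

    def test_invalid_lambda_rejected(self):
        for lam in (0.0, 1.0, -0.5, 2.0):
            with pytest.raises(ValueError):
                RegularizerWeights(lam=lam)

    def test_nonfinite_input_rejected(self):
        with pytest.raises(ValueError):
            combined_generator_loss(np.nan, 0, 0, 0, RegularizerWeights())


class TestDifferentiableMirrors:
    """The Tensor-based loss terms used in training must agree with the
    reference numpy implementations."""

    def test_tr_and_fr_forward_values_agree(self):
        rng = np.random.default_rng(11)
        real = rng.normal(size=(4, 2, 32))
        fake = rng.normal(size=(4, 2, 32))
        assert float(gan.tr_loss_t(real, Tensor(fake)).data) == \
            pytest.approx(tr_loss(real, fake), abs=1e-6)
        assert float(gan.fr_loss_t(real, Tensor(fake)).data) == \
            pytest.approx(fr_loss(real, fake), abs=1e-9)

    def test_sr_forward_value_agrees(self):
        rng = np.random.default_rng(12)
        z = rng.standard_normal((8, 6))
        fake = rng.normal(size=(8, 1, 16))
        ratios = [sr_ratio(z[i], z[4 + i], fake[i], fake[4 + i])
                  for i in range(4)]
        for mode in ("reciprocal", "negative", "literal"):
            assert float(gan.sr_loss_t(z, Tensor(fake), mode).data) == \
                pytest.approx(sr_loss(ratios, mode), rel=1e-6)
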