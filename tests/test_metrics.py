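"""Mode-Score closed forms, SWD against exact 1-D transport, Welch PSD
sanity, polynomial trend, and the printed-formula classification metrics."""

import numpy as np
import pytest

from metaceeg.containers import EpochedEEG
from metaceeg.metrics import (classification_metrics, erp_trend,
                              metrics_from_confusion, mode_score,
                              pairwise_auc, sliced_wasserstein,
                              train_eval_classifier, welch_psd)


def _epochs(data, labels, fs=256.0):
    return EpochedEEG(np.asarray(data, float), labels, fs=fs)


class _FixedClassifier:
    """Stub with a prescribed p(y|x) response, for closed-form MS checks."""

    def __init__(self, probs_fn, classes):
        self._fn = probs_fn
        self.classes = np.asarray(classes)

    def predict_proba(self, epochs):
        x = epochs.data if isinstance(epochs, EpochedEEG) else epochs
        return self._fn(np.asarray(x))


class TestModeScore:
    def test_uninformative_classifier_gives_one(self):
        c = 3
        clf = _FixedClassifier(
            lambda x: np.full((x.shape[0], c), 1.0 / c), range(c))
        real = _epochs(np.zeros((9, 1, 16)), np.repeat([0, 1, 2], 3))
        fake = _epochs(np.ones((6, 1, 16)), np.zeros(6))
        assert mode_score(clf, real, fake) == pytest.approx(1.0)

    @pytest.mark.parametrize("c", [2, 3])
    def test_one_hot_classifier_matched_uniform_marginals(self, c):
        def one_hot_cycle(x):
            out = np.zeros((x.shape[0], c))
            out[np.arange(x.shape[0]), np.arange(x.shape[0]) % c] = 1.0
            return out

        clf = _FixedClassifier(one_hot_cycle, range(c))
        real = _epochs(np.zeros((2 * c, 1, 16)), np.tile(np.arange(c), 2))
        fake = _epochs(np.ones((3 * c, 1, 16)), np.zeros(3 * c))
        assert mode_score(clf, real, fake) == pytest.approx(float(c))

    def test_fake_equals_real_drops_second_term(self):
        rng = np.random.default_rng(0)
        probs = rng.dirichlet(np.ones(3), size=12)

        clf = _FixedClassifier(lambda x: probs[:x.shape[0]], range(3))
        real = _epochs(np.zeros((12, 1, 16)), np.tile(np.arange(3), 4))
        p_star = np.full(3, 1 / 3)
        kl = np.mean([np.sum(p * np.log(p / p_star)) for p in probs])
        p_bar = probs.mean(0)
        kl2 = np.sum(p_bar * np.log(p_bar / p_star))
        assert mode_score(clf, real, real) == pytest.approx(
            np.exp(kl - kl2), rel=1e-9)

    def test_empty_set_rejected(self):
        clf = _FixedClassifier(lambda x: np.ones((x.shape[0], 2)) / 2, [0, 1])
        real = _epochs(np.zeros((4, 1, 8)), [0, 0, 1, 1])
        empty = _epochs(np.zeros((0, 1, 8)), [])
        with pytest.raises(ValueError):
            mode_score(clf, real, empty)


class TestEvalClassifier:
    def test_separable_data_learned_and_deterministic(self):
        """Separable-by-construction 2-class data: held-out accuracy > 0.9;
        same seed reproduces identical parameters."""
        from metaceeg.preprocess import bandpass_fir, maxabs_scale
        from metaceeg.synthdata import ClassSpec, SynthConfig, generate_oddball
        cfg = SynthConfig(n_channels=1, noise_sd=1.5, class_spec=(
            ClassSpec(0, 60, 0.0), ClassSpec(1, 60, 8.0)), seed=7)
        ep = maxabs_scale(bandpass_fir(generate_oddball(cfg)))
        rng = np.random.default_rng(0)
        perm = rng.permutation(ep.n_epochs)
        train_ep = ep.subset(perm[:90])
        test_ep = ep.subset(perm[90:])
        clf = train_eval_classifier(train_ep, seed=0, n_steps=300)
        probs = clf.predict_proba(test_ep)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        pred = clf.classes[np.argmax(probs, axis=1)]
        assert np.mean(pred == test_ep.labels) > 0.9
        clf2 = train_eval_classifier(train_ep, seed=0, n_steps=300)
        for k, v in clf.net.parameters().items():
            assert np.array_equal(v, clf2.net.parameters()[k])

    def test_single_class_rejected(self, oddball_scaled):
        only0 = oddball_scaled.subset(oddball_scaled.labels == 0)
        with pytest.raises(ValueError):
            train_eval_classifier(only0, seed=0, n_steps=1)


class TestSlicedWasserstein:
    def test_identical_sets_zero(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(20, 1, 16))
        a = _epochs(x, np.zeros(20))
        assert sliced_wasserstein(a, a) == 0.0

    def test_matches_exact_1d_transport(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=(30, 1, 1))
        b = rng.normal(loc=1.0, size=(30, 1, 1))
        oracle = np.mean(np.abs(np.sort(a.ravel()) - np.sort(b.ravel())))
        est = sliced_wasserstein(_epochs(a, np.zeros(30)),
                                 _epochs(b, np.zeros(30)), n_proj=64, seed=0)
        assert est == pytest.approx(oracle, rel=1e-9)

    def test_two_point_masses_distance_d(self):
        d = 2.5
        a = np.zeros((10, 1, 1))
        b = np.full((10, 1, 1), d)
        assert sliced_wasserstein(a, b, n_proj=16, seed=0) == \
            pytest.approx(d, rel=1e-9)

    def test_monotone_under_interpolation_toward_real(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(50, 1, 1))
        b = rng.normal(loc=3.0, size=(50, 1, 1))
        prev = np.inf
        for alpha in (0.0, 0.5, 1.0):
            mix = (1 - alpha) * b + alpha * a
            val = sliced_wasserstein(a, mix, n_proj=32, seed=0)
            assert val <= prev + 1e-12
            prev = val

    def test_symmetric_given_same_projections(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=(15, 2, 8))
        b = rng.normal(size=(15, 2, 8))
        assert sliced_wasserstein(a, b, seed=5) == \
            pytest.approx(sliced_wasserstein(b, a, seed=5), rel=1e-12)


class TestWelchPsd:
    def test_pure_tone_peaks_at_its_bin(self):
        fs, n = 256.0, 512
        t = np.arange(n) / fs
        x = np.sin(2 * np.pi * 10.0 * t)[None, None, :]
        freqs, psd = welch_psd(_epochs(x, [0], fs=fs))
        assert freqs[np.argmax(psd[0])] == pytest.approx(10.0, abs=0.5)

    def test_white_noise_flat_within_20pct(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal((1000, 1, 256))
        freqs, psd = welch_psd(_epochs(x, np.zeros(1000), fs=256.0))
        # average into ~5 Hz bands, then require flatness within 20%
        bands = [psd[0][(freqs >= lo) & (freqs < lo + 5)].mean()
                 for lo in range(1, 40, 5)]
        assert max(bands) / min(bands) < 1.2

    def test_total_power_close_to_variance(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal((200, 1, 512))
        ep = _epochs(x, np.zeros(200), fs=256.0)
        freqs, psd = welch_psd(ep, band=(0.0, 128.0))
        power = np.trapezoid(psd[0], freqs)
        assert power == pytest.approx(x.var(), rel=0.05)

    def test_short_epoch_rejected(self):
        with pytest.raises(ValueError):
            welch_psd(_epochs(np.zeros((1, 1, 100)), [0], fs=256.0))


class TestErpTrend:
    def test_polynomial_input_reproduced(self):
        xs = np.linspace(-1, 1, 200)
        y = 3 * xs ** 5 - xs ** 2 + 0.5
        fit = erp_trend(y, order=15)
        assert np.max(np.abs(fit - y)) / np.max(np.abs(y)) < 1e-6

    def test_constant_input_constant_trend(self):
        fit = erp_trend(np.full(64, 2.0), order=15)
        assert np.allclose(fit, 2.0, atol=1e-8)

    def test_matches_normal_equation_oracle(self):
        rng = np.random.default_rng(7)
        y = rng.normal(size=120)
        xs = np.linspace(-1, 1, 120)
        design = np.vander(xs, 16, increasing=True)
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        assert np.allclose(erp_trend(y, order=15), design @ coef, atol=1e-6)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            erp_trend(np.zeros(10), order=15)


class TestClassificationMetrics:
    def test_printed_formula_confusion_case(self):
        m = metrics_from_confusion(tp=3, fp=1, tn=5, fn=1)
        assert m["Acc"] == pytest.approx(0.8)
        assert m["Pre"] == pytest.approx(0.75)
        assert m["Rec"] == pytest.approx(0.75)
        assert m["F1"] == pytest.approx(0.75)

    def test_pairwise_auc_with_tie(self):
        y = np.array([1, 1, 0, 0])
        s = np.array([0.9, 0.5, 0.5, 0.1])
        assert pairwise_auc(y == 1, s) == pytest.approx(0.875)

    def test_perfect_predictions_all_ones(self):
        y = np.array([0, 0, 1, 1])
        s = np.array([0.1, 0.2, 0.8, 0.9])
        m = classification_metrics(y, s)
        assert (m.Acc, m.Pre, m.Rec, m.F1, m.AUC) == (1, 1, 1, 1, 1)

    def test_auc_matches_sklearn_and_is_rank_invariant(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(8)
        y = rng.integers(0, 2, size=60)
        y[:2] = [0, 1]
        s = rng.normal(size=60)
        ours = pairwise_auc(y == 1, s)
        assert ours == pytest.approx(roc_auc_score(y, s), abs=1e-12)
        assert pairwise_auc(y == 1, np.exp(3 * s)) == pytest.approx(ours)

    def test_single_class_auc_undefined(self):
        with pytest.raises(ValueError):
            classification_metrics(np.zeros(5), np.linspace(0, 1, 5))

    def test_multiclass_macro_reduction(self):
        y = np.array([0, 1, 2, 0, 1, 2])
        scores = np.eye(3)[y]  # perfect one-hot
        m = classification_metrics(y, scores)
        assert m.Acc == m.Pre == m.Rec == m.F1 == m.AUC == 1.0
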