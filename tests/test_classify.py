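"""CSP, shrinkage LDA, and cross-validation."""

import dataclasses

import numpy as np
import pytest
from scipy import linalg
from sklearn.covariance import ledoit_wolf_shrinkage

import earbci as eb
from earbci.preprocessing import EpochSet


def _random_spd(n, rng, scale=1.0):
    a = rng.standard_normal((n, 2 * n))
    return scale * (a @ a.T) / (2 * n)


def _gaussian_epochs(n_trials=40, n_ch=6, fs=200.0, seed=0, separable=False):
    rng = np.random.default_rng(seed)
    t = np.arange(int(12 * fs)) / fs - 2.0
    data = rng.standard_normal((n_trials, n_ch, len(t)))
    labels = np.array(["MA"] * (n_trials // 2) + ["LC"] * (n_trials // 2))
    if separable:
        tone = np.sin(2 * np.pi * 10 * t)
        data[labels == "MA", 0, :] += 5 * tone
    chans = tuple(f"c{i}" for i in range(n_ch))
    return EpochSet(data, labels, chans, t, fs)


class TestClassCovariances:
    def test_trace_normalization(self):
        ep = _gaussian_epochs(seed=1)
        c1, c2 = eb.class_covariances(ep)
        assert np.trace(c1) == pytest.approx(1.0)
        assert np.trace(c2) == pytest.approx(1.0)

    def test_identical_trials(self):
        ep = _gaussian_epochs(n_trials=4, seed=2)
        ep.data[1] = ep.data[0]
        ep.data[2] = ep.data[3]
        ep.labels[:] = ["MA", "MA", "LC", "LC"]
        c1, c2 = eb.class_covariances(ep)
        mask = ep.time_mask((0, 10))
        x = ep.data[2][:, mask]
        x = x - x.mean(axis=1, keepdims=True)     # demeaned within task window
        s = x @ x.T
        np.testing.assert_allclose(c1, s / np.trace(s), atol=1e-12)

    def test_hand_case_2x2(self):
        # two trials of one class, 2 channels, direct covariance definition
        fs, t = 10.0, np.arange(120) / 10.0 - 2.0
        data = np.zeros((4, 2, len(t)))
        rng = np.random.default_rng(0)
        data[:] = rng.standard_normal(data.shape)
        ep = EpochSet(data, np.array(["A", "A", "B", "B"]), ("x", "y"), t, fs)
        c1, _ = eb.class_covariances(ep, classes=["A", "B"])
        mask = ep.time_mask((0, 10))
        expected = np.zeros((2, 2))
        for i in range(2):
            x = data[i][:, mask]
            x = x - x.mean(axis=1, keepdims=True)
            s = x @ x.T / mask.sum()
            expected += s / np.trace(s) / 2
        np.testing.assert_allclose(c1, expected, atol=1e-12)

    def test_single_class_rejected(self):
        ep = _gaussian_epochs(seed=3)
        ep.labels[:] = "MA"
        with pytest.raises(ValueError):
            eb.class_covariances(ep)


class TestCspFit:
    def test_equal_covariances_give_half_eigenvalues(self):
        rng = np.random.default_rng(0)
        c = _random_spd(6, rng)
        model = eb.csp_fit(c, c, n_keep=2, ridge=0.0)
        np.testing.assert_allclose(model.eigenvalues, 0.5, atol=1e-10)
        # the default ridge perturbs the symmetric problem only marginally
        model = eb.csp_fit(c, c, n_keep=2)
        np.testing.assert_allclose(model.eigenvalues, 0.5, atol=1e-5)

    def test_diagonal_hand_case(self):
        c1 = np.diag([2.0, 1.0]) / 3
        c2 = np.diag([1.0, 2.0]) / 3
        model = eb.csp_fit(c1, c2, n_keep=1)
        np.testing.assert_allclose(model.eigenvalues, [2 / 3, 1 / 3], atol=1e-12)
        # filters along coordinate axes
        w = model.filters / np.abs(model.filters).max(axis=0)
        np.testing.assert_allclose(np.abs(w), np.eye(2), atol=1e-9)

    def test_whitening_property(self):
        rng = np.random.default_rng(1)
        c1, c2 = _random_spd(6, rng), _random_spd(6, rng)
        model = eb.csp_fit(c1, c2, n_keep=2, ridge=0.0)
        w = model.filters
        np.testing.assert_allclose(w.T @ (c1 + c2) @ w, np.eye(w.shape[1]),
                                   atol=1e-8)

    def test_matches_brute_force_generalized_eigensolve(self):
        """Oracle: direct generalized eigensolve of (C1, C1+C2)."""
        rng = np.random.default_rng(2)
        for _ in range(10):
            c1, c2 = _random_spd(6, rng), _random_spd(6, rng)
            model = eb.csp_fit(c1, c2, n_keep=2, ridge=0.0)
            ref_vals, ref_vecs = linalg.eigh(c1, c1 + c2)
            np.testing.assert_allclose(model.eigenvalues, ref_vals[::-1],
                                       atol=1e-8)
            for j in range(6):
                w, v = model.filters[:, j], ref_vecs[:, 5 - j]
                # same filter up to sign
                assert min(np.abs(w - v).max(), np.abs(w + v).max()) < 1e-8

    def test_eigenvalue_pairing(self):
        rng = np.random.default_rng(3)
        c1, c2 = _random_spd(6, rng), _random_spd(6, rng)
        a = eb.csp_fit(c1, c2, n_keep=2, ridge=0.0)
        b = eb.csp_fit(c2, c1, n_keep=2, ridge=0.0)
        np.testing.assert_allclose(a.eigenvalues + b.eigenvalues[::-1], 1.0,
                                   atol=1e-9)

    def test_rank_deficient_composite(self):
        # CAR-like: project out the constant vector -> rank 5
        rng = np.random.default_rng(4)
        P = np.eye(6) - np.ones((6, 6)) / 6
        c1 = P @ _random_spd(6, rng) @ P
        c2 = P @ _random_spd(6, rng) @ P
        model = eb.csp_fit(c1, c2, n_keep=2)
        assert model.filters.shape[1] == 5      # null direction discarded
        assert len(model.selected) == 4

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            eb.csp_fit(np.eye(4), np.eye(5))
        with pytest.raises(ValueError):
            eb.csp_fit(np.eye(4), np.eye(4), n_keep=3)


class TestMultibandFeatures:
    def test_feature_count(self):
        ep = _gaussian_epochs(seed=5)
        F, models = eb.multiband_csp_features(ep, n_keep=2)
        assert F.shape == (40, 20)
        assert set(models) == {"delta", "theta", "alpha", "beta", "gamma"}

    def test_scaling_shifts_log_variance(self):
        ep = _gaussian_epochs(seed=6)
        F1, models = eb.multiband_csp_features(ep)
        scaled = dataclasses.replace(ep, data=ep.data * 3.0)
        F2, _ = eb.multiband_csp_features(scaled, models=models)
        np.testing.assert_allclose(F2 - F1, 2 * np.log(3.0), atol=1e-9)

    def test_fit_then_apply_consistency(self):
        ep = _gaussian_epochs(seed=7)
        F1, models = eb.multiband_csp_features(ep)
        F2, _ = eb.multiband_csp_features(ep, models=models)
        np.testing.assert_allclose(F1, F2, atol=1e-12)

    def test_band_above_nyquist(self):
        ep = _gaussian_epochs(seed=8, fs=80.0)
        with pytest.raises(ValueError, match="Nyquist"):
            eb.multiband_csp_features(ep)


class TestLedoitWolf:
    def test_matches_sklearn(self):
        rng = np.random.default_rng(0)
        for n, p in [(50, 5), (30, 10), (200, 8)]:
            X = rng.standard_normal((n, p)) @ np.diag(rng.uniform(0.5, 3.0, p))
            mine = eb.ledoit_wolf_gamma(X)
            ref = float(ledoit_wolf_shrinkage(X, assume_centered=False))
            assert mine == pytest.approx(ref, abs=1e-10)

    def test_small_for_anisotropic_large_n(self):
        # strongly structured covariance, many samples: little shrinkage
        rng = np.random.default_rng(1)
        X = rng.standard_normal((10_000, 4)) * np.array([10.0, 1.0, 1.0, 0.1])
        assert eb.ledoit_wolf_gamma(X) < 0.1

    def test_large_when_undersampled(self):
        # p >> n: the sample covariance is untrustworthy, shrinkage dominates
        rng = np.random.default_rng(2)
        X = rng.standard_normal((6, 20))
        assert eb.ledoit_wolf_gamma(X) > 0.5

    def test_two_sample_degenerate_case(self):
        # with n=2 the two centered rank-1 estimates coincide with S, so
        # the estimated estimation-variance (and hence gamma) collapses to 0
        rng = np.random.default_rng(3)
        X = rng.standard_normal((2, 20))
        mine = eb.ledoit_wolf_gamma(X)
        ref = float(ledoit_wolf_shrinkage(X, assume_centered=False))
        assert mine == pytest.approx(ref, abs=1e-10)
        assert mine == pytest.approx(0.0, abs=1e-10)

    def test_constant_input(self):
        assert eb.ledoit_wolf_gamma(np.ones((10, 3))) == 1.0

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            eb.ledoit_wolf_gamma(np.ones((1, 3)))


class TestSlda:
    def test_separated_clouds_perfect_training(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.standard_normal((30, 4)) + 20,
                       rng.standard_normal((30, 4))])
        y = np.array(["B"] * 30 + ["A"] * 30)
        model = eb.slda_fit(X, y)
        assert (eb.slda_predict(model, X) == y).all()
        assert 0 <= model.gamma <= 1

    def test_recovers_bayes_direction(self):
        rng = np.random.default_rng(1)
        sigma = np.array([[2.0, 0.8, 0.0], [0.8, 1.0, 0.2], [0.0, 0.2, 0.5]])
        L = np.linalg.cholesky(sigma)
        dmu = np.array([1.0, -0.5, 0.25])
        X = np.vstack([rng.standard_normal((5000, 3)) @ L.T + dmu,
                       rng.standard_normal((5000, 3)) @ L.T])
        y = np.array([1] * 5000 + [0] * 5000)
        model = eb.slda_fit(X, y)
        bayes = np.linalg.solve(sigma, dmu)
        cos = (model.weights @ bayes) / np.linalg.norm(model.weights) / np.linalg.norm(bayes)
        assert np.degrees(np.arccos(np.clip(cos, -1, 1))) < 5.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            eb.slda_fit(np.zeros((4, 2)), np.array(["A"] * 4))


class TestCrossValidate:
    def test_fold_count(self):
        ep = _gaussian_epochs(separable=True, seed=9)
        cv = eb.cross_validate(ep, k=10, reps=10, seed=0)
        assert cv.accuracies.shape == (10, 10)
        assert cv.mean == pytest.approx(cv.accuracies.mean())

    def test_separable_data_high_accuracy(self):
        ep = _gaussian_epochs(separable=True, seed=10)
        cv = eb.cross_validate(ep, k=10, reps=2, seed=0)
        assert cv.mean > 90.0

    def test_random_labels_at_chance(self):
        """Permutation control: with labels carrying no information the
        cross-validated accuracy is unbiased at 50%."""
        ep = _gaussian_epochs(n_trials=60, separable=False, seed=11)
        cv = eb.cross_validate(ep, k=10, reps=3, seed=0)
        half_width = 196 * np.sqrt(0.25 / 60)       # 95% binomial, percent
        assert abs(cv.mean - 50.0) < half_width
        # separable data with shuffled labels, averaged over permutations:
        # residual signal from any single permutation averages out
        sep = _gaussian_epochs(n_trials=60, separable=True, seed=12)
        rng = np.random.default_rng(5)
        means = []
        for _ in range(6):
            shuffled = rng.permutation(sep.labels)
            means.append(eb.cross_validate(sep, labels=shuffled, k=10,
                                           reps=1, seed=0).mean)
        assert abs(np.mean(means) - 50.0) < half_width

    def test_channel_reordering_invariance(self):
        ep = _gaussian_epochs(separable=True, seed=12)
        perm = [3, 0, 5, 1, 4, 2]
        ep2 = EpochSet(ep.data[:, perm, :].copy(), ep.labels.copy(),
                       tuple(ep.channels[i] for i in perm),
                       ep.time_axis.copy(), ep.fs)
        a = eb.cross_validate(ep, k=5, reps=2, seed=3)
        b = eb.cross_validate(ep2, k=5, reps=2, seed=3)
        np.testing.assert_allclose(a.accuracies, b.accuracies, atol=1e-9)

    def test_leaky_ablation_is_distinct_and_off_by_default(self):
        ep = _gaussian_epochs(n_trials=30, seed=13)     # pure noise classes
        honest = eb.cross_validate(ep, k=5, reps=2, seed=1)
        leaky = eb.cross_validate(ep, k=5, reps=2, seed=1, fit_csp_on_all=True)
        assert not np.allclose(honest.accuracies, leaky.accuracies)

    def test_too_few_trials(self):
        ep = _gaussian_epochs(n_trials=10, seed=14)
        with pytest.raises(ValueError):
            eb.cross_validate(ep, k=10)
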