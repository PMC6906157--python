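"""CSP: whitening, generalized-eigenproblem filters, log variance-share features."""

import numpy as np
import pytest

from brainfe.csp import (
    CSPModel,
    extract_features,
    fit_csp,
    fit_csp_pipeline,
    reduce_whiten,
)
from brainfe.preprocess import EpochSet, average_reference


def orthogonal_waves(n_samples=256):
    """Exactly orthogonal equal-power waveforms over full periods."""
    t = np.arange(n_samples)
    return np.cos(2 * np.pi * 4 * t / n_samples), np.sin(2 * np.pi * 4 * t / n_samples)


def toy_classes(sd1=(3.0, 1.0), sd2=(1.0, 3.0), n_trials=5):
    """2-channel trials with independent channels of known variance."""
    c, s = orthogonal_waves()
    x1 = np.tile(np.stack([sd1[0] * c, sd1[1] * s]), (n_trials, 1, 1))
    x2 = np.tile(np.stack([sd2[0] * c, sd2[1] * s]), (n_trials, 1, 1))
    return x1, x2


class TestReduceWhiten:
    def test_white_noise_average_referenced_keeps_rank_n_minus_1(self):
        rng = np.random.default_rng(0)
        epochs = average_reference(EpochSet(data=rng.standard_normal((60, 8, 307))))
        wh = reduce_whiten(epochs.data)
        assert wh.n_rank == 7

    def test_low_dimensional_subspace_detected(self):
        rng = np.random.default_rng(1)
        basis = rng.standard_normal((8, 3))
        latent = rng.standard_normal((40, 3, 200))
        data = np.einsum("ck,tks->tcs", basis, latent)
        assert reduce_whiten(data).n_rank == 3

    def test_transformed_pooled_covariance_is_identity(self):
        rng = np.random.default_rng(2)
        data = rng.standard_normal((50, 6, 300)) * rng.uniform(0.5, 3, size=(1, 6, 1))
        wh = reduce_whiten(data, variance_fraction=1.0)
        covs = np.einsum("tcs,tds->tcd", data, data) / data.shape[-1]
        traces = np.trace(covs, axis1=1, axis2=2)
        pooled = (covs / traces[:, None, None]).mean(axis=0)
        assert np.allclose(wh.W @ pooled @ wh.W.T, np.eye(wh.n_rank), atol=1e-6)

    def test_rank_deficient_below_two_components(self):
        data = np.zeros((10, 4, 100))
        data[:, 0, :] = np.random.default_rng(3).standard_normal((10, 100))
        with pytest.raises(ValueError):
            reduce_whiten(data)


class TestFitCSP:
    def test_closed_form_two_channel_toy(self):
        """Variances (9,1) vs (1,9) give axis-aligned filters, lambda 0.9/0.1."""
        x1, x2 = toy_classes()
        model = fit_csp(x1, x2)
        assert model.eigenvalues == pytest.approx([0.9, 0.1], abs=1e-8)
        for w in model.filters:
            w = np.abs(w / np.linalg.norm(w))
            assert max(w) == pytest.approx(1.0, abs=1e-8)  # axis aligned

    def test_identical_class_covariances_give_half(self):
        x1, _ = toy_classes()
        model = fit_csp(x1, x1.copy())
        assert np.allclose(model.eigenvalues, 0.5, atol=1e-10)

    def test_matches_independent_eigensolver(self):
        """Filters agree (up to sign) with a brute-force eigensolution."""
        rng = np.random.default_rng(7)
        x1 = rng.standard_normal((30, 6, 200))
        x2 = rng.standard_normal((30, 6, 200)) * rng.uniform(0.5, 2, size=(1, 6, 1))
        model = fit_csp(x1, x2)

        def avg_cov(x):
            covs = np.einsum("tcs,tds->tcd", x, x) / x.shape[-1]
            tr = np.trace(covs, axis1=1, axis2=2)
            return (covs / tr[:, None, None]).mean(axis=0)

        S1, S2 = avg_cov(x1), avg_cov(x2)
        evals, evecs = np.linalg.eig(np.linalg.solve(S1 + S2, S1))
        order = np.argsort(np.maximum(evals.real, 1 - evals.real))[::-1]
        evals, evecs = evals.real[order], evecs.real[:, order]
        assert np.allclose(model.eigenvalues, evals, atol=1e-8)
        for w_model, w_ref in zip(model.filters, evecs.T):
            wm = w_model / np.linalg.norm(w_model)
            wr = w_ref / np.linalg.norm(w_ref)
            assert min(np.abs(wm - wr).max(), np.abs(wm + wr).max()) < 1e-6

    def test_paired_variance_normalization(self):
        """w' S1 w = lambda and w' S2 w = 1 - lambda under the fit normalization."""
        x1, x2 = toy_classes(sd1=(2.0, 1.0), sd2=(1.0, 1.5))
        model = fit_csp(x1, x2)
        # trace-normalized analytic covariances
        S1 = np.diag([4.0, 1.0]) / 5.0
        S2 = np.diag([1.0, 2.25]) / 3.25
        for w, lam in zip(model.filters, model.eigenvalues):
            assert w @ S1 @ w == pytest.approx(lam, abs=1e-8)
            assert w @ S2 @ w == pytest.approx(1 - lam, abs=1e-8)

    def test_singular_pooled_covariance_rejected(self):
        x = np.zeros((10, 3, 100))
        x[:, 0] = np.random.default_rng(0).standard_normal((10, 100))
        x[:, 1] = x[:, 0]
        x[:, 2] = np.random.default_rng(1).standard_normal((10, 100))
        with pytest.raises(np.linalg.LinAlgError):
            fit_csp(x, x * 2)


class TestFeatures:
    def test_single_filter_gives_zero(self):
        x1, x2 = toy_classes()
        model = fit_csp(x1, x2)
        single = CSPModel(
            filters=model.filters[:1],
            patterns=model.patterns[:, :1],
            eigenvalues=model.eigenvalues[:1],
            n_rank=1,
        )
        f = extract_features(x1, single)
        assert np.allclose(f.to_numpy(), 0.0, atol=1e-12)

    def test_scale_invariance(self):
        x1, x2 = toy_classes()
        model = fit_csp(x1, x2)
        f = extract_features(x1, model).to_numpy()
        f_scaled = extract_features(7.3 * x1, model).to_numpy()
        assert np.allclose(f, f_scaled, atol=1e-12)

    def test_exp_features_sum_to_one(self):
        rng = np.random.default_rng(4)
        x1 = rng.standard_normal((20, 5, 150))
        x2 = rng.standard_normal((20, 5, 150)) * 1.5
        model = fit_csp(x1, x2)
        f = extract_features(np.concatenate([x1, x2]), model).to_numpy()
        assert np.allclose(np.exp(f).sum(axis=1), 1.0, atol=1e-9)

    def test_hand_computed_two_trial_case(self):
        """Direct evaluation of the log variance-share formula."""
        c, s = orthogonal_waves(128)
        trials = np.stack(
            [np.stack([2 * c, 1 * s]), np.stack([1 * c, 3 * s])]
        )  # 2 trials x 2 ch x 128
        model = CSPModel(
            filters=np.eye(2), patterns=np.eye(2), eigenvalues=np.array([0.5, 0.5]), n_rank=2
        )
        f = extract_features(trials, model).to_numpy()
        v = trials.var(axis=-1)
        expected = np.log(v / v.sum(axis=1, keepdims=True))
        assert np.allclose(f, expected, atol=1e-12)

    def test_zero_variance_trial_rejected(self):
        model = CSPModel(
            filters=np.eye(2), patterns=np.eye(2), eigenvalues=np.array([0.5, 0.5]), n_rank=2
        )
        with pytest.raises(ValueError):
            extract_features(np.zeros((1, 2, 50)), model)


class TestPipelineDiscriminability:
    def test_separability_and_pattern_recovery_at_snr_2(self):
        """Top CSP features separate perception classes; leading pattern
        correlates with the injected topography (sign-invariant)."""
        from brainfe.synthetic import CohortConfig, simulate_behavior, simulate_epochs

        cfg = CohortConfig(n_trials=120, p=0.7, snr=2.0, n_channels=16, artifact_rate=0.0)
        nu = np.random.default_rng(0).permutation(np.repeat([1, 2], 60))
        trials = simulate_behavior(nu, p=0.7, rng_seed=1)
        epochs = simulate_epochs(trials, cfg, rng_seed=2)
        mu = trials["mu_true"].to_numpy()
        features, model, _ = fit_csp_pipeline(epochs, mu)

        # linear separation of the two perception classes on the top-2 features
        from sklearn.linear_model import LogisticRegression

        top2_idx = [0, model.n_rank - 1]  # most class-1 and most class-2 specific
        X = features.to_numpy()[:, top2_idx]
        clf = LogisticRegression().fit(X, mu)
        assert clf.score(X, mu) >= 0.90

        # recover the injected topographies from the extreme patterns
        from brainfe.preprocess import channel_positions, default_channel_names
        from brainfe.synthetic import _smooth_topography

        rng = np.random.default_rng(2)
        pos = channel_positions(default_channel_names(16))
        _ = np.linalg.qr(rng.standard_normal((16, 16)))  # replay generator draws
        a1 = _smooth_topography(rng, pos)
        a2 = _smooth_topography(rng, pos)
        a2 = a2 - (a2 @ a1) * a1
        a2 /= np.linalg.norm(a2)
        patterns = model.patterns
        best = max(
            abs(np.corrcoef(patterns[:, 0], a1)[0, 1]),
            abs(np.corrcoef(patterns[:, 0], a2)[0, 1]),
        )
        assert best >= 0.9
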