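"""Recognition distribution: clustering, mapping, SVM posteriors, averaging."""

import numpy as np
import pandas as pd
import pytest

from brainfe.recognition import (
    cluster_perceptions,
    estimate_recognition,
    map_clusters_to_perceptions,
    repeat_and_average,
    svm_cv_posteriors,
    tune_svm,
)


def blobs(n_per=30, sep=8.0, seed=0, dim=2):
    rng = np.random.default_rng(seed)
    a = rng.standard_normal((n_per, dim))
    b = rng.standard_normal((n_per, dim)) + sep
    x = np.vstack([a, b])
    y = np.repeat([1, 2], n_per)
    return x, y


class TestKMeans:
    def test_separated_blobs_are_pure(self):
        x, y = blobs()
        c = cluster_perceptions(x, rng_seed=0)
        # each cluster contains exactly one blob
        assert len(set(c[:30])) == 1 and len(set(c[30:])) == 1 and c[0] != c[-1]

    def test_identical_points_rejected(self):
        with pytest.raises(ValueError):
            cluster_perceptions(np.ones((10, 3)), rng_seed=0)

    def test_matches_exhaustive_partition_minimizer(self):
        """Best-of-seeds K-means equals the global WCSS minimizer on 12 points."""
        rng = np.random.default_rng(3)
        x = rng.standard_normal((12, 2)) + np.repeat([[0, 0], [3, 3]], 6, axis=0)

        def wcss(labels):
            tot = 0.0
            for g in (0, 1):
                pts = x[labels == g]
                if len(pts):
                    tot += ((pts - pts.mean(0)) ** 2).sum()
            return tot

        best_km, best_cost = None, np.inf
        for seed in range(10):
            c = cluster_perceptions(x, rng_seed=seed)
            if wcss(c) < best_cost:
                best_km, best_cost = c, wcss(c)

        brute_cost = np.inf
        for mask in range(1, 2**11):  # fix point 0 in cluster 0
            labels = np.array([0] + [(mask >> i) & 1 for i in range(11)])
            brute_cost = min(brute_cost, wcss(labels))
        assert best_cost == pytest.approx(brute_cost, rel=1e-12)


class TestClusterMapping:
    @pytest.mark.parametrize(
        "clusters, decisions, expected_mu, expected_agreement",
        [
            ([0, 0, 1, 1], [1, 1, 2, 2], [1, 1, 2, 2], 1.0),
            ([0, 0, 1, 1], [2, 2, 1, 1], [2, 2, 1, 1], 1.0),
            ([0, 1, 0, 1], [1, 1, 2, 2], [1, 2, 1, 2], 0.5),  # tie -> 0 maps to 1
        ],
    )
    def test_bijection_choice(self, clusters, decisions, expected_mu, expected_agreement):
        mu, agree = map_clusters_to_perceptions(clusters, decisions)
        assert mu.tolist() == expected_mu
        assert agree == expected_agreement

    def test_agreement_at_least_half(self):
        rng = np.random.default_rng(0)
        c = rng.integers(0, 2, 101)
        d = rng.integers(1, 3, 101)
        _, agree = map_clusters_to_perceptions(c, d)
        assert agree >= 0.5


class TestTuneSVM:
    def test_easy_problem_reaches_high_accuracy(self):
        x, y = blobs(n_per=40, sep=6.0, seed=1)
        sigma, box = tune_svm(x, y, rng_seed=0, budget=15)
        from brainfe.recognition import _cv_accuracy

        acc = _cv_accuracy(x, y, sigma, box, 10, np.random.default_rng(0))
        assert acc >= 0.95

    def test_pure_noise_labels_stay_near_chance(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((300, 4))
        y = rng.integers(1, 3, 300)
        sigma, box = tune_svm(x, y, rng_seed=3, budget=15)
        from brainfe.recognition import _cv_accuracy

        acc = _cv_accuracy(x, y, sigma, box, 10, np.random.default_rng(1))
        assert 0.4 <= acc <= 0.6

    def test_deterministic_under_seed(self):
        x, y = blobs(seed=4)
        assert tune_svm(x, y, rng_seed=5, budget=10) == tune_svm(x, y, rng_seed=5, budget=10)

    def test_small_budget_warns(self):
        x, y = blobs(seed=5)
        with pytest.warns(UserWarning):
            tune_svm(x, y, rng_seed=0, budget=3)


class TestPosteriors:
    def test_pairs_sum_to_one_everywhere(self):
        x, y = blobs(n_per=25, sep=1.0, seed=6)
        post, pred = svm_cv_posteriors(x, y, sigma=1.0, box=1.0, rng_seed=0)
        assert np.allclose(post.sum(axis=1), 1.0, atol=1e-9)
        assert not np.isnan(post).any()
        assert set(pred) <= {1, 2}

    def test_separable_data_confident_posteriors(self):
        x, y = blobs(n_per=30, sep=8.0, seed=7)
        post, pred = svm_cv_posteriors(x, y, sigma=3.0, box=10.0, rng_seed=1)
        true_post = post[np.arange(len(y)), y - 1]
        assert true_post.mean() >= 0.9
        assert (pred == y).mean() >= 0.95

    def test_shuffled_labels_predict_at_chance(self):
        rng = np.random.default_rng(8)
        x = rng.standard_normal((200, 3))
        y = rng.permutation(np.repeat([1, 2], 100))
        post, pred = svm_cv_posteriors(x, y, sigma=1.0, box=1.0, rng_seed=2)
        assert abs((pred == y).mean() - 0.5) < 0.15

    def test_too_few_trials_per_class(self):
        x, y = blobs(n_per=5)
        with pytest.raises(ValueError):
            svm_cv_posteriors(x, y, sigma=1.0, box=1.0, folds=10)


class TestEstimateRecognition:
    def test_pure_posteriors_single_group(self):
        post = np.tile([1.0, 0.0], (5, 1))
        # second group needed to avoid the empty-group error
        post = np.vstack([post, np.tile([0.2, 0.8], (3, 1))])
        mu = np.array([1] * 5 + [2] * 3)
        Q = estimate_recognition(post, mu)
        assert np.allclose(Q[0], [1.0, 0.0])
        assert np.allclose(Q[1], [0.2, 0.8])

    def test_hand_average(self):
        post = np.array([[0.8, 0.2], [0.6, 0.4], [0.5, 0.5]])
        mu = np.array([1, 1, 2])
        Q = estimate_recognition(post, mu)
        assert np.allclose(Q[0], [0.7, 0.3], atol=1e-12)

    def test_uniform_posteriors_give_uniform_Q(self):
        post = np.full((10, 2), 0.5)
        mu = np.array([1, 2] * 5)
        assert np.allclose(estimate_recognition(post, mu), 0.5)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            estimate_recognition(np.full((4, 2), 0.5), np.array([1, 1, 1, 1]))


class TestRepeatAndAverage:
    def make_table(self, y, d=None):
        return pd.DataFrame(
            {"true_category": y, "decision": y if d is None else d, "responded": True}
        )

    def test_deterministic_under_seed(self):
        x, y = blobs(n_per=20, sep=2.0, seed=9)
        t = self.make_table(y)
        r1 = repeat_and_average(x, t, n_repeats=5, rng_seed=11)
        r2 = repeat_and_average(x, t, n_repeats=5, rng_seed=11)
        assert np.array_equal(r1.Q, r2.Q)
        assert r1.hyperparams == r2.hyperparams
        assert np.array_equal(r1.per_trial_mu, r2.per_trial_mu)

    def test_rows_stochastic_and_diagnostics(self):
        x, y = blobs(n_per=20, sep=2.0, seed=10)
        r = repeat_and_average(x, self.make_table(y), n_repeats=5, rng_seed=0)
        assert np.allclose(r.Q.sum(axis=1), 1.0, atol=1e-9)
        assert 0.5 <= r.kmeans_agreement <= 1.0
        assert 0.0 <= r.svm_cv_accuracy <= 1.0

    def test_single_repeat_equals_one_pass(self):
        """n_repeats=1 reproduces a single cluster/posterior/average pass."""
        x, y = blobs(n_per=15, sep=3.0, seed=12)
        t = self.make_table(y)
        r = repeat_and_average(x, t, n_repeats=1, rng_seed=21, sigma=2.0, box=5.0)
        root = np.random.SeedSequence(21)
        _, rep = root.spawn(2)
        s_km, s_cv = rep.spawn(2)
        clusters = cluster_perceptions(x, rng_seed=s_km)
        mu, _ = map_clusters_to_perceptions(clusters, y)
        post, _ = svm_cv_posteriors(x, y, 2.0, 5.0, rng_seed=s_cv)
        assert np.allclose(r.Q, estimate_recognition(post, mu), atol=1e-12)

    def test_recovers_perception_category_agreement(self, snr_battery):
        """At snr=2 the averaged Q diagonal tracks the empirical
        perception-category agreement within 0.1."""
        entry = snr_battery[2.0]
        trials = entry["trials"]
        used = trials[trials["decision"].isin([1, 2]) & ~trials["artifact"]]
        agreement = (used["mu_true"] == used["true_category"]).mean()
        Q = entry["result"].recognition.Q
        diag = 0.5 * (Q[0, 0] + Q[1, 1])
        assert diag == pytest.approx(agreement, abs=0.1)
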