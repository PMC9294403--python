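"""Distribution calibration: statistics, Tukey transform, neighbor selection,
calibrated moments, Gaussian sampling, classifier retraining."""

import numpy as np
import pytest

from fscc.calibration import (BaseClassStatistics, CalibrationConfig, calibrate,
                              compute_base_statistics, load_base_statistics,
                              sample_calibrated_features,
                              save_base_statistics, select_nearest_base_classes,
                              train_calibrated_classifier, tukey_transform)


def stats_brute_force(features, labels):
    """Plain-loop mean/covariance oracle (divisor n-1)."""
    means, covs = {}, {}
    for c in sorted(set(labels.tolist())):
        x = features[labels == c]
        mu = x.sum(axis=0) / len(x)
        d = x - mu
        covs[c] = sum(np.outer(row, row) for row in d) / (len(x) - 1)
        means[c] = mu
    return means, covs


class TestBaseStatistics:
    def test_hand_example(self):
        feats = np.array([[0.0, 0.0], [2.0, 2.0]])
        stats = compute_base_statistics(feats, np.array([7, 7]))
        assert np.allclose(stats.means[0], [1, 1])
        assert np.allclose(stats.covariances[0], [[2, 2], [2, 2]])

    def test_identical_vectors_zero_covariance(self):
        feats = np.tile([1.0, 2.0, 3.0], (4, 1))
        stats = compute_base_statistics(feats, np.zeros(4, dtype=int))
        assert np.allclose(stats.covariances[0], 0)

    def test_matches_brute_force_oracle(self, rng):
        feats = rng.random((50, 6))
        labels = rng.integers(0, 5, size=50)
        stats = compute_base_statistics(feats, labels)
        means, covs = stats_brute_force(feats, labels)
        for i, c in enumerate(stats.class_ids):
            assert np.allclose(stats.means[i], means[c], atol=1e-10)
            assert np.allclose(stats.covariances[i], covs[c], atol=1e-10)

    def test_hdf5_cache_round_trip(self, rng, tmp_path):
        feats = rng.random((20, 4))
        labels = np.repeat([3, 7], 10)
        stats = compute_base_statistics(feats, labels)
        save_base_statistics(stats, tmp_path / "stats.h5")
        back = load_base_statistics(tmp_path / "stats.h5")
        assert np.array_equal(back.class_ids, stats.class_ids)
        assert np.allclose(back.means, stats.means)
        assert np.allclose(back.covariances, stats.covariances)
        assert np.array_equal(back.counts, stats.counts)

    def test_undersized_class_rejected(self):
        with pytest.raises(ValueError, match="class 3"):
            compute_base_statistics(np.ones((3, 2)), np.array([1, 1, 3]))

    def test_optional_transform_applies_tukey_first(self, rng):
        feats = rng.random((10, 3)) + 1.0
        a = compute_base_statistics(feats, np.zeros(10, dtype=int), tukey_lambda=0.5)
        b = compute_base_statistics(np.sqrt(feats), np.zeros(10, dtype=int))
        assert np.allclose(a.means, b.means)


class TestTukeyTransform:
    def test_lambda_one_is_identity(self, rng):
        v = rng.random(8)
        assert np.array_equal(tukey_transform(v, 1.0), v)

    def test_square_root_on_perfect_squares(self):
        assert np.array_equal(tukey_transform(np.array([4.0, 9.0]), 0.5), [2.0, 3.0])

    def test_log_case(self):
        out = tukey_transform(np.array([1.0, np.e]), 0.0)
        assert np.allclose(out, [0.0, 1.0])

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            tukey_transform(np.array([-0.1, 1.0]), 0.5)

    def test_zero_allowed_at_half_power_floored_at_log(self):
        assert tukey_transform(np.array([0.0]), 0.5)[0] == 0.0
        assert np.isfinite(tukey_transform(np.array([0.0]), 0.0)).all()


def _toy_stats(rng, n_classes=6, dim=4):
    means = rng.standard_normal((n_classes, dim))
    covs = np.stack([np.eye(dim) * (i + 1) for i in range(n_classes)])
    return BaseClassStatistics(class_ids=np.arange(n_classes), means=means,
                               covariances=covs, counts=np.full(n_classes, 10))


class TestNeighborSelection:
    def test_exact_match_selected_at_distance_zero(self, rng):
        stats = _toy_stats(rng)
        ids, dists = select_nearest_base_classes(stats.means[3], stats, k=1)
        assert ids[0] == 3 and dists[0] == 0.0

    def test_k_equal_all_selects_everything(self, rng):
        stats = _toy_stats(rng)
        ids, _ = select_nearest_base_classes(rng.standard_normal(4), stats, k=6)
        assert set(ids.tolist()) == set(range(6))

    def test_agrees_with_full_sort(self, rng):
        stats = _toy_stats(rng)
        v = rng.standard_normal(4)
        ids, _ = select_nearest_base_classes(v, stats, k=3)
        brute = np.argsort(np.linalg.norm(stats.means - v, axis=1))[:3]
        assert set(ids.tolist()) == set(stats.class_ids[brute].tolist())

    def test_k_out_of_range(self, rng):
        with pytest.raises(ValueError, match="out of range"):
            select_nearest_base_classes(np.zeros(4), _toy_stats(rng), k=7)


class TestCalibrate:
    def test_k1_fixed_point(self, rng):
        stats = _toy_stats(rng)
        v = stats.means[2]
        dist = calibrate(v, stats, [2], ridge_epsilon=0.0)
        assert np.allclose(dist.mu_prime, v)
        assert np.allclose(dist.sigma_prime, stats.covariances[2])

    def test_hand_mean(self):
        stats = BaseClassStatistics(class_ids=np.array([0, 1]),
                                    means=np.array([[0.0, 0.0], [2.0, 2.0]]),
                                    covariances=np.stack([2 * np.eye(2), 4 * np.eye(2)]),
                                    counts=np.array([5, 5]))
        dist = calibrate(np.array([1.0, 1.0]), stats, [0, 1], ridge_epsilon=0.0)
        assert np.allclose(dist.mu_prime, [1.0, 1.0])
        assert np.allclose(dist.sigma_prime, 3 * np.eye(2))

    def test_selection_order_irrelevant(self, rng):
        stats = _toy_stats(rng)
        v = rng.standard_normal(4)
        a = calibrate(v, stats, [1, 4, 2])
        b = calibrate(v, stats, [4, 2, 1])
        assert np.allclose(a.mu_prime, b.mu_prime)
        assert np.allclose(a.sigma_prime, b.sigma_prime)

    def test_matches_plain_loop_reimplementation(self, rng):
        for _ in range(100):
            n, d, k = rng.integers(2, 9), rng.integers(2, 33), 0
            stats_feats = rng.random((n * 4, d))
            labels = np.repeat(np.arange(n), 4)
            stats = compute_base_statistics(stats_feats, labels)
            v = rng.random(d)
            k = int(rng.integers(1, n + 1))
            ids, _ = select_nearest_base_classes(v, stats, k)
            dist = calibrate(v, stats, ids, ridge_epsilon=0.0)
            # independent loop evaluation
            mu = v.copy()
            sigma = np.zeros((d, d))
            for c in ids:
                i = stats.index_of(c)
                mu = mu + stats.means[i]
                sigma = sigma + stats.covariances[i]
            assert np.allclose(dist.mu_prime, mu / (k + 1), atol=1e-10)
            assert np.allclose(dist.sigma_prime, sigma / k, atol=1e-10)

    def test_empty_selection_rejected(self, rng):
        with pytest.raises(ValueError, match="empty"):
            calibrate(np.zeros(4), _toy_stats(rng), [])


class TestSampling:
    def test_zero_count_empty(self, rng):
        dist = calibrate(np.zeros(4), _toy_stats(rng), [0])
        assert sample_calibrated_features(dist, 0, seed=0).shape == (0, 4)

    def test_degenerate_covariance_collapses_to_mean(self, rng):
        stats = _toy_stats(rng)
        stats.covariances[...] = 0.0
        dist = calibrate(rng.random(4), stats, [0], ridge_epsilon=0.0)
        draws = sample_calibrated_features(dist, 5, seed=1)
        assert np.allclose(draws, dist.mu_prime, atol=1e-12)

    def test_moments_of_large_sample(self, rng):
        stats = _toy_stats(rng)
        dist = calibrate(rng.random(4), stats, [1, 3])
        draws = sample_calibrated_features(dist, 10_000, seed=2)
        se = np.sqrt(np.diag(dist.sigma_prime) / 10_000)
        assert (np.abs(draws.mean(axis=0) - dist.mu_prime) < 3.5 * se).all()
        emp_cov = np.cov(draws, rowvar=False)
        assert np.linalg.norm(emp_cov - dist.sigma_prime) < \
            0.1 * np.linalg.norm(dist.sigma_prime)

    def test_deterministic_under_seed(self, rng):
        dist = calibrate(rng.random(4), _toy_stats(rng), [0, 1])
        a = sample_calibrated_features(dist, 20, seed=9)
        b = sample_calibrated_features(dist, 20, seed=9)
        assert np.array_equal(a, b)


class TestClassifierRetraining:
    def test_training_set_size_counting(self, benchmark, benchmark_stats):
        support = benchmark.novel_features[:5]
        labels = np.arange(5)
        clf = train_calibrated_classifier(support, labels, benchmark_stats,
                                          CalibrationConfig(n_sampled_per_support=150))
        assert clf.n_training_samples_ == 5 * (1 + 150)

    def test_no_sampling_reduces_to_support_only(self, benchmark, benchmark_stats):
        support = benchmark.novel_features[:4]
        labels = np.array([0, 0, 1, 1])
        clf = train_calibrated_classifier(support, labels, benchmark_stats,
                                          CalibrationConfig(n_sampled_per_support=0))
        assert clf.n_training_samples_ == 4

    def test_separates_well_separated_classes(self):
        from fscc.synthetic import FeatureBenchmarkConfig, generate_feature_benchmark
        benchmark = generate_feature_benchmark(FeatureBenchmarkConfig(
            class_mean_scale=3.0, within_class_cov_scale=0.2, seed=6))
        benchmark_stats = compute_base_statistics(benchmark.base_features,
                                                  benchmark.base_labels, tukey_lambda=0.5)
        accs = []
        rng = np.random.default_rng(3)
        for _ in range(10):
            two = rng.choice(np.unique(benchmark.novel_labels), 2, replace=False)
            sup, sup_y, qry, qry_y = [], [], [], []
            for c in two:
                pool = benchmark.novel_features[benchmark.novel_labels == c]
                pick = rng.permutation(len(pool))
                sup.append(pool[pick[0]])
                sup_y.append(c)
                qry.append(pool[pick[1:16]])
                qry_y.extend([c] * 15)
            clf = train_calibrated_classifier(np.array(sup), np.array(sup_y),
                                              benchmark_stats,
                                              CalibrationConfig(seed=int(rng.integers(2**31))))
            accs.append((clf.predict(np.vstack(qry)) == np.array(qry_y)).mean())
        assert np.mean(accs) > 0.9

    def test_dimension_mismatch_rejected(self, benchmark_stats):
        with pytest.raises(ValueError, match="dim"):
            train_calibrated_classifier(np.ones((2, 3)), np.array([0, 1]), benchmark_stats)
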