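"""Loss closed forms, a brute-force contrastive oracle, and stage-1 training."""

import warnings

import numpy as np
import pytest

from fscc.backbone import BackboneConfig, build_backbone, extract_features
from fscc.io_datasets import normalize_volumes
from fscc.pretrain import (LossConfig, PretrainConfig, combined_loss,
                           cross_entropy_loss, pretrain,
                           supervised_contrastive_loss)
from fscc.synthetic import SimulatorConfig, build_synthetic_dataset, default_shapes


def scl_brute_force(z: np.ndarray, y: np.ndarray, tau: float) -> float:
    """Term-by-term loop evaluation of the supervised contrastive loss."""
    m = len(z)
    total = 0.0
    for i in range(m):
        positives = [j for j in range(m) if j != i and y[j] == y[i]]
        if not positives:
            continue
        inner = 0.0
        for j in positives:
            denom = sum(np.exp(z[i] @ z[k] / tau) for k in range(m) if k != i)
            inner += np.log(np.exp(z[i] @ z[j] / tau) / denom)
        total += -inner / len(positives)
    return total


class TestCrossEntropy:
    @pytest.mark.parametrize("n_classes", [2, 5, 13])
    def test_uniform_predictions_give_log_c(self, n_classes):
        probs = np.full((6, n_classes), 1 / n_classes)
        labels = np.arange(6) % n_classes
        assert cross_entropy_loss(probs, labels) == pytest.approx(np.log(n_classes), abs=1e-12)

    def test_one_hot_correct_gives_zero(self):
        probs = np.eye(4)
        assert cross_entropy_loss(probs, np.arange(4)) == pytest.approx(0.0, abs=1e-9)

    def test_direct_evaluation(self):
        assert cross_entropy_loss(np.array([[0.7, 0.3]]), [0]) == pytest.approx(-np.log(0.7))

    def test_zero_probability_is_clamped_not_infinite(self):
        loss = cross_entropy_loss(np.array([[1.0, 0.0]]), [1])
        assert np.isfinite(loss)

    def test_invalid_rows_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            cross_entropy_loss(np.array([[0.5, 0.2]]), [0])


class TestSupervisedContrastive:
    @pytest.mark.parametrize("m", [4, 8, 128])
    def test_identical_embeddings_closed_form(self, m, rng):
        z = np.tile(rng.standard_normal(6), (m, 1))
        z /= np.linalg.norm(z, axis=1, keepdims=True)
        labels = np.arange(m) % 2  # every class has >= 2 members
        assert supervised_contrastive_loss(z, labels, 0.07) == \
            pytest.approx(m * np.log(m - 1), rel=1e-9)

    def test_all_singletons_is_zero_with_warning(self, rng):
        z = rng.standard_normal((3, 4))
        with pytest.warns(UserWarning, match="singleton"):
            assert supervised_contrastive_loss(z, np.array([0, 1, 2]), 0.07) == 0.0

    def test_matches_brute_force_oracle(self, rng):
        z = rng.standard_normal((8, 5))
        z /= np.linalg.norm(z, axis=1, keepdims=True)
        y = np.array([0, 0, 1, 1, 1, 2, 2, 3])  # includes one singleton class
        assert supervised_contrastive_loss(z, y, 0.07) == \
            pytest.approx(scl_brute_force(z, y, 0.07), rel=1e-10)

    def test_invariant_to_relabeling(self, rng):
        z = rng.standard_normal((6, 4))
        y = np.array([0, 0, 1, 1, 2, 2])
        assert supervised_contrastive_loss(z, y, 0.07) == \
            pytest.approx(supervised_contrastive_loss(z, y + 10, 0.07), rel=1e-12)

    def test_decreases_when_positive_pair_moves_closer(self):
        base = np.array([[1.0, 0.0], [0.6, 0.8], [0.0, 1.0], [-1.0, 0.0]])
        closer = base.copy()
        closer[1] = [0.96, 0.28]  # move sample 1 toward its positive, sample 0
        y = np.array([0, 0, 1, 1])
        norm = lambda z: z / np.linalg.norm(z, axis=1, keepdims=True)
        assert supervised_contrastive_loss(norm(closer), y, 0.07) < \
            supervised_contrastive_loss(norm(base), y, 0.07)

    def test_batch_of_one_rejected(self):
        with pytest.raises(ValueError, match="2 samples"):
            supervised_contrastive_loss(np.ones((1, 3)), [0], 0.07)


class TestCombinedLoss:
    def test_lambda_zero_is_pure_cross_entropy(self):
        assert combined_loss(1.7, 9.9, 0.0) == 1.7

    def test_recommended_weight_arithmetic(self):
        assert combined_loss(1.0, 2.0, 0.05) == pytest.approx(1.1)

    @pytest.mark.parametrize("lam", [0.01, 0.05, 0.1])
    def test_linear_in_contrastive_term(self, lam):
        ce, scl = 0.9, 3.0
        assert combined_loss(ce, scl, lam) - ce == pytest.approx(lam * scl)


TINY_BACKBONE = dict(channel_widths=(8,) * 6, pool_blocks=(1, 2), feature_dim=8)


def _tiny_dataset(n_classes=2, samples=8, seed=0, grid=8):
    cfg = SimulatorConfig(n_classes=n_classes, shapes=default_shapes(n_classes, grid),
                         grid_size=grid, samples_per_class=samples, target_snr=5.0,
                         seed=seed)
    ds = build_synthetic_dataset(cfg)
    return normalize_volumes(ds.volumes), ds.labels


class TestPretrainLoop:
    def test_smoke_run_logs_finite_losses(self):
        vols, labels = _tiny_dataset()
        bb = build_backbone(BackboneConfig(**TINY_BACKBONE, input_edge=8), seed=0)
        result = pretrain(bb, vols, labels,
                          PretrainConfig(batch_size=8, epochs=1, learning_rate=1e-3, seed=0),
                          LossConfig())
        assert len(result.log) >= 1
        assert np.isfinite(result.log[["ce", "scl", "total"]].to_numpy()).all()

    def test_separable_two_class_set_reaches_perfect_training_accuracy(self):
        vols, labels = _tiny_dataset(samples=8, seed=1)
        bb = build_backbone(BackboneConfig(**TINY_BACKBONE, input_edge=8), seed=1)
        result = pretrain(bb, vols, labels,
                          PretrainConfig(batch_size=16, epochs=50, learning_rate=1e-3, seed=1),
                          LossConfig())
        feats = extract_features(result.backbone, vols)
        pred = result.head.forward(feats).argmax(axis=1)
        assert (pred == labels).mean() == 1.0

    def test_same_seed_identical_loss_curves(self):
        vols, labels = _tiny_dataset()
        curves = []
        for _ in range(2):
            bb = build_backbone(BackboneConfig(**TINY_BACKBONE, input_edge=8), seed=2)
            result = pretrain(bb, vols, labels,
                              PretrainConfig(batch_size=8, epochs=2, learning_rate=1e-3,
                                             seed=2), LossConfig())
            curves.append(result.log["total"].to_numpy())
        assert np.array_equal(curves[0], curves[1])

    def test_single_class_rejected(self):
        vols, labels = _tiny_dataset()
        bb = build_backbone(BackboneConfig(**TINY_BACKBONE, input_edge=8), seed=0)
        with pytest.raises(ValueError, match="2 base classes"):
            pretrain(bb, vols, np.zeros_like(labels))


def _mean_within_class_cosine(feats, labels):
    sims = []
    z = feats / np.maximum(np.linalg.norm(feats, axis=1, keepdims=True), 1e-12)
    for c in np.unique(labels):
        zc = z[labels == c]
        gram = zc @ zc.T
        sims.append(gram[np.triu_indices(len(zc), k=1)].mean())
    return float(np.mean(sims))


def test_contrastive_term_tightens_within_class_features():
    """With the contrastive term on, within-class cosine similarity of the
    learned features should not fall below plain cross-entropy training
    (majority over seeds)."""
    wins = 0
    for seed in range(3):
        vols, labels = _tiny_dataset(n_classes=3, samples=8, seed=seed, grid=8)
        sims = {}
        for lam in (0.05, 0.0):
            bb = build_backbone(BackboneConfig(**TINY_BACKBONE, input_edge=8), seed=seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                result = pretrain(bb, vols, labels,
                                  PretrainConfig(batch_size=12, epochs=8,
                                                 learning_rate=1e-3, seed=seed),
                                  LossConfig(lambda_scl=lam))
            sims[lam] = _mean_within_class_cosine(
                extract_features(result.backbone, vols), labels)
        wins += sims[0.05] >= sims[0.0]
    assert wins >= 2
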