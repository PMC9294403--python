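"""Stage-2 distribution calibration and classifier retraining.

A novel class seen through one (or a few) support examples yields a biased
estimate of its feature distribution.  Calibration borrows statistics from
the base classes, whose means and covariances are estimated from abundant
data:

1. per base class i: mean mu_i and unbiased covariance Sigma_i (divisor n-1);
2. the support feature v is made more Gaussian by the Tukey ladder of powers,
   elementwise v**lam (log v at lam = 0), default lam = 0.5;
3. the k base classes whose means are nearest (Euclidean) to the transformed
   support vector are selected, ties broken by ascending class id;
4. calibrated statistics:  mu' = (sum of selected means + v~) / (k + 1),
   Sigma' = mean of the selected covariances (+ a small ridge on the
   diagonal before sampling).

Synthetic features are then drawn from N(mu', Sigma') for each support
example and a multinomial logistic classifier is trained on the union of the
transformed support features and all sampled features.  Queries are
classified after the same Tukey transform.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np
from sklearn.linear_model import LogisticRegression

__all__ = ["BaseClassStatistics", "CalibratedDistribution", "CalibrationConfig",
           "CalibratedClassifier", "compute_base_statistics", "tukey_transform",
           "select_nearest_base_classes", "calibrate", "sample_calibrated_features",
           "train_calibrated_classifier", "save_base_statistics",
           "load_base_statistics"]

_TUKEY_LOG_FLOOR = 1e-6


@dataclass
class BaseClassStatistics:
    """Per-base-class feature mean, covariance and sample count."""

    class_ids: np.ndarray   # (C,)
    means: np.ndarray       # (C, D)
    covariances: np.ndarray  # (C, D, D)
    counts: np.ndarray      # (C,)

    def __post_init__(self):
        if not np.isfinite(self.means).all():
            raise ValueError("base-class means must be finite")
        sym_err = np.abs(self.covariances - self.covariances.transpose(0, 2, 1)).max()
        if sym_err > 1e-8:
            raise ValueError("base-class covariances must be symmetric")
        if (self.counts < 2).any():
            raise ValueError("every base class needs n >= 2")

    @property
    def dim(self) -> int:
        return self.means.shape[1]

    def index_of(self, class_id: int) -> int:
        return int(np.flatnonzero(self.class_ids == class_id)[0])


@dataclass
class CalibratedDistribution:
    """Calibrated Gaussian for one novel support example."""

    mu_prime: np.ndarray
    sigma_prime: np.ndarray
    support_feature: np.ndarray     # the Tukey-transformed support vector
    selected_classes: np.ndarray    # the k chosen base class ids


@dataclass(frozen=True)
class CalibrationConfig:
    tukey_lambda: float = 0.5
    k_neighbors: int = 2
    n_sampled_per_support: int = 150
    ridge_epsilon: float | None = None  # None -> 1e-6 * mean diagonal of Sigma'
    seed: int = 0

    def __post_init__(self):
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.n_sampled_per_support < 0:
            raise ValueError("n_sampled_per_support must be >= 0")


def compute_base_statistics(features: np.ndarray, labels: np.ndarray,
                            tukey_lambda: float | None = None) -> BaseClassStatistics:
    """Mean and unbiased covariance (divisor n-1) of each base class.

    Calibration compares base means against *Tukey-transformed* support
    vectors and mixes base covariances into the calibrated Gaussian, so the
    statistics must live in the same space as the transformed features: pass
    the pipeline's ``tukey_lambda`` to transform the base features first
    (None = features are already in the right space).
    """
    features = np.asarray(features, dtype=float)
    if tukey_lambda is not None:
        features = tukey_transform(features, tukey_lambda)
    labels = np.asarray(labels)
    class_ids = np.unique(labels)
    means, covs, counts = [], [], []
    for c in class_ids:
        x = features[labels == c]
        if len(x) < 2:
            raise ValueError(f"base class {c} has n={len(x)} < 2: covariance undefined")
        means.append(x.mean(axis=0))
        covs.append(np.cov(x, rowvar=False, ddof=1))
        counts.append(len(x))
    return BaseClassStatistics(class_ids=class_ids, means=np.stack(means),
                               covariances=np.stack(covs), counts=np.array(counts))


def save_base_statistics(stats: BaseClassStatistics, path) -> None:
    """Cache per-class statistics as HDF5: /class_<id>/{mean,cov,n}."""
    with h5py.File(path, "w") as fh:
        for i, c in enumerate(stats.class_ids):
            grp = fh.create_group(f"class_{int(c)}")
            grp.create_dataset("mean", data=stats.means[i])
            grp.create_dataset("cov", data=stats.covariances[i])
            grp.create_dataset("n", data=int(stats.counts[i]))


def load_base_statistics(path) -> BaseClassStatistics:
    with h5py.File(path, "r") as fh:
        ids = sorted(int(name.split("_", 1)[1]) for name in fh)
        means = np.stack([fh[f"class_{c}/mean"][()] for c in ids])
        covs = np.stack([fh[f"class_{c}/cov"][()] for c in ids])
        counts = np.array([int(fh[f"class_{c}/n"][()]) for c in ids])
    return BaseClassStatistics(class_ids=np.array(ids), means=means,
                               covariances=covs, counts=counts)


def tukey_transform(v: np.ndarray, tukey_lambda: float = 0.5) -> np.ndarray:
    """Tukey ladder of powers, elementwise: v**lam, or log v at lam = 0.

    Features must be nonnegative; entries must be positive when lam <= 0
    (zeros are floored at 1e-6 there, since log 0 diverges).
    """
    v = np.asarray(v, dtype=float)
    if (v < 0).any():
        raise ValueError("Tukey transform requires nonnegative features")
    if tukey_lambda == 0:
        return np.log(np.maximum(v, _TUKEY_LOG_FLOOR))
    if tukey_lambda < 0:
        v = np.maximum(v, _TUKEY_LOG_FLOOR)
    return np.power(v, tukey_lambda)


def select_nearest_base_classes(v_tilde: np.ndarray, stats: BaseClassStatistics,
                                k: int) -> tuple[np.ndarray, np.ndarray]:
    """The k base classes with minimal ||mu_i - v~||_2; ties by ascending id.

    Returns (selected class ids, their distances), distance-sorted.
    """
    if not 1 <= k <= len(stats.class_ids):
        raise ValueError(f"k={k} out of range [1, {len(stats.class_ids)}]")
    distances = np.linalg.norm(stats.means - np.asarray(v_tilde)[None, :], axis=1)
    order = np.lexsort((stats.class_ids, distances))[:k]
    return stats.class_ids[order], distances[order]


def calibrate(v_tilde: np.ndarray, stats: BaseClassStatistics,
              selected_ids, ridge_epsilon: float | None = None) -> CalibratedDistribution:
    """Calibrated mean/covariance from the selected base classes + support.

    mu' averages the k selected base means together with the transformed
    support vector; Sigma' averages the k selected covariances.  A ridge
    (default 1e-6 x mean diagonal) is added to Sigma's diagonal so sampling
    stays well posed when the average is rank deficient.
    """
    selected_ids = np.asarray(selected_ids)
    if selected_ids.size == 0:
        raise ValueError("empty base-class selection")
    v_tilde = np.asarray(v_tilde, dtype=float)
    k = len(selected_ids)
    rows = [stats.index_of(c) for c in selected_ids]
    mu_prime = (stats.means[rows].sum(axis=0) + v_tilde) / (k + 1)
    sigma_prime = stats.covariances[rows].mean(axis=0)
    if ridge_epsilon is None:
        ridge_epsilon = 1e-6 * float(np.trace(sigma_prime)) / stats.dim
    sigma_prime = sigma_prime + ridge_epsilon * np.eye(stats.dim)
    return CalibratedDistribution(mu_prime=mu_prime, sigma_prime=sigma_prime,
                                  support_feature=v_tilde,
                                  selected_classes=selected_ids)


def sample_calibrated_features(dist: CalibratedDistribution, count: int,
                               seed: int) -> np.ndarray:
    """``count`` draws from N(mu', Sigma'); deterministic under the seed."""
    d = len(dist.mu_prime)
    if count == 0:
        return np.empty((0, d))
    eigvals = np.linalg.eigvalsh(dist.sigma_prime)
    if eigvals[0] < -1e-10 * max(1.0, eigvals[-1]):
        raise ValueError(f"calibrated covariance not PSD: smallest eigenvalue {eigvals[0]:.3e}")
    rng = np.random.default_rng(seed)
    return rng.multivariate_normal(dist.mu_prime, dist.sigma_prime, size=count,
                                   method="eigh")


class CalibratedClassifier:
    """Multinomial logistic classifier operating in Tukey-transformed space."""

    def __init__(self, model: LogisticRegression, tukey_lambda: float,
                 n_training_samples: int = 0):
        self._model = model
        self.tukey_lambda = tukey_lambda
        self.n_training_samples_ = n_training_samples

    @property
    def classes_(self) -> np.ndarray:
        return self._model.classes_

    def predict(self, raw_features: np.ndarray) -> np.ndarray:
        """Classify raw (untransformed, nonnegative) query features."""
        return self._model.predict(tukey_transform(raw_features, self.tukey_lambda))

    def predict_transformed(self, transformed_features: np.ndarray) -> np.ndarray:
        return self._model.predict(transformed_features)


def train_calibrated_classifier(support_features: np.ndarray, support_labels: np.ndarray,
                                stats: BaseClassStatistics,
                                config: CalibrationConfig | None = None
                                ) -> CalibratedClassifier:
    """Calibrate every support example and retrain the novel-class classifier.

    For each support feature: Tukey transform, select the k nearest base
    classes, calibrate, draw ``n_sampled_per_support`` synthetic features.
    The classifier trains on all transformed support features plus all
    sampled features.  With ``n_sampled_per_support = 0`` this reduces to a
    plain linear probe on the transformed support set (the no-calibration
    ablation).
    """
    config = config or CalibrationConfig()
    support_features = np.asarray(support_features, dtype=float)
    support_labels = np.asarray(support_labels)
    if support_features.shape[1] != stats.dim:
        raise ValueError(f"support dim {support_features.shape[1]} != "
                         f"base-statistics dim {stats.dim}")
    seeds = np.random.SeedSequence(config.seed).generate_state(len(support_features)) % (2**31)
    xs, ys = [], []
    for i, (v, label) in enumerate(zip(support_features, support_labels)):
        v_tilde = tukey_transform(v, config.tukey_lambda)
        xs.append(v_tilde[None, :])
        ys.append(np.array([label]))
        if config.n_sampled_per_support > 0:
            selected, _ = select_nearest_base_classes(v_tilde, stats, config.k_neighbors)
            dist = calibrate(v_tilde, stats, selected, config.ridge_epsilon)
            draws = sample_calibrated_features(dist, config.n_sampled_per_support,
                                               seed=int(seeds[i]))
            xs.append(draws)
            ys.append(np.full(len(draws), label))
    x = np.vstack(xs)
    y = np.concatenate(ys)
    model = LogisticRegression(C=1.0, max_iter=2000)
    model.fit(x, y)
    return CalibratedClassifier(model, config.tukey_lambda, n_training_samples=len(x))
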