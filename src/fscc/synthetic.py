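"""Synthetic subtomogram simulator and feature-space Gaussian benchmarks.

Real cryo-ET benchmarks (SHREC-style tomograms, experimental subtomogram
collections) are external downloads; this module generates stand-ins with the
same *structure*: several distinct macromolecule-like density classes on a
cubic grid, randomly oriented, corrupted by additive noise at a controlled
signal-to-noise ratio (variance ratio, the SHREC convention) and optionally by
a missing wedge in Fourier space.

It also generates pure feature-space benchmarks — per-class multivariate
Gaussians with known means and covariances — so the distribution-calibration
stage can be tested in isolation, under exactly the Gaussian assumption it
makes.  Novel-class means can be constructed as averages of two base-class
means, which makes ground truth available for parameter-recovery checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
from scipy.ndimage import affine_transform
from scipy.spatial.transform import Rotation

__all__ = [
    "ShapeSpec", "SimulatorConfig", "FeatureBenchmarkConfig",
    "SyntheticDataset", "FeatureBenchmark",
    "generate_shape_density", "rotate_random", "add_noise_to_snr",
    "apply_missing_wedge", "build_synthetic_dataset",
    "generate_feature_benchmark", "save_feature_benchmark",
    "load_feature_benchmark", "default_shapes", "wedge_mask_fraction",
]

SHAPE_KINDS = ("sphere", "ellipsoid", "dumbbell", "rod", "hollow_shell", "l_tetromino")


@dataclass(frozen=True)
class ShapeSpec:
    """One macromolecule-like density class: a geometric primitive + sizes.

    kind: sphere (radius), ellipsoid (semi_axes: 3 reals), dumbbell (radius,
    separation), rod (radius, length), hollow_shell (outer_radius,
    inner_radius), l_tetromino (arm_length, thickness).
    """

    kind: str
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in SHAPE_KINDS:
            raise ValueError(f"unknown shape kind {self.kind!r}; choose from {SHAPE_KINDS}")

    def max_extent(self) -> float:
        """Radius of the bounding sphere, in voxels."""
        p = self.params
        if self.kind == "sphere":
            return p["radius"]
        if self.kind == "ellipsoid":
            return max(p["semi_axes"])
        if self.kind == "dumbbell":
            return p["separation"] / 2 + p["radius"]
        if self.kind == "rod":
            return np.hypot(p["length"] / 2, p["radius"])
        if self.kind == "hollow_shell":
            return p["outer_radius"]
        return p["arm_length"] * np.sqrt(2)  # l_tetromino, generous bound


@dataclass(frozen=True)
class SimulatorConfig:
    n_classes: int
    shapes: tuple[ShapeSpec, ...]
    grid_size: int = 32
    samples_per_class: int = 10
    target_snr: float = 0.5
    wedge_half_angle: float = 90.0  # degrees; 90 = no missing wedge
    seed: int = 0

    def __post_init__(self):
        if self.n_classes != len(self.shapes):
            raise ValueError("n_classes must equal the number of shape specs")
        if self.target_snr <= 0:
            raise ValueError("target_snr must be positive")
        if self.samples_per_class < 1:
            raise ValueError("samples_per_class must be >= 1")
        if not 0 < self.wedge_half_angle <= 90:
            raise ValueError("wedge_half_angle must be in (0, 90]")
        if self.grid_size < 8:
            raise ValueError("grid_size must be >= 8")
        for s in self.shapes:
            if s.max_extent() > self.grid_size / 2:
                raise ValueError(f"shape {s.kind} does not fit inside the grid")


@dataclass(frozen=True)
class FeatureBenchmarkConfig:
    """Per-class Gaussian feature benchmark with known ground truth."""

    n_base_classes: int = 8
    n_novel_classes: int = 5
    dim: int = 16
    samples_per_base_class: int = 100
    samples_per_novel_class: int = 100
    class_mean_scale: float = 1.0
    within_class_cov_scale: float = 0.5
    novel_from_base_mixture: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.dim < 2:
            raise ValueError("dim must be >= 2")
        if self.class_mean_scale <= 0 or self.within_class_cov_scale <= 0:
            raise ValueError("scales must be positive")
        if self.novel_from_base_mixture and self.n_base_classes < 2:
            raise ValueError("mixture novels need >= 2 base classes")


@dataclass
class SyntheticDataset:
    volumes: np.ndarray  # (n, E, E, E) float32
    labels: np.ndarray   # (n,) int
    config: SimulatorConfig


@dataclass
class FeatureBenchmark:
    base_features: np.ndarray
    base_labels: np.ndarray
    novel_features: np.ndarray
    novel_labels: np.ndarray          # ids offset past the base classes
    base_means: np.ndarray            # ground truth, after the nonnegativity shift
    novel_means: np.ndarray
    base_covs: np.ndarray
    novel_covs: np.ndarray
    novel_sources: np.ndarray | None  # (n_novel, 2) base ids averaged per novel mean
    config: FeatureBenchmarkConfig


# ---------------------------------------------------------------------------
# density phantoms
# ---------------------------------------------------------------------------

def _centered_coords(grid_size: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    c = (grid_size - 1) / 2.0
    ax = np.arange(grid_size) - c
    return np.meshgrid(ax, ax, ax, indexing="ij")


def generate_shape_density(shape_spec: ShapeSpec, grid_size: int) -> np.ndarray:
    """Binary density (1 inside, 0 outside) of a centered shape on a cubic grid."""
    if grid_size < 8:
        raise ValueError("grid_size must be >= 8")
    if shape_spec.max_extent() > grid_size / 2:
        raise ValueError(f"shape {shape_spec.kind} larger than the grid")
    z, y, x = _centered_coords(grid_size)
    p = shape_spec.params
    if shape_spec.kind == "sphere":
        mask = z**2 + y**2 + x**2 <= p["radius"] ** 2
    elif shape_spec.kind == "ellipsoid":
        a, b, c = p["semi_axes"]
        with np.errstate(divide="ignore"):
            mask = (z / a) ** 2 + (y / b) ** 2 + (x / c) ** 2 <= 1
    elif shape_spec.kind == "dumbbell":
        r, s = p["radius"], p["separation"]
        mask = ((z - s / 2) ** 2 + y**2 + x**2 <= r**2) | \
               ((z + s / 2) ** 2 + y**2 + x**2 <= r**2)
    elif shape_spec.kind == "rod":
        r, length = p["radius"], p["length"]
        mask = (y**2 + x**2 <= r**2) & (np.abs(z) <= length / 2)
    elif shape_spec.kind == "hollow_shell":
        ro, ri = p["outer_radius"], p["inner_radius"]
        rr = z**2 + y**2 + x**2
        mask = (rr <= ro**2) & (rr >= ri**2)
    else:  # l_tetromino: two perpendicular square-section arms
        arm, t = p["arm_length"], p["thickness"]
        arm_z = (np.abs(x) <= t) & (np.abs(y) <= t) & (z >= -t) & (z <= arm)
        arm_x = (np.abs(z) <= t) & (np.abs(y) <= t) & (x >= -t) & (x <= arm)
        mask = arm_z | arm_x
    return mask.astype(float)


def rotate_random(volume: np.ndarray, seed: int, identity: bool = False) -> np.ndarray:
    """Rotate by a uniformly random 3D rotation (trilinear interpolation).

    Values outside the grid are treated as 0, so a shape that fits inside the
    grid keeps its total mass up to interpolation loss.
    """
    volume = np.asarray(volume, dtype=float)
    if volume.ndim != 3 or len(set(volume.shape)) != 1:
        raise ValueError(f"volume must be cubic, got {volume.shape}")
    if identity:
        return volume.copy()
    rng = np.random.default_rng(seed)
    rot = Rotation.random(rng=rng).as_matrix()
    center = (np.array(volume.shape) - 1) / 2.0
    # affine_transform maps output coords through the matrix: x_in = R^T x_out
    offset = center - rot.T @ center
    return affine_transform(volume, rot.T, offset=offset, order=1, mode="constant", cval=0.0)


def add_noise_to_snr(volume: np.ndarray, target_snr: float, seed: int) -> np.ndarray:
    """Add zero-mean Gaussian noise with variance var(signal)/target_snr.

    The drawn noise field is standardized to the exact target variance, so the
    measured variance ratio matches target_snr up to floating error.
    ``target_snr=np.inf`` returns the input unchanged.
    """
    volume = np.asarray(volume, dtype=float)
    if np.isinf(target_snr):
        return volume.copy()
    if target_snr <= 0:
        raise ValueError("target_snr must be positive")
    sig_var = volume.var()
    if sig_var == 0:
        raise ValueError("constant volume: SNR undefined")
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(volume.shape)
    noise -= noise.mean()
    noise *= np.sqrt(sig_var / target_snr) / noise.std()
    return volume + noise


def apply_missing_wedge(volume: np.ndarray, wedge_half_angle: float) -> np.ndarray:
    """Zero Fourier coefficients in the double wedge of unmeasured tilts.

    With beam axis z (array axis 0) and tilt axis y, a tilt range of
    +/- wedge_half_angle measures Fourier directions within wedge_half_angle
    of the kx axis in the kx–kz plane; the rest is zeroed.  90 degrees means
    no wedge.
    """
    volume = np.asarray(volume, dtype=float)
    if volume.ndim != 3 or len(set(volume.shape)) != 1:
        raise ValueError(f"volume must be cubic, got {volume.shape}")
    if not 0 < wedge_half_angle <= 90:
        raise ValueError("wedge_half_angle must be in (0, 90] degrees")
    n = volume.shape[0]
    kz = np.fft.fftfreq(n)[:, None, None]
    kx = np.fft.fftfreq(n)[None, None, :]
    angle = np.degrees(np.arctan2(np.abs(kz), np.abs(kx)))
    mask = angle <= wedge_half_angle  # broadcasting over ky
    spec = np.fft.fftn(volume) * mask
    return np.fft.ifftn(spec).real


def wedge_mask_fraction(grid_size: int, wedge_half_angle: float) -> float:
    """Fraction of Fourier coefficients removed by the wedge (for audits)."""
    n = grid_size
    kz = np.fft.fftfreq(n)[:, None, None]
    kx = np.fft.fftfreq(n)[None, None, :]
    angle = np.degrees(np.arctan2(np.abs(kz), np.abs(kx)))
    removed = np.broadcast_to(angle > wedge_half_angle, (n, n, n))
    return float(removed.mean())


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------

def default_shapes(n_classes: int, grid_size: int) -> tuple[ShapeSpec, ...]:
    """A palette of macromolecule stand-ins with size-graded difficulty.

    Three compact kinds (sphere, ellipsoid, dumbbell) cycle across shrinking
    size tiers, so classes of the same kind at adjacent sizes are confusable
    — the large/medium/small difficulty spread of real subtomogram
    benchmarks — and any base/novel split leaves each novel class with a
    structurally similar base class, the regime distribution calibration
    presumes.
    """
    tiers = (0.78, 0.60, 0.46, 0.35, 0.27)
    shapes = []
    for c in range(n_classes):
        kind = ("sphere", "ellipsoid", "dumbbell")[c % 3]
        scale = grid_size / 2 * tiers[(c // 3) % len(tiers)]
        if kind == "sphere":
            spec = ShapeSpec("sphere", {"radius": 0.62 * scale})
        elif kind == "ellipsoid":
            spec = ShapeSpec("ellipsoid", {"semi_axes": (0.95 * scale, 0.62 * scale,
                                                         0.45 * scale)})
        else:
            spec = ShapeSpec("dumbbell", {"radius": 0.42 * scale, "separation": 0.95 * scale})
        shapes.append(spec)
    return tuple(shapes)


def build_synthetic_dataset(config: SimulatorConfig) -> SyntheticDataset:
    """n_classes x samples_per_class randomly oriented, noisy subtomograms."""
    templates = [generate_shape_density(s, config.grid_size) for s in config.shapes]
    seeds = np.random.SeedSequence(config.seed).generate_state(
        2 * config.n_classes * config.samples_per_class) % (2**31)
    volumes, labels = [], []
    i = 0
    for c, template in enumerate(templates):
        for _ in range(config.samples_per_class):
            vol = rotate_random(template, seed=int(seeds[i]))
            if config.wedge_half_angle < 90:
                vol = apply_missing_wedge(vol, config.wedge_half_angle)
            vol = add_noise_to_snr(vol, config.target_snr, seed=int(seeds[i + 1]))
            volumes.append(vol.astype(np.float32))
            labels.append(c)
            i += 2
    return SyntheticDataset(np.stack(volumes), np.array(labels), config)


# ---------------------------------------------------------------------------
# feature-space benchmark
# ---------------------------------------------------------------------------

def _random_cov(dim: int, scale: float, rng: np.random.Generator) -> np.ndarray:
    """SPD covariance: isotropic floor + one random correlated direction."""
    u = rng.standard_normal(dim)
    u /= np.linalg.norm(u)
    return scale * (0.8 * np.eye(dim) + 0.2 * dim * np.outer(u, u))


def generate_feature_benchmark(config: FeatureBenchmarkConfig) -> FeatureBenchmark:
    """Draw per-class Gaussian features with recorded ground truth.

    Means are drawn isotropically then shifted by a common vector so every
    mean sits at least six within-class standard deviations above zero:
    features are nonnegative (required by the Tukey power transform) without
    materially truncating the Gaussians.  When ``novel_from_base_mixture`` is
    on, each novel mean is the average of two distinct base means and the
    novel covariance the average of their covariances — the "similar classes
    have similar distributions" premise made literally true.
    """
    rng = np.random.default_rng(config.seed)
    d = config.dim
    base_means = rng.standard_normal((config.n_base_classes, d)) * config.class_mean_scale
    base_covs = np.stack([_random_cov(d, config.within_class_cov_scale, rng)
                          for _ in range(config.n_base_classes)])
    if config.novel_from_base_mixture:
        sources = np.stack([rng.choice(config.n_base_classes, size=2, replace=False)
                            for _ in range(config.n_novel_classes)])
        novel_means = base_means[sources].mean(axis=1)
        novel_covs = base_covs[sources].mean(axis=1)
    else:
        sources = None
        novel_means = rng.standard_normal((config.n_novel_classes, d)) * config.class_mean_scale
        novel_covs = np.stack([_random_cov(d, config.within_class_cov_scale, rng)
                               for _ in range(config.n_novel_classes)])

    sigma_max = np.sqrt(max(base_covs.max(), novel_covs.max()))
    all_means = np.vstack([base_means, novel_means])
    shift = 6.0 * sigma_max - all_means.min()
    base_means = base_means + shift
    novel_means = novel_means + shift
    if base_means.min() <= 0 or novel_means.min() <= 0:
        raise ValueError("config produces negative feature support after shifting")

    def draw(means, covs, n_per):
        feats, labels = [], []
        for c, (m, s) in enumerate(zip(means, covs)):
            x = rng.multivariate_normal(m, s, size=n_per, method="cholesky")
            feats.append(np.clip(x, 0.0, None))  # 6-sigma margin: clipping is ~never active
            labels.append(np.full(n_per, c))
        return np.vstack(feats), np.concatenate(labels)

    bx, by = draw(base_means, base_covs, config.samples_per_base_class)
    nx, ny = draw(novel_means, novel_covs, config.samples_per_novel_class)
    ny = ny + config.n_base_classes  # disjoint id spaces for base and novel
    return FeatureBenchmark(bx, by, nx, ny, base_means, novel_means,
                            base_covs, novel_covs, sources, config)


def save_feature_benchmark(benchmark: FeatureBenchmark, path) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("base/features", data=benchmark.base_features)
        fh.create_dataset("base/labels", data=benchmark.base_labels)
        fh.create_dataset("novel/features", data=benchmark.novel_features)
        fh.create_dataset("novel/labels", data=benchmark.novel_labels)
        fh.create_dataset("truth/means", data=benchmark.novel_means)
        fh.create_dataset("truth/base_means", data=benchmark.base_means)
        if benchmark.novel_sources is not None:
            fh.create_dataset("truth/novel_sources", data=benchmark.novel_sources)


def load_feature_benchmark(path) -> dict[str, np.ndarray]:
    out: dict[str, np.ndarray] = {}
    with h5py.File(path, "r") as fh:
        fh.visititems(lambda name, obj: out.__setitem__(name, obj[()])
                      if isinstance(obj, h5py.Dataset) else None)
    return out
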