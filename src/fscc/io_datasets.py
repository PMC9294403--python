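"""Subtomogram I/O (MRC), manifests, base/novel splits, balanced batching.

Volumes are stored one-per-file in MRC/CCP4 map format (via gemmi) next to a
CSV manifest with columns ``subtomogram_path, class_id, split`` where split is
``base`` or ``novel``.  Class ids are dense integers.  Volumes are indexed
(z, y, x), 0-based.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

__all__ = ["Subtomogram", "SplitSpec", "DatasetManifest", "FormatError",
           "read_subtomogram", "write_subtomogram", "make_split",
           "class_balanced_batches", "normalize_volumes", "write_dataset",
           "load_manifest_volumes"]

MANIFEST_COLUMNS = ["subtomogram_path", "class_id", "split"]


class FormatError(ValueError):
    """Raised when an on-disk volume cannot be read as a cubic MRC map."""


@dataclass
class Subtomogram:
    """One cubic 3D density volume, optionally labeled."""

    volume: np.ndarray
    class_id: int | None = None
    voxel_size: float = 1.0
    source_path: str | None = None

    def __post_init__(self):
        v = np.asarray(self.volume, dtype=np.float32)
        if v.ndim != 3 or len(set(v.shape)) != 1:
            raise ValueError(f"subtomogram volume must be cubic, got {v.shape}")
        if not np.isfinite(v).all():
            raise ValueError("subtomogram volume contains non-finite values")
        self.volume = v

    @property
    def edge(self) -> int:
        return self.volume.shape[0]


@dataclass(frozen=True)
class SplitSpec:
    """Disjoint base/novel class partition."""

    base_classes: frozenset[int]
    novel_classes: frozenset[int]
    seed: int = 0

    def __post_init__(self):
        if self.base_classes & self.novel_classes:
            raise ValueError("base and novel classes must be disjoint")
        if not self.base_classes or not self.novel_classes:
            raise ValueError("both sides of the split must be nonempty")


@dataclass
class DatasetManifest:
    """Path/label/split records backing one dataset directory."""

    records: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=MANIFEST_COLUMNS))

    def __post_init__(self):
        missing = set(MANIFEST_COLUMNS) - set(self.records.columns)
        if missing:
            raise ValueError(f"manifest missing columns: {sorted(missing)}")
        per_class_splits = self.records.groupby("class_id")["split"].nunique()
        if (per_class_splits > 1).any():
            bad = per_class_splits[per_class_splits > 1].index.tolist()
            raise ValueError(f"classes {bad} appear on both sides of the split")

    @property
    def class_counts(self) -> dict[int, int]:
        return self.records["class_id"].value_counts().to_dict()

    def paths_labels(self, split: str | None = None) -> tuple[list[str], np.ndarray]:
        df = self.records if split is None else self.records[self.records["split"] == split]
        return df["subtomogram_path"].tolist(), df["class_id"].to_numpy()

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "DatasetManifest":
        return cls(pd.read_csv(path))


# ---------------------------------------------------------------------------
# MRC I/O
# ---------------------------------------------------------------------------

def read_subtomogram(path) -> Subtomogram:
    """Read a cubic MRC volume; voxel spacing kept from the header."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        ccp4 = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot read MRC map {path}: {exc}") from exc
    vol = np.array(ccp4.grid, copy=True)
    if vol.ndim != 3 or len(set(vol.shape)) != 1:
        raise FormatError(f"{path}: volume is not cubic, shape {vol.shape}")
    voxel = ccp4.grid.unit_cell.a / vol.shape[0]
    return Subtomogram(volume=vol, voxel_size=voxel, source_path=str(path))


def write_subtomogram(subtomogram: Subtomogram, path, overwrite: bool = False) -> None:
    """Write a standard MRC map readable by :func:`read_subtomogram`."""
    path = Path(path)
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True to replace it")
    edge = subtomogram.edge
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = gemmi.FloatGrid(np.ascontiguousarray(subtomogram.volume, dtype=np.float32))
    cell = edge * subtomogram.voxel_size
    ccp4.grid.unit_cell = gemmi.UnitCell(cell, cell, cell, 90, 90, 90)
    ccp4.grid.spacegroup = gemmi.SpaceGroup("P1")
    ccp4.update_ccp4_header()
    ccp4.write_ccp4_map(str(path))


def write_dataset(volumes: np.ndarray, labels: np.ndarray, split: SplitSpec,
                  out_dir, voxel_size: float = 1.0, overwrite: bool = False) -> DatasetManifest:
    """Write one MRC file per volume plus the CSV manifest; returns the manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (vol, label) in enumerate(zip(volumes, labels)):
        name = f"subtomo_{i:05d}.mrc"
        write_subtomogram(Subtomogram(vol, class_id=int(label), voxel_size=voxel_size),
                          out_dir / name, overwrite=overwrite)
        tag = "base" if int(label) in split.base_classes else "novel"
        rows.append({"subtomogram_path": name, "class_id": int(label), "split": tag})
    manifest = DatasetManifest(pd.DataFrame(rows, columns=MANIFEST_COLUMNS))
    manifest.to_csv(out_dir / "manifest.csv")
    return manifest


def load_manifest_volumes(manifest: DatasetManifest, root,
                          split: str | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Load all volumes (optionally one split) as a stacked float array."""
    root = Path(root)
    paths, labels = manifest.paths_labels(split)
    volumes = np.stack([read_subtomogram(root / p).volume for p in paths])
    return volumes.astype(float), labels


# ---------------------------------------------------------------------------
# splits and batching
# ---------------------------------------------------------------------------

def make_split(class_ids, n_novel: int, seed: int) -> SplitSpec:
    """Uniformly random disjoint base/novel partition of the class set."""
    class_ids = sorted(set(int(c) for c in class_ids))
    if n_novel >= len(class_ids) or n_novel < 1:
        raise ValueError(f"n_novel={n_novel} must be in [1, {len(class_ids) - 1}]")
    rng = np.random.default_rng(seed)
    novel = rng.choice(class_ids, size=n_novel, replace=False)
    return SplitSpec(base_classes=frozenset(set(class_ids) - set(novel.tolist())),
                     novel_classes=frozenset(int(c) for c in novel), seed=seed)


def class_balanced_batches(labels, batch_size: int, seed: int,
                           n_batches: int | None = None) -> list[np.ndarray]:
    """Index batches with a (near-)uniform number of samples per class.

    Each class contributes ``batch_size // n_classes`` samples per batch; when
    batch_size is not a multiple of the class count the remainder goes to
    randomly chosen classes, so per-class counts within a batch differ by at
    most 1.  Classes cycle through a shuffled order of their own indices, so
    one epoch touches every sample at least once before repeats.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    classes = np.unique(labels)
    n_classes = len(classes)
    if batch_size < n_classes:
        raise ValueError(f"batch_size {batch_size} < number of classes {n_classes}")
    per = batch_size // n_classes
    if per < 2:
        warnings.warn("fewer than 2 samples per class per batch: contrastive "
                      "positives may be missing", stacklevel=2)
    pools = {}
    for c in classes:
        idx = np.flatnonzero(labels == c)
        if len(idx) < 2:
            warnings.warn(f"class {c} has fewer than 2 samples; its contrastive "
                          "terms will be skipped", stacklevel=2)
        pools[c] = [rng.permutation(idx), 0]
    if n_batches is None:
        n_batches = max(1, len(labels) // batch_size)

    def take(c, k):
        order, pos = pools[c]
        out = []
        while k > 0:
            if pos == len(order):
                order = rng.permutation(order)
                pos = 0
            grab = min(k, len(order) - pos)
            out.append(order[pos:pos + grab])
            pos += grab
            k -= grab
        pools[c] = [order, pos]
        return np.concatenate(out)

    batches = []
    remainder = batch_size - per * n_classes
    for _ in range(n_batches):
        extra = set(rng.choice(classes, size=remainder, replace=False).tolist()) \
            if remainder else set()
        batch = np.concatenate([take(c, per + (1 if c in extra else 0)) for c in classes])
        batches.append(rng.permutation(batch))
    return batches


def normalize_volumes(volumes: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Per-subtomogram zero-mean unit-variance normalization."""
    volumes = np.asarray(volumes, dtype=float)
    flat = volumes.reshape(len(volumes), -1)
    mean = flat.mean(axis=1)[:, None, None, None]
    std = flat.std(axis=1)[:, None, None, None]
    return (volumes - mean) / np.maximum(std, eps)
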