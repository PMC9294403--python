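"""Conv-6 feature extractor: six ConvBlocks and a linear classifier head.

Each ConvBlock is 3D convolution -> batch normalization -> ReLU -> (2x2x2 max
pooling on the configured blocks).  The remaining spatial grid is collapsed by
global average pooling, so the embedding width equals the last convolution
width and every feature is nonnegative (the ReLU precedes the pooling) — the
domain the Tukey power transform downstream requires.

Pooling cannot be applied after all six blocks for 32^3 inputs (32 / 2^6 < 1);
the default pools after blocks 1–4, which supports both the 32^3 synthetic
and 28^3 real-data subtomogram sizes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from ._nn import BatchNorm3d, Conv3d, GlobalAvgPool, Layer, MaxPool3d, ReLU

__all__ = ["BackboneConfig", "Conv6Backbone", "build_backbone", "extract_features",
           "linear_head", "save_checkpoint", "load_checkpoint"]

CHECKPOINT_VERSION = 1


@dataclass(frozen=True)
class BackboneConfig:
    """Architecture knobs for the six-block 3D convolutional extractor.

    channel_widths: output channels of each of the 6 blocks.
    pool_blocks: 1-based block indices followed by 2x2x2 max pooling.
    feature_dim: embedding size; must equal channel_widths[-1] because the
        final grid is collapsed by global average pooling.
    input_edge: voxels per edge of the cubic input (28 or 32 for real use).
    """

    channel_widths: tuple[int, ...] = (64, 64, 64, 64, 64, 64)
    pool_blocks: tuple[int, ...] = (1, 2, 3, 4)
    feature_dim: int = 64
    input_edge: int = 32

    def __post_init__(self):
        if len(self.channel_widths) != 6:
            raise ValueError("Conv-6 requires exactly 6 channel widths")
        if self.feature_dim != self.channel_widths[-1]:
            raise ValueError("feature_dim must equal the last channel width "
                             "(global average pooling)")
        if self.feature_dim < 2:
            raise ValueError("feature_dim must be >= 2")
        if not set(self.pool_blocks) <= set(range(1, 7)):
            raise ValueError("pool_blocks must be a subset of {1..6}")
        edge = self.input_edge
        for b in range(1, 7):
            if b in self.pool_blocks:
                if edge < 2:
                    raise ValueError(
                        f"spatial size {edge} before block {b} cannot be pooled")
                edge //= 2


class Conv6Backbone:
    """Six ConvBlocks + global average pooling; maps volumes to embeddings."""

    def __init__(self, config: BackboneConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        self.layers: list[Layer] = []
        c_in = 1
        for b, width in enumerate(config.channel_widths, start=1):
            self.layers.append(Conv3d(c_in, width, rng))
            self.layers.append(BatchNorm3d(width))
            self.layers.append(ReLU())
            if b in config.pool_blocks:
                self.layers.append(MaxPool3d())
            c_in = width
        self.layers.append(GlobalAvgPool())

    # -- parameter plumbing -------------------------------------------------
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params()]

    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads()]

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params()))

    # -- forward / backward -------------------------------------------------
    def forward(self, volumes: np.ndarray, train: bool = False) -> np.ndarray:
        """(B, E, E, E) volumes -> (B, feature_dim) nonnegative embeddings."""
        e = self.config.input_edge
        if volumes.ndim != 4 or volumes.shape[1:] != (e, e, e):
            raise ValueError(f"expected (B, {e}, {e}, {e}) volumes, got {volumes.shape}")
        x = volumes[:, None].astype(float)
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dfeatures: np.ndarray) -> None:
        dy = dfeatures
        for layer in reversed(self.layers):
            dy = layer.backward(dy)

    # -- (de)serialization --------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        arrays: dict[str, np.ndarray] = {}
        for i, layer in enumerate(self.layers):
            for j, p in enumerate(layer.params()):
                arrays[f"layer{i}_param{j}"] = p
            if isinstance(layer, BatchNorm3d):
                arrays[f"layer{i}_running_mean"] = layer.running_mean
                arrays[f"layer{i}_running_var"] = layer.running_var
        return arrays

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            for j, p in enumerate(layer.params()):
                p[...] = arrays[f"layer{i}_param{j}"]
            if isinstance(layer, BatchNorm3d):
                layer.running_mean[...] = arrays[f"layer{i}_running_mean"]
                layer.running_var[...] = arrays[f"layer{i}_running_var"]


def build_backbone(config: BackboneConfig | None = None, seed: int = 0,
                   verbose: bool = False) -> Conv6Backbone:
    """Construct the extractor; optionally print its parameter count."""
    backbone = Conv6Backbone(config or BackboneConfig(), seed=seed)
    if verbose:
        print(f"Conv-6 backbone: {backbone.n_parameters()} parameters")
    return backbone


def extract_features(extractor: Conv6Backbone, volumes: np.ndarray,
                     eval_mode: bool = True, batch_size: int = 32) -> np.ndarray:
    """Embed a stack of volumes, chunked to bound memory.

    With eval_mode on, batch-norm uses its frozen running statistics, so the
    embedding of a volume does not depend on its batch companions.
    """
    out = [extractor.forward(volumes[i:i + batch_size], train=not eval_mode)
           for i in range(0, len(volumes), batch_size)]
    return np.concatenate(out, axis=0)


def linear_head(features: np.ndarray, weights: np.ndarray,
                bias: np.ndarray | None = None) -> np.ndarray:
    """Affine class scores: features (B, D) x weights (C, D) + bias (C,)."""
    features = np.asarray(features)
    weights = np.asarray(weights)
    if features.shape[-1] != weights.shape[-1]:
        raise ValueError(
            f"feature dim {features.shape[-1]} != weight dim {weights.shape[-1]}")
    scores = features @ weights.T
    if bias is not None:
        scores = scores + bias
    return scores


def save_checkpoint(path, backbone: Conv6Backbone, train_seed: int | None = None,
                    extra: dict | None = None) -> None:
    """Single-archive checkpoint: parameters + config + seed + version."""
    meta = {"version": CHECKPOINT_VERSION,
            "config": {"channel_widths": list(backbone.config.channel_widths),
                       "pool_blocks": list(backbone.config.pool_blocks),
                       "feature_dim": backbone.config.feature_dim,
                       "input_edge": backbone.config.input_edge},
            "train_seed": train_seed,
            "extra": extra or {}}
    arrays = backbone.state_arrays()
    arrays["_meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def load_checkpoint(path) -> tuple[Conv6Backbone, dict]:
    with np.load(path) as npz:
        meta = json.loads(bytes(npz["_meta"]).decode())
        if meta["version"] != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta['version']}")
        cfg = meta["config"]
        config = BackboneConfig(channel_widths=tuple(cfg["channel_widths"]),
                                pool_blocks=tuple(cfg["pool_blocks"]),
                                feature_dim=cfg["feature_dim"],
                                input_edge=cfg["input_edge"])
        backbone = Conv6Backbone(config, seed=0)
        backbone.load_state_arrays({k: npz[k] for k in npz.files if k != "_meta"})
    return backbone, meta
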