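"""Two-stage convolutional encoder with per-layer projection heads.

The architecture follows the first two convolutional stages of AlexNet with
batch normalization. Capacity grows between stages — channels 64 -> 192,
receptive field via subsampled pooling — and each stage applies exactly two
nonlinearity types (ReLU rectification and max pooling):

    stage 1: conv(64, 11x11, stride 4, pad 2) -> BN -> ReLU -> maxpool(3, stride 2)
    stage 2: conv(192, 5x5, stride 1, pad 2) -> BN -> ReLU -> maxpool(3, stride 2)

Each stage has a single-hidden-layer MLP projection head that is applied
independently at every spatial location of the stage's feature map, followed
by global average pooling (GAP) to produce the embedding used by the
self-supervised objective. The layer-2 forward pass composes stage 2 after
stage 1.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from . import nn
from ._autodiff import Tensor

__all__ = [
    "StageConfig",
    "ProjectorConfig",
    "TwoStageEncoder",
    "stage_forward",
    "project_and_pool",
    "extract_features",
    "receptive_field_extent",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclasses.dataclass(frozen=True)
class StageConfig:
    out_channels: int
    kernel: int
    stride: int
    padding: int
    pool_kernel: int = 3
    pool_stride: int = 2
    batch_norm: bool = True


@dataclasses.dataclass(frozen=True)
class ProjectorConfig:
    hidden_dim: int = 512
    out_dim: int = 256


DEFAULT_STAGE_CONFIGS = (
    StageConfig(out_channels=64, kernel=11, stride=4, padding=2),
    StageConfig(out_channels=192, kernel=5, stride=1, padding=2),
)


class _Stage(nn.Module):
    def __init__(self, in_channels: int, cfg: StageConfig, rng: np.random.Generator):
        self.conv = nn.Conv2d(in_channels, cfg.out_channels, cfg.kernel,
                              stride=cfg.stride, padding=cfg.padding, rng=rng)
        self.bn = nn.BatchNorm2d(cfg.out_channels) if cfg.batch_norm else None
        self.pool = nn.MaxPool2d(cfg.pool_kernel, cfg.pool_stride)

    def __call__(self, x: Tensor) -> Tensor:
        h = self.conv(x)
        if self.bn is not None:
            h = self.bn(h)
        return self.pool(h.relu())


class TwoStageEncoder(nn.Module):
    """Stages f1, f2 plus projection heads g1, g2."""

    def __init__(self,
                 stage_configs: tuple[StageConfig, StageConfig] = DEFAULT_STAGE_CONFIGS,
                 projector_configs: tuple[ProjectorConfig, ProjectorConfig] = (
                     ProjectorConfig(), ProjectorConfig()),
                 in_channels: int = 1,
                 seed: int = 0):
        if stage_configs[1].out_channels <= stage_configs[0].out_channels:
            raise ValueError("stage 2 must have more channels than stage 1")
        rng = np.random.default_rng(seed)
        self.stage_configs = stage_configs
        self.projector_configs = projector_configs
        self.in_channels = in_channels
        self.seed = seed
        self.stage1 = _Stage(in_channels, stage_configs[0], rng)
        self.stage2 = _Stage(stage_configs[0].out_channels, stage_configs[1], rng)
        self.projector1 = nn.MLP(stage_configs[0].out_channels,
                                 projector_configs[0].hidden_dim,
                                 projector_configs[0].out_dim, rng=rng)
        self.projector2 = nn.MLP(stage_configs[1].out_channels,
                                 projector_configs[1].hidden_dim,
                                 projector_configs[1].out_dim, rng=rng)
        self.training = True

    # -- forward paths -------------------------------------------------------
    def forward_stage(self, x: Tensor, layer: int,
                      isolate_gradients: bool = False) -> Tensor:
        """Feature map of the requested layer. With ``isolate_gradients`` the
        stage-1 output feeding stage 2 is detached, so the layer-2 loss cannot
        reach stage-1 parameters."""
        if layer not in (1, 2):
            raise ValueError("layer must be 1 or 2")
        h = self.stage1(x)
        if layer == 1:
            return h
        if isolate_gradients:
            h = h.detach()
        return self.stage2(h)

    def stages(self, layer: int) -> list[StageConfig]:
        return list(self.stage_configs[:layer])

    def projector(self, layer: int) -> nn.MLP:
        return self.projector1 if layer == 1 else self.projector2

    def config_dict(self) -> dict:
        return {
            "in_channels": self.in_channels,
            "seed": self.seed,
            "stages": [dataclasses.asdict(c) for c in self.stage_configs],
            "projectors": [dataclasses.asdict(c) for c in self.projector_configs],
        }


def _to_nchw(images: np.ndarray, in_channels: int) -> np.ndarray:
    images = np.asarray(images, dtype=np.float64)
    if images.ndim == 2:
        images = images[None]
    if images.ndim == 3:
        images = images[:, None, :, :]
    elif images.ndim == 4 and images.shape[-1] in (1, 3) and images.shape[1] not in (1, 3):
        images = images.transpose(0, 3, 1, 2)
    if images.shape[1] != in_channels:
        raise ValueError(f"expected {in_channels} channel(s), got {images.shape[1]}")
    return images


def stage_forward(encoder: TwoStageEncoder, layer: int,
                  images: np.ndarray) -> np.ndarray:
    """Inference-mode feature maps (batch x channels x h x w); deterministic
    (batch norm uses running statistics)."""
    x = _to_nchw(images, encoder.in_channels)
    encoder.set_training(False)
    try:
        out = encoder.forward_stage(Tensor(x), layer)
    finally:
        encoder.set_training(True)
    return out.data


def project_and_pool(feature_map, projector: nn.MLP):
    """Apply the projector MLP at every spatial location, then global average
    pooling. Accepts a Tensor (training graph) or ndarray (inference)."""
    is_tensor = isinstance(feature_map, Tensor)
    fm = feature_map if is_tensor else Tensor(np.asarray(feature_map, dtype=np.float64))
    b, c, h, w = fm.shape
    in_dim = projector.fc1.weight.shape[0]
    if c != in_dim:
        raise ValueError(f"projector expects {in_dim} channels, got {c}")
    flat = fm.transpose((0, 2, 3, 1)).reshape(b * h * w, c)
    proj = projector(flat)
    out_dim = proj.shape[1]
    pooled = proj.reshape(b, h * w, out_dim).mean(axis=1)
    return pooled if is_tensor else pooled.data


def extract_features(encoder: TwoStageEncoder, images: np.ndarray, layer: int,
                     include_projector: bool = False) -> np.ndarray:
    """Per-image feature matrix for downstream (e.g. neural-predictivity)
    fitting: flattened post-stage activations by default, or pooled projector
    embeddings behind the flag."""
    fmap = stage_forward(encoder, layer, images)
    if include_projector:
        return project_and_pool(fmap, encoder.projector(layer))
    return fmap.reshape(fmap.shape[0], -1)


def receptive_field_extent(encoder: TwoStageEncoder, layer: int) -> int:
    """Analytic receptive field of one output unit from the kernel/stride
    composition of conv and pool operations up to ``layer``."""
    rf, jump = 1, 1
    for cfg in encoder.stages(layer):
        rf += (cfg.kernel - 1) * jump
        jump *= cfg.stride
        rf += (cfg.pool_kernel - 1) * jump
        jump *= cfg.pool_stride
    return rf


# ---------------------------------------------------------------------------
# Checkpointing: single NPZ archive with params, running stats, config
# ---------------------------------------------------------------------------

def save_checkpoint(encoder: TwoStageEncoder, path: str | Path,
                    metadata: dict | None = None) -> None:
    state = encoder.named_state()
    payload = {f"param::{k}": v for k, v in state.items()}
    payload["config_json"] = np.array(json.dumps(encoder.config_dict()))
    payload["metadata_json"] = np.array(json.dumps(metadata or {}))
    np.savez(Path(path), **payload)


def load_checkpoint(path: str | Path) -> tuple[TwoStageEncoder, dict]:
    with np.load(Path(path), allow_pickle=False) as z:
        config = json.loads(str(z["config_json"]))
        metadata = json.loads(str(z["metadata_json"]))
        state = {k[len("param::"):]: z[k] for k in z.files if k.startswith("param::")}
    encoder = TwoStageEncoder(
        stage_configs=tuple(StageConfig(**c) for c in config["stages"]),
        projector_configs=tuple(ProjectorConfig(**c) for c in config["projectors"]),
        in_channels=config["in_channels"],
        seed=config["seed"],
    )
    encoder.load_state(state)
    return encoder, metadata
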