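"""Layerwise optimization of the two-stage encoder.

Each batch draws complexity-scaled view pairs per layer (smaller patches and
weaker deformations for layer 1, doubled for layer 2), computes the per-layer
self-supervised losses, and updates each stage and its projector only from
its own loss: the layer-2 forward pass through stage 1 is gradient-blocked,
so no gradient ever crosses a stage boundary. By default both layers train
simultaneously within each batch; a sequential mode trains layer 1 to
completion before layer 2.

Early stopping monitors the summed validation loss, computed on a held-out
image split with frozen (pre-drawn) validation views so that successive
evaluations are comparable. Training stops when the relative improvement of
the best summed validation loss stays below a threshold for a patience
number of consecutive evaluations.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn, objectives
from ._autodiff import Tensor
from .encoder import TwoStageEncoder, project_and_pool, save_checkpoint, load_checkpoint
from .views import (AugmentSpec, ComplexitySchedule, default_schedule,
                    deformation_strength_ladder, make_view_pair)

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "TrainingDiverged",
    "train_layerwise",
    "early_stop",
    "run_ablation_grid",
]


@dataclasses.dataclass
class TrainConfig:
    learning_rate: float = 0.001
    weight_decay: float = 0.0
    batch_size: int = 16
    max_epochs: int = 20
    val_fraction: float = 0.1
    stop_threshold: float = 1e-3
    stop_patience: int = 5
    seed: int = 0
    loss: str = "barlow"  # barlow | simclr | simsiam
    barlow: objectives.BarlowConfig = dataclasses.field(
        default_factory=objectives.BarlowConfig)
    temperature: float = 0.1
    sequential: bool = False

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if not 0 < self.val_fraction < 1:
            raise ValueError("val_fraction must lie in (0, 1)")
        if self.loss not in ("barlow", "simclr", "simsiam"):
            raise ValueError(f"unknown loss {self.loss!r}")


@dataclasses.dataclass
class TrainHistory:
    epochs: list[int] = dataclasses.field(default_factory=list)
    train_loss: dict[int, list[float]] = dataclasses.field(
        default_factory=lambda: {1: [], 2: []})
    val_loss: dict[int, list[float]] = dataclasses.field(
        default_factory=lambda: {1: [], 2: []})
    stopped_epoch: int | None = None

    @property
    def summed_val_loss(self) -> list[float]:
        return [a + b for a, b in zip(self.val_loss[1], self.val_loss[2])]

    @property
    def summed_train_loss(self) -> list[float]:
        return [a + b for a, b in zip(self.train_loss[1], self.train_loss[2])]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "epoch": self.epochs,
            "train_loss_l1": self.train_loss[1],
            "train_loss_l2": self.train_loss[2],
            "val_loss_l1": self.val_loss[1],
            "val_loss_l2": self.val_loss[2],
        })

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "TrainHistory":
        df = pd.read_csv(path)
        h = cls()
        h.epochs = df.epoch.tolist()
        h.train_loss = {1: df.train_loss_l1.tolist(), 2: df.train_loss_l2.tolist()}
        h.val_loss = {1: df.val_loss_l1.tolist(), 2: df.val_loss_l2.tolist()}
        return h


class TrainingDiverged(RuntimeError):
    def __init__(self, message: str, state: dict | None = None):
        super().__init__(message)
        self.state = state or {}


def early_stop(summed_val_losses: list[float], stop_threshold: float,
               stop_patience: int) -> bool:
    """Stop when the best summed validation loss has not improved by more
    than ``stop_threshold`` (relative) for ``stop_patience`` consecutive
    evaluations."""
    if len(summed_val_losses) < 2:
        return False
    best = summed_val_losses[0]
    stale = 0
    for value in summed_val_losses[1:]:
        if best - value > stop_threshold * abs(best):
            best = value
            stale = 0
        else:
            stale += 1
            best = min(best, value)
    return stale >= stop_patience


def _layer_loss(z_a, z_b, config: TrainConfig, predictor: nn.MLP | None):
    if config.loss == "barlow":
        c = objectives.cross_correlation(z_a, z_b,
                                         center=config.barlow.center_features)
        return objectives.barlow_loss(c, config.barlow)
    if config.loss == "simclr":
        return objectives.sample_contrastive_loss(z_a, z_b, config.temperature)
    return objectives.noncontrastive_loss(z_a, z_b, predictor)


def _embed(encoder: TwoStageEncoder, views: np.ndarray, layer: int) -> Tensor:
    x = Tensor(views[:, None, :, :])
    fmap = encoder.forward_stage(x, layer, isolate_gradients=(layer == 2))
    return project_and_pool(fmap, encoder.projector(layer))


def _batch_views(images: np.ndarray, spec: AugmentSpec,
                 rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    pairs = [make_view_pair(img, spec, rng) for img in images]
    return (np.stack([p[0] for p in pairs]), np.stack([p[1] for p in pairs]))


def train_layerwise(encoder: TwoStageEncoder, corpus: np.ndarray,
                    schedule: ComplexitySchedule | None = None,
                    config: TrainConfig = TrainConfig(),
                    ) -> tuple[TwoStageEncoder, TrainHistory]:
    """Train both stages with per-layer losses and strict gradient isolation.

    Deterministic given ``config.seed``: corpus split, view sampling and
    parameter initialization all derive from it.
    """
    schedule = schedule or default_schedule()
    if len(schedule.layers) != 2:
        raise ValueError("schedule must define exactly two layers")
    if corpus.shape[-1] < schedule.max_patch_size:
        raise ValueError(
            f"corpus images ({corpus.shape[-1]}px) smaller than the largest "
            f"patch ({schedule.max_patch_size}px)")
    ss = np.random.SeedSequence(config.seed)
    split_rng, view_rng_seed, val_rng = [np.random.default_rng(s)
                                         for s in ss.spawn(3)]
    n = len(corpus)
    n_val = max(1, int(round(config.val_fraction * n)))
    perm = split_rng.permutation(n)
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    train_images, val_images = corpus[train_idx], corpus[val_idx]

    # frozen validation views: same pairs at every evaluation
    val_views = {
        layer: _batch_views(val_images, spec, val_rng)
        for layer, spec in enumerate(schedule.layers, start=1)
    }

    predictors = {
        layer: nn.MLP(encoder.projector_configs[layer - 1].out_dim,
                      encoder.projector_configs[layer - 1].out_dim // 2,
                      encoder.projector_configs[layer - 1].out_dim,
                      rng=np.random.default_rng(config.seed + 1000 + layer))
        for layer in (1, 2)
    } if config.loss == "simsiam" else {1: None, 2: None}

    params = {
        1: encoder.stage1.parameters() + encoder.projector1.parameters(),
        2: encoder.stage2.parameters() + encoder.projector2.parameters(),
    }
    for layer in (1, 2):
        if predictors[layer] is not None:
            params[layer] = params[layer] + predictors[layer].parameters()
    optimizers = {
        layer: nn.Adam(params[layer], lr=config.learning_rate,
                       weight_decay=config.weight_decay)
        for layer in (1, 2)
    }

    history = TrainHistory()
    phases = [(1,), (2,)] if config.sequential else [(1, 2)]
    view_rng = np.random.default_rng(view_rng_seed.integers(2**31))
    epoch_counter = 0
    for layers_active in phases:
        val_track: list[float] = []
        for _epoch in range(config.max_epochs):
            epoch_counter += 1
            order = view_rng.permutation(len(train_images))
            epoch_losses = {1: [], 2: []}
            for start in range(0, len(order), config.batch_size):
                batch = train_images[order[start:start + config.batch_size]]
                if len(batch) < 2:
                    continue
                encoder.zero_grad()
                for layer in layers_active:
                    spec = schedule.layers[layer - 1]
                    va, vb = _batch_views(batch, spec, view_rng)
                    za = _embed(encoder, va, layer)
                    zb = _embed(encoder, vb, layer)
                    loss = _layer_loss(za, zb, config, predictors[layer])
                    value = float(loss.data)
                    if not np.isfinite(value):
                        raise TrainingDiverged(
                            f"non-finite loss at epoch {epoch_counter}, layer {layer}",
                            state={"epoch": epoch_counter, "layer": layer,
                                   "history": history})
                    loss.backward()
                    optimizers[layer].step()
                    optimizers[layer].zero_grad()
                    epoch_losses[layer].append(value)
            # validation with running BN statistics and frozen views
            encoder.set_training(False)
            val_losses = {}
            for layer in (1, 2):
                va, vb = val_views[layer]
                za = _embed(encoder, va, layer)
                zb = _embed(encoder, vb, layer)
                val_losses[layer] = float(
                    _layer_loss(za, zb, config, predictors[layer]).data)
            encoder.set_training(True)
            history.epochs.append(epoch_counter)
            for layer in (1, 2):
                history.train_loss[layer].append(
                    float(np.mean(epoch_losses[layer])) if epoch_losses[layer]
                    else np.nan)
                history.val_loss[layer].append(val_losses[layer])
            summed = val_losses[1] + val_losses[2] if len(layers_active) == 2 \
                else val_losses[layers_active[0]]
            val_track.append(summed)
            logger.debug("epoch %d: val loss %.4f", epoch_counter, summed)
            if early_stop(val_track, config.stop_threshold, config.stop_patience):
                history.stopped_epoch = epoch_counter
                break
    return encoder, history


# ---------------------------------------------------------------------------
# Complexity-mismatch / loss ablation grid
# ---------------------------------------------------------------------------

def run_ablation_grid(corpus: np.ndarray,
                      patch_sizes: dict[int, list[int]],
                      deformation_strengths: dict[int, list],
                      losses: list[str],
                      eval_hook,
                      base_schedule: ComplexitySchedule | None = None,
                      config: TrainConfig = TrainConfig(),
                      out_dir: str | Path | None = None,
                      encoder_factory=None) -> pd.DataFrame:
    """Sweep layerwise training hyperparameters cell by cell.

    ``patch_sizes`` and ``deformation_strengths`` map a layer id to the values
    to sweep for that layer while the other layer keeps the base schedule
    (the layer-1 optimum is fixed before layer-2 is swept). Every cell trains
    a fresh encoder with a cell-specific but reproducible seed, then scores
    it with ``eval_hook(encoder)``. Cell failures are recorded and the grid
    continues; with ``out_dir`` set, completed cells are checkpointed and
    reruns are idempotent.
    """
    base = base_schedule or default_schedule()
    ladder = deformation_strength_ladder()
    cells = []
    for layer, sizes in patch_sizes.items():
        for ps in sizes:
            cells.append(("patch", layer, ps, config.loss))
    for layer, strengths in deformation_strengths.items():
        for s in strengths:
            cells.append(("deform", layer, s, config.loss))
    for loss_name in losses:
        cells.append(("loss", 2, None, loss_name))

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)

    rows = []
    for idx, (kind, layer, value, loss_name) in enumerate(cells):
        cell_id = f"{kind}_l{layer}_{value}_{loss_name}"
        specs = list(base.layers)
        if kind == "patch":
            old = specs[layer - 1]
            view = int(round(old.view_size * value / old.patch_size))
            specs[layer - 1] = dataclasses.replace(old, patch_size=value,
                                                   view_size=view)
        elif kind == "deform":
            rung = ladder[value]
            old = specs[layer - 1]
            if rung == "non_overlap":
                specs[layer - 1] = dataclasses.replace(old, non_overlap=True)
            else:
                specs[layer - 1] = dataclasses.replace(old, area_scale_range=rung,
                                                       non_overlap=False)
        cell_schedule = ComplexitySchedule(layers=specs,
                                           scale_factor=base.scale_factor)
        cell_seed = int(np.random.SeedSequence([config.seed, idx]).generate_state(1)[0]
                        % 2**31)
        cell_config = dataclasses.replace(config, seed=cell_seed, loss=loss_name)
        ckpt = out_dir / f"{cell_id}.npz" if out_dir is not None else None
        try:
            if ckpt is not None and ckpt.exists():
                enc, _ = load_checkpoint(ckpt)
            else:
                enc = (encoder_factory(cell_seed) if encoder_factory is not None
                       else TwoStageEncoder(seed=cell_seed))
                enc, _ = train_layerwise(enc, corpus, cell_schedule, cell_config)
                if ckpt is not None:
                    save_checkpoint(enc, ckpt, metadata={"cell": cell_id})
            score = eval_hook(enc)
            rows.append({"cell": cell_id, "kind": kind, "layer": layer,
                         "value": value, "loss": loss_name,
                         "score": score, "error": ""})
        except Exception as exc:  # record and continue
            logger.warning("cell %s failed: %s", cell_id, exc)
            rows.append({"cell": cell_id, "kind": kind, "layer": layer,
                         "value": value, "loss": loss_name,
                         "score": np.nan, "error": str(exc)})
    return pd.DataFrame(rows)
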