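"""Self-supervised objectives for layerwise training.

The primary loss is the feature-contrastive Barlow Twins objective: the
cross-view, per-batch feature cross-correlation matrix

    c_ij = sum_b z^A_{b,i} z^B_{b,j} / (sqrt(sum_b (z^A_{b,i})^2)
                                        sqrt(sum_b (z^B_{b,j})^2))

is driven toward the identity,

    L_BT = sum_i (1 - c_ii)^2 + lambda * sum_i sum_{j != i} c_ij^2,

maximizing invariance across views on the diagonal while decorrelating
features off it. A sample-contrastive alternative (normalized-temperature
cross-entropy, as in SimCLR) and a non-contrastive alternative (negative
cosine with a stop-gradient predictor branch, as in SimSiam) are provided
for loss-ablation experiments.

All functions accept either autodiff Tensors (training graph) or plain numpy
arrays (returning floats/arrays), so the same code path is exercised by the
trainer and by oracle-based tests.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from ._autodiff import Tensor
from .nn import MLP

__all__ = [
    "BarlowConfig",
    "cross_correlation",
    "barlow_loss",
    "layerwise_loss",
    "sample_contrastive_loss",
    "noncontrastive_loss",
]


@dataclasses.dataclass(frozen=True)
class BarlowConfig:
    lambda_offdiag: float = 0.005
    center_features: bool = False

    def __post_init__(self):
        if self.lambda_offdiag < 0:
            raise ValueError("lambda_offdiag must be >= 0")


def _wrap(x):
    if isinstance(x, Tensor):
        return x, True
    return Tensor(np.asarray(x, dtype=np.float64)), False


def cross_correlation(z_a, z_b, center: bool = False):
    """Cross-view feature cross-correlation matrix; entries in [-1, 1].

    ``center`` subtracts per-feature batch means first (the original Barlow
    Twins convention); the default applies the normalization to the raw
    embeddings.
    """
    za, ta = _wrap(z_a)
    zb, tb = _wrap(z_b)
    if za.shape != zb.shape:
        raise ValueError("view embeddings must have matching shapes")
    if za.shape[0] < 2:
        raise ValueError("batch size must be >= 2")
    if center:
        za = za - za.mean(axis=0, keepdims=True)
        zb = zb - zb.mean(axis=0, keepdims=True)
    norm_a = (za * za).sum(axis=0) ** 0.5
    norm_b = (zb * zb).sum(axis=0) ** 0.5
    for name, norm in (("A", norm_a), ("B", norm_b)):
        bad = np.flatnonzero(norm.data <= 0)
        if bad.size:
            raise ValueError(
                f"zero-norm feature column(s) in view {name}: indices {bad.tolist()}"
            )
    c = (za / norm_a.reshape(1, -1)).transpose((1, 0)) @ (zb / norm_b.reshape(1, -1))
    return c if (ta or tb) else c.data


def barlow_loss(c, config: BarlowConfig = BarlowConfig()):
    """Barlow Twins redundancy-reduction loss on a cross-correlation matrix.

    Non-negative, and zero exactly when the matrix is the identity."""
    ct, was_tensor = _wrap(c)
    d = ct.shape[0]
    if ct.ndim != 2 or ct.shape[1] != d:
        raise ValueError("cross-correlation matrix must be square")
    eye = np.eye(d)
    diag_term = (((ct - eye) * eye) ** 2).sum()
    off_term = ((ct * (1 - eye)) ** 2).sum()
    loss = diag_term + config.lambda_offdiag * off_term
    return loss if was_tensor else float(loss.data)


def layerwise_loss(embeddings_per_layer, config: BarlowConfig = BarlowConfig()):
    """Sum of per-layer Barlow losses.

    ``embeddings_per_layer`` maps layer id -> (z_A, z_B). Returns
    (per-layer losses dict, total). The total is a logging/stopping signal;
    gradient routing between stages is the trainer's contract.
    """
    per_layer = {}
    total = None
    for layer, (za, zb) in embeddings_per_layer.items():
        loss = barlow_loss(
            cross_correlation(za, zb, center=config.center_features), config
        )
        per_layer[layer] = loss
        total = loss if total is None else total + loss
    return per_layer, total


def sample_contrastive_loss(z_a, z_b, temperature: float = 0.1):
    """Normalized-temperature cross-entropy (NT-Xent) over the 2N-view batch:
    the positive for each view is its counterpart; all other 2N - 2 views are
    negatives. Cosine similarities are divided by the temperature."""
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    za, ta = _wrap(z_a)
    zb, tb = _wrap(z_b)
    n = za.shape[0]
    if n < 2:
        raise ValueError("batch size must be >= 2")
    # stack to 2N rows: [A; B] without a concat primitive, via block matmul
    norm_a = ((za * za).sum(axis=1, keepdims=True) ** 0.5)
    norm_b = ((zb * zb).sum(axis=1, keepdims=True) ** 0.5)
    ua = za / norm_a
    ub = zb / norm_b
    saa = ua @ ua.transpose((1, 0))
    sab = ua @ ub.transpose((1, 0))
    sbb = ub @ ub.transpose((1, 0))
    inv_t = 1.0 / temperature
    # for each anchor: log-sum-exp over all others minus positive similarity
    self_mask = np.eye(n) * 1e9  # exclude self-similarity
    exp_aa = ((saa * inv_t) - self_mask).exp()
    exp_bb = ((sbb * inv_t) - self_mask).exp()
    exp_ab = (sab * inv_t).exp()
    denom_a = exp_aa.sum(axis=1) + exp_ab.sum(axis=1)
    denom_b = exp_bb.sum(axis=1) + exp_ab.transpose((1, 0)).sum(axis=1)
    pos = (sab * np.eye(n)).sum(axis=1) * inv_t
    loss = ((denom_a.log() - pos).sum() + (denom_b.log() - pos).sum()) * (1.0 / (2 * n))
    return loss if (ta or tb) else float(loss.data)


def noncontrastive_loss(z_a, z_b, predictor: MLP | None = None,
                        symmetrized: bool = True):
    """Symmetrized negative cosine similarity with a stop-gradient target
    branch (SimSiam-style). Value in [-1, 1]; the gradient with respect to
    the blocked (target) branch is exactly zero. ``predictor=None`` uses the
    identity predictor; ``symmetrized=False`` returns the one-sided form
    -cos(pred(z_A), stopgrad(z_B))."""
    za, ta = _wrap(z_a)
    zb, tb = _wrap(z_b)
    for name, z in (("A", za), ("B", zb)):
        norms = np.sqrt((z.data**2).sum(axis=1))
        if np.any(norms <= 0):
            raise ValueError(f"zero-norm embedding in view {name}")
    pred = (lambda z: z) if predictor is None else predictor
    if symmetrized:
        loss = (_neg_cosine(pred(za), zb.detach())
                + _neg_cosine(pred(zb), za.detach())) * 0.5
    else:
        loss = _neg_cosine(pred(za), zb.detach())
    return loss if (ta or tb) else float(loss.data)


def _neg_cosine(p: Tensor, target: Tensor) -> Tensor:
    # small floor keeps the loss finite if the predictor output collapses
    pn = p / (((p * p).sum(axis=1, keepdims=True) + 1e-24) ** 0.5)
    tn = target / (((target * target).sum(axis=1, keepdims=True) + 1e-24) ** 0.5)
    return -(pn * tn).sum(axis=1).mean()
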