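"""Neural-alignment evaluation suite.

Provides (a) a simulator of V2-like responses to a texture/noise stimulus
set, shaped like the canonical 103-neuron dataset (neurons x 450 images),
with analytically known ground truth; (b) texture-modulation statistics
Rmod = (tex - noise)/(tex + noise) at the per-(neuron, family), per-neuron
and per-family levels; (c) cross-validated PLS regression predictivity
(per-neuron squared Pearson correlation on held-out images); (d) best-layer
selection and the V1-like/V2-like quartile partition; and (e) distributional
(Q-Q) and family-rank (Spearman) comparisons with a paired-bootstrap
significance test for differences between rank correlations.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import KFold

from .stimuli import StimulusSet

logger = logging.getLogger(__name__)

__all__ = [
    "NeuralDataset",
    "ModulationTable",
    "PredictivityResult",
    "RankCompareResult",
    "simulate_v2_neurons",
    "modulation_index",
    "fit_pls_predictivity",
    "select_best_layer",
    "partition_neurons",
    "qq_compare",
    "family_rank_compare",
    "relative_improvement",
    "save_neural_dataset",
    "load_neural_dataset",
]


@dataclasses.dataclass
class NeuralDataset:
    """Non-negative firing rates (neurons x images) aligned to stimulus
    metadata; ``ground_truth`` carries simulator parameters when known."""

    responses: np.ndarray
    meta: pd.DataFrame
    ground_truth: dict | None = None

    def __post_init__(self):
        if self.responses.shape[1] != len(self.meta):
            raise ValueError("response columns must match stimulus count")

    @property
    def n_neurons(self) -> int:
        return self.responses.shape[0]


@dataclasses.dataclass
class ModulationTable:
    """Rmod at three aggregation levels. ``per_pair`` is neurons x families
    with NaN marking undefined entries (tex + noise = 0), excluded pairwise
    from the averages."""

    per_pair: np.ndarray
    per_neuron: np.ndarray
    per_family: np.ndarray
    family_ids: np.ndarray


@dataclasses.dataclass
class PredictivityResult:
    """Per-neuron explained variance (squared Pearson r on held-out images),
    per fold and averaged, with the population median."""

    per_neuron_per_fold: np.ndarray  # folds x neurons
    per_neuron: np.ndarray
    median: float
    n_components: int
    n_folds: int


@dataclasses.dataclass
class RankCompareResult:
    rho: float
    rank_pairs: np.ndarray  # families x 2 (model rank, reference rank)
    competitor_rho: float | None = None
    delta_rho_p_value: float | None = None


# ---------------------------------------------------------------------------
# Simulated neurons
# ---------------------------------------------------------------------------

def simulate_v2_neurons(stimuli: StimulusSet,
                        n_neurons: int = 103,
                        mode: str = "metadata",
                        baseline_range: tuple[float, float] = (5.0, 20.0),
                        gain_range: tuple[float, float] = (0.0, 15.0),
                        modulation_range: tuple[float, float] = (0.0, 1.0),
                        noise_sd: float = 1.0,
                        feature_basis: np.ndarray | None = None,
                        n_components_true: int = 10,
                        rng_seed: int = 0) -> NeuralDataset:
    """Simulate V2-like responses to a texture/noise stimulus set.

    metadata mode: response = baseline_n + gain_n * 1[texture] * m_{n,fam}
    + Gaussian noise, rectified at zero. Ground-truth Rmod for a pair is
    g*m / (2b + g*m), stored in ``ground_truth``.

    feature mode: response = softplus(w_n . features) + noise, for PLS
    parameter-recovery tests; requires ``feature_basis`` row-aligned to the
    stimuli.
    """
    for lo, hi in (baseline_range, gain_range, modulation_range):
        if hi < lo:
            raise ValueError("distribution ranges must be ordered (lo <= hi)")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(rng_seed)
    n_images = len(stimuli)
    families = stimuli.meta.family_id.to_numpy()
    is_texture = (stimuli.meta.condition == "texture").to_numpy()
    if mode == "metadata":
        n_fam = families.max() + 1
        baseline = rng.uniform(*baseline_range, size=n_neurons)
        gain = rng.uniform(*gain_range, size=n_neurons)
        modulation = rng.uniform(*modulation_range, size=(n_neurons, n_fam))
        clean = baseline[:, None] + (
            gain[:, None] * modulation[:, families] * is_texture[None, :]
        )
        drive = gain[:, None] * modulation
        truth = {
            "mode": "metadata",
            "baseline": baseline,
            "gain": gain,
            "modulation": modulation,
            "rmod": drive / (2 * baseline[:, None] + drive),
        }
    elif mode == "feature":
        if feature_basis is None:
            raise ValueError("feature mode requires feature_basis")
        feats = np.asarray(feature_basis, dtype=np.float64)
        if feats.shape[0] != n_images:
            raise ValueError("feature_basis rows must align to stimuli")
        feats = (feats - feats.mean(0)) / (feats.std(0) + 1e-12)
        k = min(n_components_true, feats.shape[1])
        proj = rng.standard_normal((feats.shape[1], k)) / np.sqrt(feats.shape[1])
        w = rng.standard_normal((k, n_neurons))
        drive = feats @ proj @ w
        drive = (drive - drive.mean(0)) / (drive.std(0) + 1e-12)
        # softplus link biased into its quasi-linear regime; rates in Hz-like
        # units comparable to the metadata mode
        clean = 10.0 * np.logaddexp(0.0, drive + 2.0).T  # neurons x images
        truth = {"mode": "feature", "weights": w, "projection": proj}
    else:
        raise ValueError(f"unknown mode {mode!r}")
    responses = clean + rng.normal(0.0, noise_sd, size=clean.shape)
    responses = np.maximum(responses, 0.0)
    return NeuralDataset(responses=responses, meta=stimuli.meta.copy(),
                         ground_truth=truth)


# ---------------------------------------------------------------------------
# Texture modulation statistics
# ---------------------------------------------------------------------------

def modulation_index(data: NeuralDataset) -> ModulationTable:
    """Rmod_{n,i} = (tex_{n,i} - noise_{n,i}) / (tex_{n,i} + noise_{n,i}),
    where tex/noise are responses averaged across image samples of family i.
    Per-neuron values average over families, per-family over neurons."""
    meta = data.meta
    fam_ids = np.unique(meta.family_id)
    n_neurons = data.n_neurons
    per_pair = np.full((n_neurons, len(fam_ids)), np.nan)
    for j, fam in enumerate(fam_ids):
        tex_cols = np.flatnonzero((meta.family_id == fam) & (meta.condition == "texture"))
        noi_cols = np.flatnonzero((meta.family_id == fam) & (meta.condition == "noise"))
        if tex_cols.size == 0 or noi_cols.size == 0:
            raise ValueError(f"family {fam} lacks one of the two conditions")
        tex = data.responses[:, tex_cols].mean(axis=1)
        noi = data.responses[:, noi_cols].mean(axis=1)
        total = tex + noi
        defined = total > 0
        if not defined.all():
            logger.debug("family %s: %d undefined Rmod entries excluded",
                         fam, int((~defined).sum()))
        per_pair[defined, j] = (tex[defined] - noi[defined]) / total[defined]
    import warnings

    with warnings.catch_warnings():
        # rows/columns that are entirely undefined average to NaN by design
        warnings.simplefilter("ignore", category=RuntimeWarning)
        per_neuron = np.nanmean(per_pair, axis=1)
        per_family = np.nanmean(per_pair, axis=0)
    return ModulationTable(per_pair=per_pair, per_neuron=per_neuron,
                           per_family=per_family, family_ids=fam_ids)


# ---------------------------------------------------------------------------
# PLS predictivity
# ---------------------------------------------------------------------------

def _squared_pearson(pred: np.ndarray, obs: np.ndarray) -> float:
    if pred.std() == 0 or obs.std() == 0:
        return 0.0
    r = np.corrcoef(pred, obs)[0, 1]
    if not np.isfinite(r):
        return 0.0
    return float(r**2)


def fit_pls_predictivity(features: np.ndarray, responses: NeuralDataset,
                         n_components: int = 25, n_folds: int = 10,
                         rng_seed: int = 0) -> PredictivityResult:
    """Cross-validated PLS regression from model features to all neurons
    jointly; per-neuron score = squared Pearson correlation between predicted
    and observed held-out responses, averaged over folds."""
    feats = np.asarray(features, dtype=np.float64)
    resp = responses.responses.T  # images x neurons
    if feats.shape[0] != resp.shape[0]:
        raise ValueError("features must be row-aligned to responses")
    n_images, n_neurons = resp.shape
    max_comp = min(feats.shape[1], n_images - n_images // n_folds - 1)
    k = min(n_components, max_comp)
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=rng_seed)
    scores = np.zeros((n_folds, n_neurons))
    for f, (train, test) in enumerate(kf.split(feats)):
        pls = PLSRegression(n_components=k, scale=False)
        mu, sd = feats[train].mean(0), feats[train].std(0) + 1e-12
        pls.fit((feats[train] - mu) / sd, resp[train])
        pred = pls.predict((feats[test] - mu) / sd)
        for n in range(n_neurons):
            scores[f, n] = _squared_pearson(pred[:, n], resp[test][:, n])
    per_neuron = scores.mean(axis=0)
    return PredictivityResult(per_neuron_per_fold=scores, per_neuron=per_neuron,
                              median=float(np.median(per_neuron)),
                              n_components=k, n_folds=n_folds)


def select_best_layer(validation_results: dict[int, PredictivityResult]) -> int:
    """Layer with the highest validation median; ties go to the lowest layer
    index. The final reported score must come from an untouched test split."""
    if not validation_results:
        raise ValueError("no layers evaluated")
    best, best_median = None, -np.inf
    for layer in sorted(validation_results):
        med = validation_results[layer].median
        if med > best_median:
            best, best_median = layer, med
        elif med == best_median:
            logger.debug("layer %s ties layer %s; keeping the lower index", layer, best)
    return best


def partition_neurons(baseline_scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Quartile partition by a baseline model's per-neuron explained
    variance: top quartile -> 'V1-like', bottom quartile -> 'V2-like'.
    Subset size is ceil(N/4); boundary ties resolve by stable sort order."""
    scores = np.asarray(baseline_scores, dtype=np.float64)
    n = scores.size
    q = int(np.ceil(n / 4))
    order = np.argsort(scores, kind="stable")
    v2_like = order[:q]
    v1_like = order[-q:]
    return v1_like, v2_like


# ---------------------------------------------------------------------------
# Distributional and rank comparisons
# ---------------------------------------------------------------------------

def qq_compare(model_values: np.ndarray, reference_values: np.ndarray,
               n_quantiles: int = 20):
    """Empirical quantiles of both samples at matched probability points
    (window midpoints); returns (probs, model_q, reference_q, max |gap|)."""
    model_values = np.asarray(model_values, dtype=np.float64)
    reference_values = np.asarray(reference_values, dtype=np.float64)
    if model_values.size == 0 or reference_values.size == 0:
        raise ValueError("both samples must be non-empty")
    probs = (np.arange(n_quantiles) + 0.5) / n_quantiles
    mq = np.quantile(model_values, probs)
    rq = np.quantile(reference_values, probs)
    return probs, mq, rq, float(np.abs(mq - rq).max())


def _spearman(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return np.nan
    return float(stats.spearmanr(a, b).statistic)


def family_rank_compare(model_per_family: np.ndarray,
                        reference_per_family: np.ndarray,
                        model_table: np.ndarray | None = None,
                        reference_table: np.ndarray | None = None,
                        competitor_per_family: np.ndarray | None = None,
                        competitor_table: np.ndarray | None = None,
                        n_bootstrap: int = 10_000,
                        rng_seed: int = 0) -> RankCompareResult:
    """Spearman rank correlation between per-family modulation indices of a
    model and a reference (rank 1 = lowest-modulation family).

    When a competitor model is supplied along with the per-(neuron, family)
    Rmod tables, the significance of the difference between the two rank
    correlations is assessed by a paired bootstrap: neurons are resampled
    with replacement (the same reference resample serving both correlations),
    family means recomputed, and a two-sided p-value taken from the Delta-rho
    distribution.
    """
    model_per_family = np.asarray(model_per_family, dtype=np.float64)
    reference_per_family = np.asarray(reference_per_family, dtype=np.float64)
    if model_per_family.shape != reference_per_family.shape:
        raise ValueError("family vectors must have equal length")
    rho = _spearman(model_per_family, reference_per_family)
    if np.isnan(rho):
        logger.warning("constant family vector: Spearman rho undefined")
    ranks = np.column_stack([
        stats.rankdata(model_per_family),
        stats.rankdata(reference_per_family),
    ])
    result = RankCompareResult(rho=rho, rank_pairs=ranks)
    if competitor_per_family is None:
        return result
    competitor_per_family = np.asarray(competitor_per_family, dtype=np.float64)
    result.competitor_rho = _spearman(competitor_per_family, reference_per_family)
    if model_table is None or reference_table is None or competitor_table is None:
        return result
    rng = np.random.default_rng(rng_seed)
    observed = rho - result.competitor_rho
    deltas = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        ref_idx = rng.integers(0, reference_table.shape[0], reference_table.shape[0])
        mod_idx = rng.integers(0, model_table.shape[0], model_table.shape[0])
        com_idx = rng.integers(0, competitor_table.shape[0], competitor_table.shape[0])
        ref_fam = np.nanmean(reference_table[ref_idx], axis=0)
        rho_m = _spearman(np.nanmean(model_table[mod_idx], axis=0), ref_fam)
        rho_c = _spearman(np.nanmean(competitor_table[com_idx], axis=0), ref_fam)
        deltas[b] = rho_m - rho_c
    # two-sided: how often the bootstrap difference crosses zero
    p_low = np.mean(deltas <= 0) if observed > 0 else np.mean(deltas >= 0)
    result.delta_rho_p_value = float(min(1.0, 2 * p_low))
    return result


def relative_improvement(candidate: float, baseline: float) -> float:
    """100 * (candidate - baseline) / baseline."""
    if baseline <= 0:
        raise ValueError("baseline must be > 0")
    return 100.0 * (candidate - baseline) / baseline


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def save_neural_dataset(data: NeuralDataset, path: str | Path) -> None:
    """NPZ bundle plus CSV long format (neuron, image, response) alongside."""
    path = Path(path)
    np.savez(path,
             responses=data.responses,
             family_id=data.meta.family_id.to_numpy(),
             sample_id=data.meta.sample_id.to_numpy(),
             condition=data.meta.condition.to_numpy().astype("U"))
    n_neurons, n_images = data.responses.shape
    long = pd.DataFrame({
        "neuron": np.repeat(np.arange(n_neurons), n_images),
        "image": np.tile(np.arange(n_images), n_neurons),
        "response": data.responses.ravel(),
    })
    long.to_csv(path.with_suffix(".csv"), index=False)


def load_neural_dataset(path: str | Path) -> NeuralDataset:
    with np.load(Path(path)) as z:
        meta = pd.DataFrame({
            "family_id": z["family_id"],
            "sample_id": z["sample_id"],
            "condition": z["condition"],
        })
        return NeuralDataset(responses=z["responses"], meta=meta)
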