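# lcl — layerwise complexity-matched learning

`lcl` is a research toolkit for studying how early visual cortex can be
modeled by *layerwise* self-supervised learning: each stage of a two-stage
convolutional encoder is trained by its own objective, with no gradient
crossing stage boundaries, and the *complexity* of each stage's learning
problem — input patch size and spatial-deformation strength — is scaled to
that stage's computational capacity. Receptive fields roughly double between
cortical areas V1 and V2, so the default schedule doubles the patch size,
the view size and the deformation strength between layer 1 and layer 2.

It is aimed at computational visual neuroscientists who want to train and
probe such models end-to-end at desk scale: everything runs on a single CPU
with synthetic stimuli and simulated neurons.

## What's inside

- **`lcl.stimuli`** — synthetic texture families (oriented band-pass noise
  with cross-scale phase coherence and a sparsifying nonlinearity),
  spectrally-matched noise counterparts (amplitude-preserving phase
  scrambling), the canonical 15-family x 15-sample x {texture, noise}
  stimulus design (450 images), and natural-image-like training corpora.
- **`lcl.views`** — complexity-scaled augmentation: central patch crops,
  random resized crops with per-layer area-scale ranges, weak photometric
  distortion, and the deformation-strength ladder used by the ablation grid.
- **`lcl.encoder`** — the two-stage AlexNet-style encoder (conv 64ch 11x11/4
  → BN → ReLU → maxpool; conv 192ch 5x5 → BN → ReLU → maxpool) with
  per-location MLP projection heads followed by global average pooling.
- **`lcl.objectives`** — the Barlow Twins feature-contrastive loss

  $$c_{ij} = \frac{\sum_b z^A_{b,i} z^B_{b,j}}
    {\sqrt{\sum_b (z^A_{b,i})^2}\sqrt{\sum_b (z^B_{b,j})^2}},\qquad
    \mathcal{L}_{BT} = \sum_i (1 - c_{ii})^2
      + \lambda \sum_i \sum_{j \ne i} c_{ij}^2,$$

  plus sample-contrastive (NT-Xent) and non-contrastive (stop-gradient
  negative cosine) alternatives for loss ablations.
- **`lcl.trainer`** — layerwise Adam training with strict gradient
  isolation, validation early stopping, checkpointing and the
  complexity-mismatch ablation grid.
- **`lcl.v1pyr`** — the hand-crafted V1 baseline: a complex steerable
  pyramid (tight frame, exact reconstruction) with simple/complex cell
  nonlinearities and spatial L2 (energy) pooling.
- **`lcl.neuroeval`** — simulated V2-like neurons with analytic ground
  truth, the texture modulation index
  $R_{mod} = (tex - noise)/(tex + noise)$, cross-validated PLS
  predictivity, best-layer selection, the V1-like/V2-like quartile
  partition, Q-Q and Spearman family-rank comparisons with a paired
  bootstrap test.

The networks and their training run on a compact numpy reverse-mode
autodiff core (`lcl._autodiff`), so the package has no deep-learning
framework dependency.

## Worked example

```python
import numpy as np
from lcl.stimuli import build_v2_stimulus_set, make_training_corpus
from lcl.encoder import TwoStageEncoder, extract_features
from lcl.trainer import TrainConfig, train_layerwise
from lcl.views import default_schedule
from lcl.neuroeval import simulate_v2_neurons, modulation_index, \
    fit_pls_predictivity

# 450 images: 15 texture families x 15 samples, each paired with
# spectrally-matched noise
stim = build_v2_stimulus_set(n_families=15, n_samples=15, size=64, rng_seed=0)
print(len(stim))                       # 450

# layerwise smoke training on a synthetic corpus
corpus = make_training_corpus(200, size=128, rng_seed=0)
enc, hist = train_layerwise(TwoStageEncoder(seed=0), corpus,
                            default_schedule(),
                            TrainConfig(max_epochs=20, seed=0))
print(round(hist.train_loss[1][-1] / hist.train_loss[1][0], 2))  # 0.79
print(round(hist.train_loss[2][-1] / hist.train_loss[2][0], 2))  # 0.48

# texture modulation of simulated V2 neurons
data = simulate_v2_neurons(stim, n_neurons=103, rng_seed=0)
table = modulation_index(data)
print(table.per_pair.shape)            # (103, 15)

# predictivity of encoder features for feature-driven neurons
feats = extract_features(enc, stim.images, layer=2)
res = fit_pls_predictivity(feats, data, n_components=25, rng_seed=0)
print(0.0 <= res.median <= 1.0)        # True
```

The loss ratios show both stages improving under their own objectives (a
value below 1 means the final epoch's training loss is below the first
epoch's); the modulation table holds one $R_{mod}$ value per (neuron,
family), from which per-neuron and per-family averages and rank comparisons
are derived.

A CLI mirrors the main workflows:

```bash
lcl stimuli --families 15 --samples 15 --size 64 --seed 0 --out stim/
lcl train --n-images 200 --epochs 20 --seed 0 --out run/
lcl simulate-neurons --mode metadata --seed 0 --out neurons.npz
lcl evaluate --checkpoint run/checkpoint.npz --stimuli stim/ --neural neurons.npz
```

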