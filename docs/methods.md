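# Methods

This note documents the models, default parameters and design choices of
`lcl`, and what the synthetic data used throughout the test suite does and
does not establish about real neural data.

## The layerwise complexity-matched model

The encoder is the first two convolutional stages of an AlexNet-style
network with batch normalization:

| stage | operation | output channels | receptive field |
|---|---|---|---|
| 1 | conv 11x11, stride 4, pad 2 → BN → ReLU → maxpool 3/2 | 64 | 19 px |
| 2 | + conv 5x5, stride 1, pad 2 → BN → ReLU → maxpool 3/2 | 192 | 51 px |

Each stage has a projection head — an MLP with a single hidden layer
(defaults: hidden 512, output 256) — applied independently at every spatial
location of the stage's feature map, then globally average pooled. The
resulting embeddings of two augmented views of the same image patch feed
the per-layer loss.

Capacity grows between stages (channels, receptive field, number of
nonlinearities), and the learning problem is scaled with it: layer 1 sees
56 px central patches reduced to 48 px views by random resized crops with
area scale (0.6, 0.9); layer 2 sees 112 px patches, 96 px views, and scale
(0.3, 0.9). Patch size, view size, and deformation strength (minimum area
scale) all change by exactly a factor of 2, mirroring the approximate
doubling of receptive field size between cortical areas V1 and V2. Both
patches share the image center, so the layer-1 patch is nested in the
layer-2 patch.

Photometric distortion is deliberately weak: multiplicative contrast
uniform in [0.8, 1.2] about the view mean, additive luminance uniform in
[-0.1, 0.1], Gaussian pixel noise with sigma uniform in [0, 0.05] (on [0,1]
images). These ranges are configurable; aggressive augmentations (flips,
strong color jitter, blur, solarization) are intentionally absent. The
random-resized-crop sampler draws the area fraction uniformly in its range
and then the aspect ratio log-uniformly over the sub-range feasible for
that area (default (3/4, 4/3)), so the stated area-fraction law holds
exactly; resizing is bilinear with half-pixel-center (align_corners=false)
semantics for bit-reproducibility.

### Objectives

The primary loss is Barlow Twins: the batch cross-correlation matrix
between the two views' embeddings is pushed toward the identity, with
off-diagonal weight λ = 0.005 (the conventional setting; configurable).
The cross-correlation is implemented as printed, without mean-centering; a
`center_features` flag restores the original convention of subtracting
per-feature batch means, and both modes are tested. Alternatives for
ablation: NT-Xent (sample-contrastive, temperature 0.1 by default) and a
stop-gradient negative-cosine loss with a predictor MLP (non-contrastive).

### Training and gradient isolation

Adam (lr 0.001, no weight decay), batch size 16, no learning-rate schedule.
The total loss is the sum of the per-layer losses, but gradients are
strictly isolated: the stage-1 output feeding stage 2 is detached, so the
layer-2 loss cannot reach stage-1 parameters (asserted to machine zero in
the tests). Both layers update within each batch by default; a sequential
mode trains layer 1 to completion first. Validation uses 10% of the corpus
with view pairs frozen at split time, so successive evaluations are
comparable; training stops when the best summed validation loss fails to
improve by more than 1e-3 (relative) for 5 consecutive evaluations. All
randomness (split, views, initialization) derives from a single seed, and
two runs with the same seed produce bit-identical parameters.

The networks run on a small numpy reverse-mode autodiff core written for
this package; convolution uses im2col, and every primitive's gradient is
verified against central finite differences in the test suite.

### Complexity-mismatch ablation

The ablation grid sweeps one layer's patch size or deformation strength
while the other keeps its defaults, following the protocol of fixing the
layer-1 optimum before sweeping layer 2. The deformation ladder is:
strength 0 = no spatial deformation, strengths 1–3 = minimum area scales
0.6 / 0.3 / 0.08, plus a non-overlap mode that forces the two views onto
disjoint patch regions. Cells are seeded independently but reproducibly,
failures are recorded without aborting the grid, and completed cells are
cached so reruns are idempotent.

## Synthetic stimuli

Texture samples are oriented band-pass filtered Gaussian noise in which a
second band one octave above the dominant frequency is driven by the same
phases (cross-scale coherence in [0,1]), followed by a sparsifying
pointwise nonlinearity sign(x)|x|^γ with γ < 1. The nonlinearity is what
makes a texture differ from its phase-scrambled counterpart: a purely
linear filtered Gaussian field is statistically indistinguishable from its
spectral match. Families are parameterized by orientation, orientation
bandwidth, dominant frequency, octave bandwidth, coherence and γ, drawn
once per family from fixed ranges; samples within a family share the
filters and differ only in the noise realization. This generator is *not*
a perceptual texture-synthesis model: it produces family-graded
higher-order structure sufficient for texture-versus-noise contrasts, not
naturalistic textures.

Spectrally-matched noise takes the Fourier amplitudes of the source image
and the phases of a white-noise image (which guarantees a real-valued
result), preserving the DC component so the mean is unchanged. The output
is clipped to [0, 1]; the clipped fraction is logged and the operation
rejected if it exceeds 5%, since silent clipping would distort the
spectrum. Amplitude preservation before clipping holds to ~1e-13.

The training corpus consists of 1/f-amplitude noise backgrounds with 3–7
superimposed Gabor-like oriented elements per image, normalized to [0, 1];
its radially averaged power spectrum has a log-log slope near -2, inside
the range typical of natural images. The canonical stimulus design is 15
families x 15 samples x {texture, noise} = 450 images; tests and the
acceptance run use 64 px images, and smoke training uses 200 corpus images
at 128 px — desk-scale sizes chosen so the full pipeline runs in minutes on
one CPU.

## The V1 baseline

The hand-crafted baseline is a complex steerable pyramid built in the
Fourier domain: raised-cosine (in log2 radius) radial masks split the
spectrum into a high-pass residual, dyadic band-pass annuli and a low-pass
residual; angular masks |cos(θ - θ_k)|^(K-1) split each annulus into K
orientations. Squared masks tile the plane exactly, so analysis–synthesis
round trips are exact to machine precision; subbands are decimated by exact
Fourier-domain cropping (band at scale s is downsampled by 2^(s-1)).
Quadrature pairs come from restricting each filter to a frequency
half-plane: the real part of each complex subband is the even-filter
response and the imaginary part its Hilbert partner. Defaults: 4
orientations, 3 scales — a conventional V1 modeling choice, configurable
for sensitivity checks.

Simple cells are the four half-wave rectified phase/polarity channels per
subband; complex cells are the subband modulus (phase-invariant on grating
probes to well under 2%). L2 pooling takes the square root of the windowed
*mean* of squares (window 4, stride 2, valid region), so spatially constant
maps are fixed points. The V1 feature vector concatenates pooled simple-
and complex-cell maps over all scales and orientations.

## Simulated neurons and evaluation

Two generator modes, both shaped like the canonical dataset (103 neurons x
450 images, non-negative rates):

- **metadata mode** — response = baseline_n + gain_n · 1[texture] ·
  m_{n,family} + Gaussian noise, rectified at zero. Baselines are uniform
  in [5, 20] (arbitrary Hz-like units), gains in [0, 15], per-(neuron,
  family) modulations in [0, 1], noise sd 1.0. The ground-truth modulation
  index is analytic: R_mod = g·m / (2b + g·m); the estimate recovers it
  within 0.02 at 100 samples per family and noise at 1% of baseline.
- **feature mode** — response = 10 · softplus(standardized w·features + 2)
  + noise. The drive is standardized per neuron and offset into the
  quasi-linear regime of the softplus so that a linear readout (PLS) can
  recover feature-driven structure; with zero noise, median explained
  variance exceeds 0.99, and responses independent of the features score
  ~0.02.

The modulation index averages responses over image samples within each
(neuron, family) before forming (tex - noise)/(tex + noise); pairs with
tex + noise = 0 are marked undefined and excluded pairwise from averages
rather than imputed. Per-neuron values average over families, per-family
values over neurons; all three levels are mutually consistent by
construction and bounded in [-1, 1] for non-negative responses.

PLS predictivity follows the standard encoding-model protocol: per
cross-validation fold (default 10, shuffled by seed), features are
z-scored on the training images, a PLS regression (default 25 components)
is fit jointly to all neurons, and each neuron's score on held-out images
is the squared Pearson correlation between predicted and observed
responses (degenerate constant vectors score 0). No noise-ceiling
normalization is applied — simulated data has no repeat structure — and a
ceiling hook is left for real data. Best-layer selection maximizes the
validation-split median (ties to the lower layer); the quartile partition
sorts neurons by the V1-baseline score and takes ceil(N/4) from each end,
giving 26 + 26 of 103.

Family-rank comparisons use the Spearman correlation of per-family
modulation indices (verified against the closed form 1 - 6Σd²/(T(T²-1)) on
tie-free cases, including exhaustive enumeration at T = 4). Significance
of a *difference* between two models' rank correlations against a common
reference uses a paired bootstrap (default 10,000 resamples): neurons are
resampled with replacement in each population, family means recomputed,
and the two-sided p-value read from the Δρ distribution — a pragmatic
choice where a canonical test for dependent Spearman correlations is not
available.

## Numerical choices and degenerate inputs

- Cross-correlation columns with zero norm are rejected with the offending
  feature indices named; SimSiam cosine norms are floored at 1e-12 so a
  collapsed predictor yields a finite loss instead of NaN.
- Non-finite training losses abort with a state dump
  (`TrainingDiverged`).
- Batch norm uses batch statistics in training and running averages
  (momentum 0.1) at inference, making inference deterministic.
- Checkpoints are single NPZ archives (parameters, running statistics,
  config, metadata) and round-trip bit-exactly.
- The crop sampler falls back to the maximal centered crop after 10
  infeasible draws (logged).
- Undefined Spearman correlations (constant vectors) are reported as NaN,
  not silently replaced.

## What the tests do and do not show

Passing tests establish that the implementation is internally correct —
objectives match brute-force oracles, gradients match finite differences,
the pyramid is a tight frame, simulators have recoverable ground truth,
and training reduces both layers' losses under the stated conditions. They
do not establish that the trained desk-scale model reproduces primate V2
response properties: that claim requires natural-image training at scale
and real electrophysiological data, both outside this package's scope. The
simulated neurons encode texture selectivity by construction (metadata
mode) or linear feature drive (feature mode); they do not model adaptation,
correlated variability, or repeat-to-repeat noise structure.
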