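"""Synthetic visual stimuli: texture families, spectrally-matched noise, and
desk-scale training corpora.

Texture samples are generated as oriented band-pass filtered noise with a
controlled cross-scale phase correlation followed by a sparsifying pointwise
nonlinearity. The nonlinearity is essential: it creates higher-order (phase)
structure that phase scrambling destroys, so each texture image differs
statistically from its spectrally-matched noise counterpart — the contrast
that texture-selective V2 neurons respond to. A linear filtered Gaussian
field would be statistically identical to its scrambled version.

The canonical V2 stimulus set pairs every texture sample with one noise
counterpart: ``n_families x n_samples x {texture, noise}`` images, with the
default 15 x 15 design giving 450 images.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

logger = logging.getLogger(__name__)

__all__ = [
    "TextureFamilySpec",
    "StimulusSet",
    "make_texture_family",
    "spectral_match_noise",
    "build_v2_stimulus_set",
    "make_training_corpus",
    "save_stimulus_set",
    "load_stimulus_set",
]

MAX_CLIP_FRACTION = 0.05


@dataclasses.dataclass(frozen=True)
class TextureFamilySpec:
    """Parameters defining one synthetic texture family.

    orientation : preferred orientation of the dominant band, radians.
    orientation_bw : angular std of the oriented filter, radians.
    freq : dominant spatial frequency, cycles/pixel (must stay below Nyquist).
    freq_bw : octave bandwidth (std in log2-frequency).
    cross_scale : in [0, 1]; phase coherence between the dominant band and the
        band one octave above. High values yield edge/line-like structure.
    contrast_exponent : gamma < 1 sparsifies, creating non-Gaussian statistics.
    seed : base seed; samples are drawn from spawned child streams.
    """

    orientation: float = 0.0
    orientation_bw: float = 0.35
    freq: float = 0.12
    freq_bw: float = 0.55
    cross_scale: float = 0.8
    contrast_exponent: float = 0.5
    seed: int = 0


@dataclasses.dataclass
class StimulusSet:
    """Images plus aligned per-image metadata.

    images : (N, H, W) float array in [0, 1].
    meta : DataFrame with columns family_id, sample_id, condition.
    size : edge length in pixels.
    """

    images: np.ndarray
    meta: pd.DataFrame
    size: int

    def __post_init__(self):
        if len(self.images) != len(self.meta):
            raise ValueError("images and metadata lengths differ")

    def __len__(self) -> int:
        return len(self.images)

    def validate(self) -> None:
        if self.images.min() < 0 or self.images.max() > 1:
            raise ValueError("intensities must lie in [0, 1]")
        for cond in ("texture", "noise"):
            if not (self.meta["condition"] == cond).any():
                raise ValueError(f"missing condition {cond!r}")
        tex = self.meta[self.meta.condition == "texture"]
        noi = self.meta[self.meta.condition == "noise"]
        tex_keys = set(zip(tex.family_id, tex.sample_id))
        noi_keys = set(zip(noi.family_id, noi.sample_id))
        if tex_keys != noi_keys or len(tex) != len(tex_keys):
            raise ValueError("texture/noise pairing is not a bijection")

    def select(self, condition: str) -> np.ndarray:
        """Images of one condition, ordered by (family_id, sample_id)."""
        sub = self.meta[self.meta.condition == condition]
        order = sub.sort_values(["family_id", "sample_id"]).index
        return self.images[np.asarray(order)]


def _freq_grid(size: int) -> tuple[np.ndarray, np.ndarray]:
    fy = np.fft.fftfreq(size)[:, None]
    fx = np.fft.fftfreq(size)[None, :]
    r = np.hypot(fy, fx)
    theta = np.arctan2(fy, fx)
    return r, theta


def _oriented_band(size: int, freq: float, freq_bw: float,
                   orientation: float, orientation_bw: float) -> np.ndarray:
    """Real, even-symmetric log-Gabor-style frequency mask."""
    r, theta = _freq_grid(size)
    with np.errstate(divide="ignore"):
        radial = np.exp(-((np.log2(np.maximum(r, 1e-9) / freq)) ** 2) / (2 * freq_bw**2))
    radial[0, 0] = 0.0
    # even angular term: respond identically to theta and theta + pi
    d = np.angle(np.exp(2j * (theta - orientation))) / 2.0
    angular = np.exp(-(d**2) / (2 * orientation_bw**2))
    return radial * angular


def _normalize01(img: np.ndarray, n_sigma: float = 3.0) -> np.ndarray:
    sd = img.std()
    if sd == 0:
        return np.full_like(img, 0.5)
    out = 0.5 + (img - img.mean()) / (2 * n_sigma * sd)
    return np.clip(out, 0.0, 1.0)


def make_texture_family(spec: TextureFamilySpec, n_samples: int, size: int,
                        rng_seed: int | None = None) -> list[np.ndarray]:
    """Generate ``n_samples`` realizations sharing one family's statistics."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if size < 32:
        raise ValueError("size must be >= 32")
    cycles = spec.freq * size
    if cycles < 3.0:
        raise ValueError(
            f"size {size} too small for frequency {spec.freq} c/px "
            f"({cycles:.1f} cycles per image; need >= 3)"
        )
    if spec.freq * 2 ** (1 + spec.freq_bw) > 0.5:
        raise ValueError(
            f"frequency band (peak {spec.freq} c/px, bw {spec.freq_bw} oct) "
            "exceeds the Nyquist limit at the octave above"
        )
    seed = spec.seed if rng_seed is None else rng_seed
    children = np.random.SeedSequence(seed).spawn(n_samples)
    band_lo = _oriented_band(size, spec.freq, spec.freq_bw,
                             spec.orientation, spec.orientation_bw)
    band_hi = _oriented_band(size, 2 * spec.freq, spec.freq_bw,
                             spec.orientation, spec.orientation_bw)
    images = []
    for child in children:
        rng = np.random.default_rng(child)
        n0 = rng.standard_normal((size, size))
        n1 = rng.standard_normal((size, size))
        f0 = np.fft.fft2(n0)
        # cross-scale coherent component: same phases drive both octaves
        f_hi = spec.cross_scale * f0 + np.sqrt(1 - spec.cross_scale**2) * np.fft.fft2(n1)
        x = np.real(np.fft.ifft2(f0 * band_lo + f_hi * band_hi))
        x = x / (x.std() + 1e-12)
        g = spec.contrast_exponent
        x = np.sign(x) * np.abs(x) ** g
        images.append(_normalize01(x))
    return images


def spectral_match_noise(image: np.ndarray, rng_seed: int | None = None,
                         return_info: bool = False):
    """Randomize Fourier phases while preserving the amplitude spectrum.

    The random phase field is taken from the spectrum of a white-noise image,
    which guarantees Hermitian symmetry (real output) for free. The DC
    component is copied from the input so the mean is preserved. The result is
    clipped into [0, 1]; the clipped fraction is logged and the call rejected
    if it exceeds 5 % (clipping distorts the spectrum silently otherwise).
    """
    image = np.asarray(image, dtype=np.float64)
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite pixels")
    rng = np.random.default_rng(rng_seed)
    if image.ndim == 3:  # RGB: shared phase field across channels
        w = rng.standard_normal(image.shape[:2])
        chans = [
            _phase_scramble(image[..., c], w) for c in range(image.shape[2])
        ]
        raw = np.stack(chans, axis=-1)
    else:
        w = rng.standard_normal(image.shape)
        raw = _phase_scramble(image, w)
    out = np.clip(raw, 0.0, 1.0)
    clipped = float(np.mean(out != raw))
    if clipped > 0:
        logger.debug("spectral_match_noise clipped %.3f%% of pixels", 100 * clipped)
    if clipped > MAX_CLIP_FRACTION:
        raise ValueError(f"{100 * clipped:.1f}% of pixels clipped (limit 5%)")
    if return_info:
        return out, {"clipped_fraction": clipped, "unclipped": raw}
    return out


def _phase_scramble(channel: np.ndarray, white: np.ndarray) -> np.ndarray:
    spec = np.fft.fft2(channel)
    phase = np.exp(1j * np.angle(np.fft.fft2(white)))
    scrambled = np.abs(spec) * phase
    scrambled[0, 0] = spec[0, 0]  # preserve the mean exactly
    return np.real(np.fft.ifft2(scrambled))


def _family_specs(n_families: int, rng: np.random.Generator,
                  size: int) -> list[TextureFamilySpec]:
    """Distinct, graded family parameterizations spanning orientation,
    frequency, coherence and sparsity. The frequency range is floored so
    the dominant band always fits the requested image size."""
    freq_lo = max(0.08, 3.2 / size)
    specs = []
    for fam in range(n_families):
        freq_bw = float(rng.uniform(0.4, 0.7))
        # keep the octave above the peak inside the Nyquist limit
        freq_hi = min(0.16, 0.995 * 0.5 / 2 ** (1 + freq_bw))
        specs.append(TextureFamilySpec(
            orientation=float(rng.uniform(0, np.pi)),
            orientation_bw=float(rng.uniform(0.2, 0.7)),
            freq=float(rng.uniform(freq_lo, freq_hi)),
            freq_bw=freq_bw,
            cross_scale=float(rng.uniform(0.5, 0.98)),
            contrast_exponent=float(rng.uniform(0.35, 0.7)),
            seed=int(rng.integers(2**31)),
        ))
    return specs


def build_v2_stimulus_set(n_families: int = 15, n_samples: int = 15,
                          size: int = 64, rng_seed: int = 0) -> StimulusSet:
    """Texture/noise paired stimulus set; defaults give 15 x 15 x 2 = 450."""
    if n_families < 1 or n_samples < 1:
        raise ValueError("n_families and n_samples must be >= 1")
    master = np.random.default_rng(rng_seed)
    specs = _family_specs(n_families, master, size)
    images, records = [], []
    for fam_id, spec in enumerate(specs):
        samples = make_texture_family(spec, n_samples, size)
        for samp_id, tex in enumerate(samples):
            noise_seed = int(master.integers(2**31))
            noise = spectral_match_noise(tex, rng_seed=noise_seed)
            images.append(tex)
            records.append((fam_id, samp_id, "texture"))
            images.append(noise)
            records.append((fam_id, samp_id, "noise"))
    meta = pd.DataFrame(records, columns=["family_id", "sample_id", "condition"])
    out = StimulusSet(images=np.stack(images), meta=meta, size=size)
    out.validate()
    return out


def make_training_corpus(n_images: int, size: int = 224, rng_seed: int = 0,
                         min_size: int | None = None) -> np.ndarray:
    """Natural-image-like composites: 1/f-amplitude noise backgrounds with
    superimposed oriented (Gabor) structure, in [0, 1].

    ``min_size`` optionally rejects corpora too small for a downstream
    augmentation pipeline (largest configured patch).
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    if min_size is not None and size < min_size:
        raise ValueError(f"size {size} smaller than required patch {min_size}")
    rng = np.random.default_rng(rng_seed)
    r, _ = _freq_grid(size)
    amp = np.where(r > 0, 1.0 / np.maximum(r, 1.0 / size), 0.0)
    yy, xx = np.mgrid[0:size, 0:size]
    corpus = np.empty((n_images, size, size))
    for k in range(n_images):
        phases = np.exp(1j * np.angle(np.fft.fft2(rng.standard_normal((size, size)))))
        bg = np.real(np.fft.ifft2(amp * phases))
        bg = bg / (bg.std() + 1e-12)
        img = bg.copy()
        for _ in range(rng.integers(3, 8)):
            cy, cx = rng.uniform(0, size, 2)
            theta = rng.uniform(0, np.pi)
            f = rng.uniform(0.03, 0.15)
            sigma = rng.uniform(0.05, 0.2) * size
            u = (xx - cx) * np.cos(theta) + (yy - cy) * np.sin(theta)
            v = -(xx - cx) * np.sin(theta) + (yy - cy) * np.cos(theta)
            env = np.exp(-(u**2 + v**2) / (2 * sigma**2))
            img = img + rng.uniform(0.5, 1.5) * env * np.cos(2 * np.pi * f * u)
        corpus[k] = _normalize01(img)
    return corpus


# ---------------------------------------------------------------------------
# I/O: 16-bit PNG per image + NPZ bundle + CSV metadata
# ---------------------------------------------------------------------------

def save_stimulus_set(stim: StimulusSet, out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    filenames = []
    for i, img in enumerate(stim.images):
        row = stim.meta.iloc[i]
        name = f"fam{row.family_id:02d}_s{row.sample_id:02d}_{row.condition}.png"
        arr16 = np.round(img * 65535).astype(np.uint16)
        Image.fromarray(arr16).save(out_dir / name)
        filenames.append(name)
    np.savez(
        out_dir / "stimuli.npz",
        images=stim.images,
        family_id=stim.meta.family_id.to_numpy(),
        sample_id=stim.meta.sample_id.to_numpy(),
        condition=stim.meta.condition.to_numpy().astype("U"),
        size=stim.size,
    )
    meta = stim.meta.copy()
    meta.insert(0, "filename", filenames)
    meta.to_csv(out_dir / "metadata.csv", index=False)


def load_stimulus_set(in_dir: str | Path) -> StimulusSet:
    with np.load(Path(in_dir) / "stimuli.npz") as z:
        meta = pd.DataFrame({
            "family_id": z["family_id"],
            "sample_id": z["sample_id"],
            "condition": z["condition"],
        })
        return StimulusSet(images=z["images"], meta=meta, size=int(z["size"]))
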