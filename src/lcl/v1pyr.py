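"""Hand-crafted V1 model: complex steerable pyramid + rectifying
nonlinearities + spatial L2 (energy) pooling.

The decomposition is built in the Fourier domain with polar-separable
filters: raised-cosine radial masks split the spectrum into a high-pass
residual, dyadic band-pass annuli and a low-pass residual, and even angular
masks |cos(theta - theta_k)|^(K-1) split each annulus into K orientations.
The squared masks tile the frequency plane exactly (a tight frame), so the
analysis-synthesis round trip is exact to machine precision. Quadrature
pairs are obtained by restricting each oriented filter to a frequency
half-plane (analytic signal): the real part of each complex subband is the
even-filter response and the imaginary part its Hilbert partner.

Simple cells are half-wave rectified odd/even phase channels; complex cells
are the quadrature energy (modulus); L2 pooling takes the root of the
windowed mean of squared responses, so spatially constant maps are fixed
points.
"""

from __future__ import annotations

import dataclasses
from math import comb

import numpy as np

__all__ = [
    "PyramidConfig",
    "SubbandStack",
    "steerable_decompose",
    "reconstruct",
    "simple_cells",
    "complex_cells",
    "l2_pool",
    "v1_features",
]


@dataclasses.dataclass(frozen=True)
class PyramidConfig:
    n_orientations: int = 4
    n_scales: int = 3
    pool_window: int = 4
    pool_stride: int = 2

    def __post_init__(self):
        if self.n_orientations < 2 or self.n_scales < 1:
            raise ValueError("need >= 2 orientations and >= 1 scale")
        if self.pool_window < self.pool_stride:
            raise ValueError("pool_window must be >= pool_stride")


@dataclasses.dataclass
class SubbandStack:
    """Complex oriented subbands keyed by (scale, orientation), plus real
    high/low residuals. Band at scale s is downsampled by 2**(s-1)."""

    bands: dict[tuple[int, int], np.ndarray]
    highpass: np.ndarray
    lowpass: np.ndarray
    size: int
    config: PyramidConfig


def _radial_lowpass(r: np.ndarray, cutoff: float) -> np.ndarray:
    """Raised-cosine (in log2 radius) lowpass: 1 below cutoff/2, 0 above."""
    out = np.zeros_like(r)
    out[r <= cutoff / 2] = 1.0
    trans = (r > cutoff / 2) & (r < cutoff)
    out[trans] = np.cos(np.pi / 2 * np.log2(2 * r[trans] / cutoff))
    return out


def _polar_grid(size: int) -> tuple[np.ndarray, np.ndarray]:
    f = np.fft.fftfreq(size) * 2 * np.pi
    fy, fx = f[:, None], f[None, :]
    return np.hypot(fy, fx), np.arctan2(fy, fx)


def _build_masks(size: int, config: PyramidConfig):
    """Real filter masks whose squares sum to one, plus half-plane doubling
    masks for the analytic (quadrature) bands."""
    r, theta = _polar_grid(size)
    n_sc, n_or = config.n_scales, config.n_orientations
    lows = [_radial_lowpass(r, np.pi / 2**s) for s in range(n_sc + 1)]
    highs = [np.sqrt(np.clip(1 - lo**2, 0, 1)) for lo in lows]
    highpass = highs[0]
    radial_bands = []
    prod = np.ones_like(r)
    for s in range(1, n_sc + 1):
        prod = prod * lows[s - 1]
        radial_bands.append(prod * highs[s])
    lowres = prod * lows[n_sc]
    n = n_or - 1
    norm = np.sqrt(n_or * comb(2 * n, n) / 4.0**n)
    oriented, halfmask = [], []
    for k in range(n_or):
        th_k = np.pi * k / n_or
        d = np.cos(theta - th_k)
        oriented.append(np.abs(d) ** n / norm)
        halfmask.append(np.where(d > 1e-12, 2.0, np.where(d < -1e-12, 0.0, 1.0)))
    return highpass, radial_bands, lowres, oriented, halfmask


def _fourier_downsample(spec: np.ndarray, factor: int) -> np.ndarray:
    """Exact decimation of a band-limited signal by central spectrum crop."""
    if factor == 1:
        return np.fft.ifft2(spec)
    n = spec.shape[0]
    m = n // factor
    sh = np.fft.fftshift(spec)
    lo = n // 2 - m // 2
    crop = sh[lo:lo + m, lo:lo + m]
    return np.fft.ifft2(np.fft.ifftshift(crop)) / factor**2


def _fourier_upsample(img: np.ndarray, factor: int, n: int) -> np.ndarray:
    """Inverse of `_fourier_downsample`: zero-pad the spectrum back to n."""
    if factor == 1:
        return np.fft.fft2(img)
    m = img.shape[0]
    spec = np.fft.fftshift(np.fft.fft2(img)) * factor**2
    out = np.zeros((n, n), dtype=complex)
    lo = n // 2 - m // 2
    out[lo:lo + m, lo:lo + m] = spec
    return np.fft.ifftshift(out)


def steerable_decompose(image: np.ndarray, config: PyramidConfig = PyramidConfig()
                        ) -> SubbandStack:
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2 or image.shape[0] != image.shape[1]:
        raise ValueError("expected a square single-channel image")
    size = image.shape[0]
    if size % 2**config.n_scales != 0 or size < 2 ** (config.n_scales + 2):
        raise ValueError(
            f"image side {size} too small or not divisible by 2^{config.n_scales}"
        )
    highpass, radial_bands, lowres, oriented, halfmask = _build_masks(size, config)
    spec = np.fft.fft2(image)
    bands: dict[tuple[int, int], np.ndarray] = {}
    for s, rb in enumerate(radial_bands, start=1):
        factor = 2 ** (s - 1)
        for k in range(config.n_orientations):
            band_spec = spec * rb * oriented[k] * halfmask[k]
            bands[(s, k)] = _fourier_downsample(band_spec, factor)
    hp = np.real(np.fft.ifft2(spec * highpass))
    lp = np.real(_fourier_downsample(spec * lowres, 2**config.n_scales))
    return SubbandStack(bands=bands, highpass=hp, lowpass=lp, size=size,
                        config=config)


def reconstruct(stack: SubbandStack) -> np.ndarray:
    """Synthesis: refilter every stored band and sum; exact for the tight
    frame (relative L2 error at machine precision)."""
    config, size = stack.config, stack.size
    highpass, radial_bands, lowres, oriented, _ = _build_masks(size, config)
    acc = np.fft.fft2(stack.highpass) * highpass
    for (s, k), band in stack.bands.items():
        factor = 2 ** (s - 1)
        spec = _fourier_upsample(np.real(band), factor, size)
        acc = acc + spec * radial_bands[s - 1] * oriented[k]
    acc = acc + _fourier_upsample(stack.lowpass, 2**config.n_scales, size) * lowres
    return np.real(np.fft.ifft2(acc))


def simple_cells(stack: SubbandStack) -> dict[tuple[int, int], np.ndarray]:
    """Half-wave rectified even/odd phase channels: for each subband a
    (4, h, w) array of [relu(re), relu(-re), relu(im), relu(-im)]."""
    out = {}
    for key, band in stack.bands.items():
        re, im = np.real(band), np.imag(band)
        out[key] = np.stack([
            np.maximum(re, 0), np.maximum(-re, 0),
            np.maximum(im, 0), np.maximum(-im, 0),
        ])
    return out


def complex_cells(stack: SubbandStack) -> dict[tuple[int, int], np.ndarray]:
    """Quadrature energy: modulus of each complex subband."""
    return {key: np.abs(band) for key, band in stack.bands.items()}


def l2_pool(response_map: np.ndarray, pool_window: int, pool_stride: int
            ) -> np.ndarray:
    """Root of the windowed mean of squares (valid windows only), applied to
    the trailing two axes. Constant maps are fixed points."""
    h, w = response_map.shape[-2:]
    if pool_window > h or pool_window > w:
        raise ValueError(f"pool window {pool_window} exceeds map extent {h}x{w}")
    sq = response_map.astype(np.float64) ** 2
    win = np.lib.stride_tricks.sliding_window_view(sq, (pool_window, pool_window),
                                                   axis=(-2, -1))
    win = win[..., ::pool_stride, ::pool_stride, :, :]
    return np.sqrt(win.mean(axis=(-2, -1)))


def v1_features(image: np.ndarray, config: PyramidConfig = PyramidConfig()
                ) -> np.ndarray:
    """Concatenated pooled simple- and complex-cell responses across all
    scales and orientations; non-negative, deterministic, fixed length for a
    fixed config and image size."""
    stack = steerable_decompose(image, config)
    simple = simple_cells(stack)
    energy = complex_cells(stack)
    feats = []
    for key in sorted(stack.bands):
        extent = stack.bands[key].shape[-1]
        window = min(config.pool_window, extent)
        stride = min(config.pool_stride, window)
        feats.append(l2_pool(simple[key], window, stride).ravel())
        feats.append(l2_pool(energy[key], window, stride).ravel())
    return np.concatenate(feats)
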