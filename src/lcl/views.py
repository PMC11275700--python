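"""Complexity-scaled view generation for layerwise self-supervised training.

Each layer sees augmented view pairs cut from a central patch of the input
image. The patch size, output view size, and spatial-deformation strength
(minimum random-resized-crop area fraction) are all doubled between layer 1
and layer 2, matching the approximate doubling of receptive field size
between cortical areas V1 and V2. Photometric distortion is deliberately
weak (mild contrast/luminance jitter plus Gaussian noise); aggressive
augmentations such as flips, strong color jitter or blur are excluded.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "PhotometricSpec",
    "AugmentSpec",
    "ComplexitySchedule",
    "central_crop",
    "random_resized_crop",
    "photometric_distort",
    "make_view_pair",
    "default_schedule",
    "deformation_strength_ladder",
    "schedule_to_yaml",
    "schedule_from_yaml",
]


@dataclasses.dataclass(frozen=True)
class PhotometricSpec:
    """Weak photometric distortion ranges, sampled uniformly per view."""

    contrast_range: tuple[float, float] = (0.8, 1.2)
    luminance_range: tuple[float, float] = (-0.1, 0.1)
    noise_sigma_range: tuple[float, float] = (0.0, 0.05)

    def __post_init__(self):
        for lo, hi in (self.contrast_range, self.noise_sigma_range):
            if lo < 0 or hi < lo:
                raise ValueError("photometric ranges must be non-negative and ordered")


@dataclasses.dataclass(frozen=True)
class AugmentSpec:
    """Per-layer augmentation: central patch -> random resized crop -> view.

    ``area_scale_range=None`` disables spatial deformation (identity resize
    of the full patch); ``non_overlap=True`` forces the two views of a pair
    onto disjoint patch regions.
    """

    patch_size: int
    view_size: int
    area_scale_range: tuple[float, float] | None = (0.6, 0.9)
    aspect_range: tuple[float, float] = (3 / 4, 4 / 3)
    photometric: PhotometricSpec = dataclasses.field(default_factory=PhotometricSpec)
    non_overlap: bool = False

    def __post_init__(self):
        if self.view_size > self.patch_size:
            raise ValueError("view_size must not exceed patch_size")
        if self.area_scale_range is not None:
            lo, hi = self.area_scale_range
            if not (0 < lo <= hi <= 1):
                raise ValueError("area_scale_range must satisfy 0 < lo <= hi <= 1")
        if self.aspect_range[0] > self.aspect_range[1] or self.aspect_range[0] <= 0:
            raise ValueError("invalid aspect_range")


@dataclasses.dataclass
class ComplexitySchedule:
    """Per-layer augmentation specs with a geometric complexity scaling."""

    layers: list[AugmentSpec]
    scale_factor: int = 2

    def validate(self) -> None:
        for a, b in zip(self.layers, self.layers[1:]):
            if b.patch_size != self.scale_factor * a.patch_size:
                raise ValueError("patch_size does not follow the scaling rule")
            if b.view_size != self.scale_factor * a.view_size:
                raise ValueError("view_size does not follow the scaling rule")
            if a.area_scale_range is not None and b.area_scale_range is not None:
                # deformation strength doubles: minimum area scale halves
                if not np.isclose(a.area_scale_range[0],
                                  self.scale_factor * b.area_scale_range[0]):
                    raise ValueError("minimum area scale does not follow the scaling rule")

    @property
    def max_patch_size(self) -> int:
        return max(spec.patch_size for spec in self.layers)


def default_schedule() -> ComplexitySchedule:
    """Layer 1: 56 px patch -> 48 px views, RRC scale (0.6, 0.9).
    Layer 2: 112 px patch -> 96 px views, RRC scale (0.3, 0.9)."""
    phot = PhotometricSpec()
    sched = ComplexitySchedule(layers=[
        AugmentSpec(patch_size=56, view_size=48, area_scale_range=(0.6, 0.9),
                    photometric=phot),
        AugmentSpec(patch_size=112, view_size=96, area_scale_range=(0.3, 0.9),
                    photometric=phot),
    ])
    sched.validate()
    return sched


def deformation_strength_ladder() -> dict:
    """Spatial-deformation strengths for the complexity-mismatch ablation:
    0 = none, 1-3 = minimum RRC area scales 0.6 / 0.3 / 0.08, plus a
    'non_overlap' mode forcing disjoint crop supports."""
    return {
        0: None,
        1: (0.6, 0.9),
        2: (0.3, 0.9),
        3: (0.08, 0.9),
        "non_overlap": "non_overlap",
    }


def central_crop(image: np.ndarray, size: int) -> np.ndarray:
    h, w = image.shape[:2]
    if size > h or size > w:
        raise ValueError(f"crop size {size} exceeds image extent {h}x{w}")
    oy = (h - size) // 2
    ox = (w - size) // 2
    return image[oy:oy + size, ox:ox + size]


def _resize_bilinear(img: np.ndarray, out_size: int) -> np.ndarray:
    """Bilinear resampling with half-pixel-center (align_corners=False)
    semantics, clamped at borders."""
    h, w = img.shape[:2]
    if h == out_size and w == out_size:
        return img.copy()
    sy, sx = h / out_size, w / out_size
    yc = np.clip((np.arange(out_size) + 0.5) * sy - 0.5, 0, h - 1)
    xc = np.clip((np.arange(out_size) + 0.5) * sx - 0.5, 0, w - 1)
    y0 = np.floor(yc).astype(int)
    x0 = np.floor(xc).astype(int)
    y1 = np.minimum(y0 + 1, h - 1)
    x1 = np.minimum(x0 + 1, w - 1)
    wy = (yc - y0)[:, None]
    wx = (xc - x0)[None, :]
    a = img[np.ix_(y0, x0)]
    b = img[np.ix_(y0, x1)]
    c = img[np.ix_(y1, x0)]
    d = img[np.ix_(y1, x1)]
    return (a * (1 - wy) * (1 - wx) + b * (1 - wy) * wx
            + c * wy * (1 - wx) + d * wy * wx)


def sample_crop_geometry(patch_shape: tuple[int, int],
                         area_scale_range: tuple[float, float],
                         aspect_range: tuple[float, float],
                         rng: np.random.Generator,
                         max_tries: int = 10):
    """Sample (top, left, height, width): area fraction uniform in range,
    aspect ratio log-uniform over the sub-range feasible for the drawn area
    (so the area-fraction law stays exactly uniform). Falls back to the
    maximal centered crop when the geometry is infeasible after bounded
    retries."""
    h, w = patch_shape
    area = h * w
    for _ in range(max_tries):
        frac = rng.uniform(*area_scale_range)
        target = frac * area
        # cw = sqrt(target * aspect) <= w  and  ch = sqrt(target / aspect) <= h
        a_lo = max(aspect_range[0], target / h**2)
        a_hi = min(aspect_range[1], w**2 / target)
        if a_lo > a_hi:
            continue
        aspect = np.exp(rng.uniform(np.log(a_lo), np.log(a_hi)))
        cw = int(round(np.sqrt(target * aspect)))
        ch = int(round(np.sqrt(target / aspect)))
        if 0 < cw <= w and 0 < ch <= h:
            top = int(rng.integers(0, h - ch + 1))
            left = int(rng.integers(0, w - cw + 1))
            return top, left, ch, cw
    logger.debug("crop sampler fell back to maximal centered crop")
    side = min(h, w)
    return (h - side) // 2, (w - side) // 2, side, side


def random_resized_crop(patch: np.ndarray, view_size: int,
                        area_scale_range: tuple[float, float],
                        aspect_range: tuple[float, float],
                        rng: np.random.Generator) -> np.ndarray:
    top, left, ch, cw = sample_crop_geometry(
        patch.shape[:2], area_scale_range, aspect_range, rng)
    crop = patch[top:top + ch, left:left + cw]
    return _resize_bilinear(crop, view_size)


def photometric_distort(view: np.ndarray, photometric: PhotometricSpec,
                        rng: np.random.Generator) -> np.ndarray:
    """Multiplicative contrast about the mean, additive luminance shift,
    then additive Gaussian noise; clipped to [0, 1]."""
    contrast = rng.uniform(*photometric.contrast_range)
    luminance = rng.uniform(*photometric.luminance_range)
    sigma = rng.uniform(*photometric.noise_sigma_range)
    out = (view - view.mean()) * contrast + view.mean() + luminance
    if sigma > 0:
        out = out + rng.normal(0.0, sigma, size=view.shape)
    return np.clip(out, 0.0, 1.0)


def _sample_nonoverlap_pair(patch_shape: tuple[int, int],
                            rng: np.random.Generator):
    """Two crop rectangles with empty intersection: split the patch along a
    random axis at a random boundary and crop within each half."""
    h, w = patch_shape
    if rng.random() < 0.5:  # vertical split
        cut = int(rng.integers(h // 4, 3 * h // 4 + 1))
        regions = [(0, 0, cut, w), (cut, 0, h - cut, w)]
    else:
        cut = int(rng.integers(w // 4, 3 * w // 4 + 1))
        regions = [(0, 0, h, cut), (0, cut, h, w - cut)]
    rng.shuffle(regions)
    return regions


def make_view_pair(image: np.ndarray, spec: AugmentSpec,
                   rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """One central patch, two independently augmented views of it."""
    patch = central_crop(image, spec.patch_size)
    views = []
    if spec.non_overlap:
        regions = _sample_nonoverlap_pair(patch.shape[:2], rng)
        for top, left, rh, rw in regions:
            sub = patch[top:top + rh, left:left + rw]
            views.append(_resize_bilinear(sub, spec.view_size))
    elif spec.area_scale_range is None:
        views = [_resize_bilinear(patch, spec.view_size) for _ in range(2)]
    else:
        views = [
            random_resized_crop(patch, spec.view_size, spec.area_scale_range,
                                spec.aspect_range, rng)
            for _ in range(2)
        ]
    return tuple(photometric_distort(v, spec.photometric, rng) for v in views)


# ---------------------------------------------------------------------------
# YAML (de)serialization of schedules
# ---------------------------------------------------------------------------

def schedule_to_yaml(schedule: ComplexitySchedule) -> str:
    payload = {
        "scale_factor": schedule.scale_factor,
        "layers": [
            {
                "patch_size": s.patch_size,
                "view_size": s.view_size,
                "area_scale_range": list(s.area_scale_range) if s.area_scale_range else None,
                "aspect_range": list(s.aspect_range),
                "non_overlap": s.non_overlap,
                "photometric": {
                    "contrast_range": list(s.photometric.contrast_range),
                    "luminance_range": list(s.photometric.luminance_range),
                    "noise_sigma_range": list(s.photometric.noise_sigma_range),
                },
            }
            for s in schedule.layers
        ],
    }
    return yaml.safe_dump(payload, sort_keys=False)


def schedule_from_yaml(text: str) -> ComplexitySchedule:
    payload = yaml.safe_load(text)
    layers = []
    for entry in payload["layers"]:
        phot = PhotometricSpec(
            contrast_range=tuple(entry["photometric"]["contrast_range"]),
            luminance_range=tuple(entry["photometric"]["luminance_range"]),
            noise_sigma_range=tuple(entry["photometric"]["noise_sigma_range"]),
        )
        asr = entry["area_scale_range"]
        layers.append(AugmentSpec(
            patch_size=entry["patch_size"],
            view_size=entry["view_size"],
            area_scale_range=tuple(asr) if asr is not None else None,
            aspect_range=tuple(entry["aspect_range"]),
            photometric=phot,
            non_overlap=entry.get("non_overlap", False),
        ))
    return ComplexitySchedule(layers=layers, scale_factor=payload["scale_factor"])
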