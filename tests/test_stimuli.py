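"""Texture-family generation, spectral matching, corpus statistics, I/O."""

import numpy as np
import pytest

from lcl import stimuli
from lcl.stimuli import (StimulusSet, TextureFamilySpec, build_v2_stimulus_set,
                         load_stimulus_set, make_texture_family,
                         make_training_corpus, save_stimulus_set,
                         spectral_match_noise)


def oriented_energy_profile(img: np.ndarray, n_bins: int = 8) -> np.ndarray:
    """Independent oracle: mean spectral energy inside angular wedges."""
    spec = np.abs(np.fft.fft2(img - img.mean())) ** 2
    size = img.shape[0]
    fy = np.fft.fftfreq(size)[:, None]
    fx = np.fft.fftfreq(size)[None, :]
    theta = np.mod(np.arctan2(fy, fx), np.pi)
    r = np.hypot(fy, fx)
    mask = (r > 0.02) & (r < 0.45)
    edges = np.linspace(0, np.pi, n_bins + 1)
    prof = np.array([
        spec[mask & (theta >= lo) & (theta < hi)].mean()
        for lo, hi in zip(edges[:-1], edges[1:])
    ])
    return prof / prof.sum()


class TestMakeTextureFamily:
    def test_count_size_and_range(self):
        spec = TextureFamilySpec(seed=1)
        imgs = make_texture_family(spec, n_samples=15, size=64)
        assert len(imgs) == 15
        assert all(im.shape == (64, 64) for im in imgs)
        assert all(0 <= im.min() and im.max() <= 1 for im in imgs)

    def test_deterministic_given_seed(self):
        spec = TextureFamilySpec(seed=5)
        a = make_texture_family(spec, 3, 64)
        b = make_texture_family(spec, 3, 64)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)

    def test_samples_differ_but_share_orientation_stats(self):
        spec = TextureFamilySpec(orientation=0.3, orientation_bw=0.25, seed=2)
        imgs = make_texture_family(spec, 6, 64)
        assert np.abs(imgs[0] - imgs[1]).max() > 0
        profiles = np.stack([oriented_energy_profile(im) for im in imgs])
        # peak orientation bin consistent within the family
        assert len(set(profiles.argmax(axis=1))) <= 2

    def test_orientation_bandwidth_changes_energy_profile(self):
        narrow = TextureFamilySpec(orientation=0.5, orientation_bw=0.15, seed=3)
        broad = TextureFamilySpec(orientation=0.5, orientation_bw=0.9, seed=3)
        prof_n = np.mean([oriented_energy_profile(im)
                          for im in make_texture_family(narrow, 5, 64)], axis=0)
        prof_b = np.mean([oriented_energy_profile(im)
                          for im in make_texture_family(broad, 5, 64)], axis=0)
        # a narrower angular band concentrates energy in fewer wedges
        assert prof_n.max() > prof_b.max() + 0.02

    def test_size_too_small_for_band_rejected(self):
        spec = TextureFamilySpec(freq=0.05)
        with pytest.raises(ValueError, match="too small"):
            make_texture_family(spec, 2, 32)

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            make_texture_family(TextureFamilySpec(freq=0.3), 1, 64)


class TestSpectralMatchNoise:
    def test_amplitude_spectrum_preserved(self, rng):
        img = 0.25 + 0.5 * rng.random((48, 48))
        out, info = spectral_match_noise(img, rng_seed=0, return_info=True)
        amp_in = np.abs(np.fft.fft2(img))
        amp_out = np.abs(np.fft.fft2(info["unclipped"]))
        assert np.abs(amp_in - amp_out).max() < 1e-6
        assert np.isclose(info["unclipped"].mean(), img.mean())

    def test_constant_image_is_fixed_point(self):
        img = np.full((32, 32), 0.7)
        out = spectral_match_noise(img, rng_seed=1)
        np.testing.assert_allclose(out, img, atol=1e-12)

    def test_sinusoid_maps_to_shifted_sinusoid(self):
        x = np.arange(64)
        img = 0.5 + 0.3 * np.sin(2 * np.pi * 5 * x / 64)[None, :] * np.ones((64, 1))
        out = spectral_match_noise(img, rng_seed=2)
        spec_in, spec_out = np.fft.fft2(img), np.fft.fft2(out)
        np.testing.assert_allclose(np.abs(spec_out), np.abs(spec_in), atol=1e-8)
        # energy still concentrated on the same frequency pair
        idx_in = np.argsort(np.abs(spec_in).ravel())[-3:]
        idx_out = np.argsort(np.abs(spec_out).ravel())[-3:]
        assert set(idx_in) == set(idx_out)

    def test_nonfinite_rejected(self):
        img = np.zeros((16, 16))
        img[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            spectral_match_noise(img)

    def test_rgb_uses_shared_phases(self, rng):
        base = 0.3 + 0.4 * rng.random((32, 32))
        img = np.stack([base, base, base], axis=-1)
        out = spectral_match_noise(img, rng_seed=3)
        # identical channels + shared phase field -> identical outputs
        np.testing.assert_allclose(out[..., 0], out[..., 1], atol=1e-12)


class TestBuildV2StimulusSet:
    @pytest.mark.parametrize("families,samples,expected", [(1, 1, 2), (3, 4, 24)])
    def test_counts(self, families, samples, expected):
        stim = build_v2_stimulus_set(families, samples, size=48, rng_seed=0)
        assert len(stim) == expected
        assert (stim.meta.condition == "texture").sum() == expected // 2

    def test_pairing_is_bijection(self, small_stimulus_set):
        small_stimulus_set.validate()
        tex = small_stimulus_set.meta.query("condition == 'texture'")
        noi = small_stimulus_set.meta.query("condition == 'noise'")
        assert set(zip(tex.family_id, tex.sample_id)) == set(
            zip(noi.family_id, noi.sample_id))

    def test_validate_rejects_broken_pairing(self, small_stimulus_set):
        broken = StimulusSet(
            images=small_stimulus_set.images[:-1],
            meta=small_stimulus_set.meta.iloc[:-1].reset_index(drop=True),
            size=small_stimulus_set.size)
        with pytest.raises(ValueError, match="bijection"):
            broken.validate()


class TestTrainingCorpus:
    def test_shape_and_determinism(self):
        c1 = make_training_corpus(5, size=64, rng_seed=0)
        c2 = make_training_corpus(5, size=64, rng_seed=0)
        assert c1.shape == (5, 64, 64)
        np.testing.assert_array_equal(c1, c2)
        c3 = make_training_corpus(5, size=64, rng_seed=1)
        assert np.abs(c1 - c3).max() > 0

    def test_power_spectrum_slope_natural(self, small_corpus):
        """Radially averaged power spectrum slope in [-2.5, -1.5] (log-log)."""
        size = small_corpus.shape[-1]
        f = np.fft.fftfreq(size)
        r = np.hypot(f[:, None], f[None, :])
        power = np.mean([np.abs(np.fft.fft2(im - im.mean())) ** 2
                         for im in small_corpus[:20]], axis=0)
        bins = np.logspace(np.log10(2 / size), np.log10(0.4), 12)
        centers, means = [], []
        for lo, hi in zip(bins[:-1], bins[1:]):
            m = (r >= lo) & (r < hi)
            if m.any():
                centers.append(np.sqrt(lo * hi))
                means.append(power[m].mean())
        slope = np.polyfit(np.log(centers), np.log(means), 1)[0]
        assert -2.5 <= slope <= -1.5

    def test_min_size_guard(self):
        with pytest.raises(ValueError, match="smaller than"):
            make_training_corpus(1, size=64, min_size=112)


def test_png_npz_csv_round_trip(tmp_path, small_stimulus_set):
    save_stimulus_set(small_stimulus_set, tmp_path)
    loaded = load_stimulus_set(tmp_path)
    np.testing.assert_array_equal(loaded.images, small_stimulus_set.images)
    assert loaded.meta.equals(small_stimulus_set.meta)
    pngs = list(tmp_path.glob("*.png"))
    assert len(pngs) == len(small_stimulus_set)
    assert (tmp_path / "metadata.csv").exists()
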