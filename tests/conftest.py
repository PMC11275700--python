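import numpy as np
import pytest

from lcl.encoder import ProjectorConfig, StageConfig, TwoStageEncoder
from lcl.views import AugmentSpec, ComplexitySchedule, PhotometricSpec


TINY_STAGES = (
    StageConfig(out_channels=8, kernel=5, stride=2, padding=2),
    StageConfig(out_channels=16, kernel=3, stride=1, padding=1),
)
TINY_PROJECTORS = (ProjectorConfig(hidden_dim=16, out_dim=8),
                   ProjectorConfig(hidden_dim=16, out_dim=8))


def tiny_encoder(seed: int = 0) -> TwoStageEncoder:
    return TwoStageEncoder(stage_configs=TINY_STAGES,
                           projector_configs=TINY_PROJECTORS, seed=seed)


def tiny_schedule() -> ComplexitySchedule:
    phot = PhotometricSpec()
    sched = ComplexitySchedule(layers=[
        AugmentSpec(patch_size=24, view_size=16, area_scale_range=(0.6, 0.9),
                    photometric=phot),
        AugmentSpec(patch_size=48, view_size=32, area_scale_range=(0.3, 0.9),
                    photometric=phot),
    ])
    sched.validate()
    return sched


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_stimulus_set():
    from lcl.stimuli import build_v2_stimulus_set

    return build_v2_stimulus_set(n_families=4, n_samples=5, size=64, rng_seed=7)


@pytest.fixture(scope="session")
def full_stimulus_set():
    """The canonical 15-family x 15-sample texture/noise design (450 images)."""
    from lcl.stimuli import build_v2_stimulus_set

    return build_v2_stimulus_set(n_families=15, n_samples=15, size=64, rng_seed=0)


@pytest.fixture(scope="session")
def small_corpus():
    from lcl.stimuli import make_training_corpus

    return make_training_corpus(40, size=64, rng_seed=3)
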