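import numpy as np
import pytest

from ersa.config import PipelineConfig, StudyConfig
from ersa.spectral import FrequencyGrid, TimeFrequencyRepresentation
from ersa.synth import generate_dataset


def small_study(seed: int = 0, **overrides) -> StudyConfig:
    """A reduced cohort that keeps every structural feature of the default."""
    cfg = StudyConfig(
        n_participants=2,
        n_trials_per_condition={"AR": 8, "IR": 8, "M": 4, "CR": 4},
        seed=seed,
    )
    for key, val in overrides.items():
        setattr(cfg, key, val)
    return cfg


def small_pipeline(seed: int = 0) -> PipelineConfig:
    cfg = PipelineConfig()
    cfg.study = small_study(seed)
    cfg.analysis.precision = "float32"
    cfg.analysis.map_enc_range = (0.3, 1.2)
    cfg.analysis.map_ret_range = (0.8, 1.7)
    cfg.stats.n_permutations = 100
    cfg.stats.seed = seed
    return cfg


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small two-participant study with all planted effects, generated once."""
    return generate_dataset(small_study(seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def synthetic_tfr(power: np.ndarray, t0: float = -1.0, step: float = 0.01,
                  normalization: str = "relative",
                  lock: str = "stimulus") -> TimeFrequencyRepresentation:
    """Wrap an arbitrary (n_trials, 43, n_times) power array as a TFR."""
    grid = FrequencyGrid.default()
    power = np.asarray(power, dtype=float)
    assert power.shape[1] == grid.n_frequencies
    times = t0 + step * np.arange(power.shape[2])
    valid = np.ones((power.shape[1], power.shape[2]), dtype=bool)
    return TimeFrequencyRepresentation(power=power, times=times, grid=grid,
                                       valid=valid, normalization=normalization,
                                       lock=lock)
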