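import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from qams.analytes import CANONICAL_FOUR
from qams.peakio import RunMeta, StandardSolution
from qams.synth import GeneratorConfig, make_control_run, make_sample_run

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def noise_free_config() -> GeneratorConfig:
    return GeneratorConfig(rt_jitter_sd=0.0, area_noise_cv=0.0, seed=0)


@pytest.fixture
def standard_mix() -> StandardSolution:
    """Equal-concentration four-analyte control mix, 0.02 mg/mL each."""
    return StandardSolution({a: 0.02 for a in CANONICAL_FOUR}, label="mix")


@pytest.fixture
def control_run(noise_free_config, standard_mix):
    return make_control_run(noise_free_config, standard_mix)


@pytest.fixture
def sample_meta() -> RunMeta:
    return RunMeta(sample_mass=1.0, extraction_volume=50.0)


@pytest.fixture
def sample_run(noise_free_config, sample_meta):
    return make_sample_run(noise_free_config, sample_meta)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20190808)
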