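import pytest
from hypothesis import settings, HealthCheck

from cordyqc import chromio, synthgen

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_config():
    """The default three-class, 30-sample study design."""
    return synthgen.default_config(seed=1234)


@pytest.fixture(scope="session")
def study(default_config):
    """Simulated 30-sample study with ground truth."""
    return synthgen.generate_study(default_config)


@pytest.fixture(scope="session")
def study_tables(study, default_config):
    """(noise estimate, matched peak tables) for the simulated study."""
    samples, _truth = study
    noise = chromio.estimate_noise(samples[0], (0.5, 2.0))
    detected = [(c.sample_id, chromio.detect_peaks(c, noise)) for c in samples]
    tables = chromio.match_common_peaks(
        detected, synthgen.reference_times(default_config))
    return noise, tables
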