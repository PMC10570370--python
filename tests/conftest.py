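import pytest

from c2netms.pipeline import RunConfig, run_pipeline
from c2netms.simulate import SimulationConfig


@pytest.fixture(scope="session")
def default_result():
    """One full pipeline run under the default (noisy) study conditions."""
    return run_pipeline(RunConfig(random_seed=11))


@pytest.fixture(scope="session")
def noiseless_config():
    """Study conditions with mass error, noise and dropout switched off."""
    sim = SimulationConfig(
        mass_error_ppm=0.0, noise_peaks=0, replicate_dropout=0.0, random_seed=5,
    )
    return RunConfig(simulation=sim, random_seed=5)


@pytest.fixture(scope="session")
def noiseless_result(noiseless_config):
    return run_pipeline(noiseless_config)
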