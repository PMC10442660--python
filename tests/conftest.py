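import numpy as np
import pytest

from nirhsi.pipeline import PipelineConfig, run_all
from nirhsi.preprocess import PreprocessParams, preprocess_specimen
from nirhsi.synth import SpecimenConfig, simulate_specimen


@pytest.fixture
def small_config():
    """A fast, fully exposed specimen for unit tests."""
    return SpecimenConfig(
        shape=(64, 88),
        semi_axes=(18.0, 26.0),
        core_fraction=1.0,
        seed=11,
    )


@pytest.fixture
def clean_config(small_config):
    """Same geometry with every stochastic nuisance switched off."""
    from dataclasses import replace

    return replace(
        small_config, noise_sd=0.0, bio_sd=0.0, n_highlight=0, n_shadow=0, n_necrosis=0
    )


@pytest.fixture
def specimen(small_config):
    return simulate_specimen(small_config, specimen_id="unit")


@pytest.fixture
def preprocessed(specimen):
    return preprocess_specimen(
        specimen.specimen_id, specimen.calibration, specimen.annotation, PreprocessParams()
    )


@pytest.fixture(scope="session")
def default_run():
    """One full pipeline run on the default 10-specimen cohort (seed 1).

    Session-scoped: several structural and statistical checks share it.
    """
    return run_all(PipelineConfig(seed=1))


@pytest.fixture
def rng():
    return np.random.default_rng(42)
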