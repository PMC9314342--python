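import pytest

from agemodel import (
    SimulationConfig,
    TemplateSequence,
    build_model,
    simulate_cohort,
)
from agemodel.metrics import validate_model
from agemodel.simulate import shepp_logan, smooth_random_svf


@pytest.fixture(scope="session")
def phantom():
    return shepp_logan((128, 128))


@pytest.fixture
def smooth_field():
    """Factory for seeded smooth random SVFs."""
    return smooth_random_svf


@pytest.fixture(scope="session")
def small_config():
    """A reduced synthetic configuration for fast pipeline-level tests."""
    return SimulationConfig(
        grid_shape=(64, 64),
        n_subjects=6,
        n_timepoints=3,
        n_bump_sites=5,
        site_radius=6.0,
        sigma_subject=1.5,
        aging_magnitudes=(0.5, 1.0, 1.5),
        ages=(40.0, 50.0, 60.0),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture(scope="session")
def small_model(small_cohort):
    seq = TemplateSequence(small_cohort.templates, small_cohort.ages)
    return build_model(seq)


@pytest.fixture(scope="session")
def default_cohort():
    """The full default study conditions: 50 subjects x 5 timepoints, 128x128."""
    return simulate_cohort(SimulationConfig())


@pytest.fixture(scope="session")
def default_model(default_cohort):
    seq = TemplateSequence(default_cohort.templates, default_cohort.ages)
    return build_model(seq)


@pytest.fixture(scope="session")
def default_report(default_model, default_cohort):
    return validate_model(default_model, default_cohort)
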