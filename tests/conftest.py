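import logging

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")

logging.disable(logging.WARNING)


@pytest.fixture(scope="session")
def constants18():
    from photophys import carbonate as cb

    return cb.equilibrium_constants(18.0, 35.0)


@pytest.fixture(scope="session")
def study_df():
    from photophys import carbonate as cb

    return cb.load_study_conditions()


@pytest.fixture(scope="session")
def small_bundle():
    """A reduced factorial dataset (2 lights x 2 reps) for module tests."""
    from photophys import synthdata as sd

    design = sd.StudyDesign(light_levels=(30.0, 160.0), replicates=2, seed=11)
    return sd.sim_study(design)
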