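import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from bhtyper import phantom

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_spec():
    """A quick cohort: coarse grid, smaller lesions, still straddling 100 voxels."""
    return phantom.CohortSpec(
        n_subjects=5,
        grid_shape=(40, 40, 40),
        lesion_size_range=(60, 300),
        mean_lesions_per_subject=6.0,
        master_seed=11,
    )


@pytest.fixture(scope="session")
def subject(small_spec):
    return phantom.generate_subject(small_spec, 0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
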