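import numpy as np
import pytest

from vesselrep import CardiacModel, T1W_GATED, default_scene, render_scene
from vesselrep.cohort import CohortConfig, simulate_cohort
from vesselrep.pipeline import quantify_cohort


@pytest.fixture(scope="session")
def small_scene():
    """Cropped-FOV T1W scene at the full 0.390625 mm resolution."""
    return default_scene(T1W_GATED, "T1W", matrix=(96, 96))


@pytest.fixture(scope="session")
def gated_acquisition(small_scene):
    return render_scene(small_scene, T1W_GATED, CardiacModel(), repeat_index=1, seed=1234)


@pytest.fixture(scope="session")
def small_cohort_metrics():
    """Quantified metrics of a seeded 6-subject T1W cohort (cropped FOV)."""
    config = CohortConfig(n_subjects=6, weightings=("T1W",), matrix=(96, 96), seed=99)
    records, truth = simulate_cohort(config)
    return quantify_cohort(records), truth


def rng(seed=0):
    return np.random.default_rng(seed)
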