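import numpy as np
import pytest

from slidequant import pipeline as pipe
from slidequant import synthetic as synth

#: master seed of the reference synthetic study used by the acceptance tests
EXPERIMENT_SEED = 1234


@pytest.fixture(scope="session")
def experiment():
    """Full-scale synthetic study: 20-slide cohorts at 8x8 mm, 4 um/px.

    Session-scoped because rendering and quantifying the three cohorts takes
    minutes; every acceptance-level check shares this one run.
    """
    return pipe.run_synthetic_experiment(
        master_seed=EXPERIMENT_SEED, n_slides=20, canvas_mm=(8.0, 8.0), mpp=4.0)


@pytest.fixture(scope="session")
def small_vessel_slide():
    """One homogeneous vessel slide at reduced scale for unit-level checks."""
    spec = synth.vessel_marker_spec(mpp=8.0)
    return next(iter(synth.iter_cohort(1, 0.0, spec, 42, (4.0, 4.0))))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
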