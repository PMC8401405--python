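import numpy as np
import pytest

from ergokin import SegmentRotation
from ergokin.evaluation import arm_swing_rmse, cohort_median_velocities


@pytest.fixture
def identity_rotation():
    return SegmentRotation(np.eye(3))


@pytest.fixture(scope="session")
def swing_benchmark():
    """Angle/velocity RMSE of both sensor paths on the standard arm swing."""
    return arm_swing_rmse(seed=1)


@pytest.fixture(scope="session")
def cohort_medians():
    """Group-mean median velocities for the four variants on a fast cohort."""
    return cohort_median_velocities(n_subjects=6, seed=7)
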