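import numpy as np
import pytest

from boldmse.cohort import CohortConfig, PlantedRoi


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def tiny_config():
    """A desk-scale cohort config for fast end-to-end unit tests."""
    return CohortConfig(
        group_sizes={"NC": 3, "EMCI": 3, "LMCI": 3, "AD": 3},
        shape=(8, 8, 8),
        n_timepoints=60,
        n_dummy=5,
        rois=(PlantedRoi("planted", (0.0, 0.0, 0.0), radius_mm=6.0),),
    )
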