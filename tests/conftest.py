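import numpy as np
import pytest

from neurotimescales.roi_spheres import RoiSpec
from neurotimescales.synth_data import CohortConfig, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def tiny_rois():
    # two spheres well inside the tiny 12^3 grid below
    return [
        RoiSpec("roiA", "synthetic sphere A", (-6.0, -6.0, -6.0), 6.0, "W"),
        RoiSpec("roiB", "synthetic sphere B", (9.0, 9.0, 9.0), 6.0, "U"),
    ]


def tiny_affine():
    aff = np.diag([3.0, 3.0, 3.0, 1.0])
    aff[:3, 3] = -18.0
    return aff


@pytest.fixture(scope="session")
def tiny_config(tiny_rois):
    return CohortConfig(
        n_per_group=(4, 3, 3),
        n_volumes=200,
        grid_shape=(12, 12, 12),
        affine=tiny_affine(),
        rois=tiny_rois,
        group_effect={"SZ": {"roiA": 0.1}},
        mask_mode="full",
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    return simulate_cohort(tiny_config)


@pytest.fixture(scope="session")
def default_cohort():
    """Full-size cohort (55/30/39, 947 volumes) on the sphere-union mask."""
    return simulate_cohort(CohortConfig(seed=11))
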