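import numpy as np
import pytest

import earlygad as eg

PHANTOM_SHAPE = (64, 64, 64)
VOXEL_SIZE = 1.5

DAY_ENHANCEMENT = {
    "cerebral_cortex": 166.4,
    "cerebellar_cortex": 174.6,
    "cerebral_white_matter": 39.3,
    "cerebellar_white_matter": 50.4,
    "basal_ganglia": 40.0,
    "bg_pvs": 87.2,
    "choroid_plexus": 869.7,
}


@pytest.fixture(scope="session")
def labels64() -> eg.LabelVolume:
    return eg.build_label_volume(PHANTOM_SHAPE, VOXEL_SIZE)


@pytest.fixture(scope="session")
def rendered64(labels64):
    """Day-condition phantom with moderate voxel noise."""
    return eg.render_t1_pair(labels64, DAY_ENHANCEMENT, noise_sd=10.0, seed=7)


@pytest.fixture(scope="session")
def rendered64_clean(labels64):
    """Noiseless day-condition phantom (exact ground truth)."""
    return eg.render_t1_pair(labels64, DAY_ENHANCEMENT, noise_sd=0.0, seed=0)


@pytest.fixture(scope="session")
def default_cohort():
    return eg.generate_cohort(seed=123)


@pytest.fixture(scope="session")
def center64():
    return eg.volume_center_world(PHANTOM_SHAPE, VOXEL_SIZE)
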