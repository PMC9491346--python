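import numpy as np
import pytest

from narsync import (
    BoldSimConfig,
    make_assignment,
    make_design,
    simulate_bold_cohort,
)


@pytest.fixture(scope="session")
def small_design():
    """Four videos in two runs of two, 13-volume clips, trim 2."""
    return make_design(
        n_videos=4, n_runs=2, tr_seconds=2.62, trim_volumes=2,
        duration_volumes=13, gap_volumes=3,
    )


@pytest.fixture(scope="session")
def small_assignment(small_design):
    return make_assignment(small_design, 8, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_design, small_assignment):
    cfg = BoldSimConfig(
        n_subjects=8,
        grid_shape=(6, 6, 6),
        design=small_design,
        assignment=small_assignment,
        shared_gain_base=1.0,
        noise_sd=1.0,
        seed=101,
    )
    return simulate_bold_cohort(cfg)


@pytest.fixture(scope="session")
def full_mask():
    return np.ones((6, 6, 6), dtype=bool)
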