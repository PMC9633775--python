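import numpy as np
import pytest

import dyngrad as dg


@pytest.fixture(scope="session")
def small_cohort():
    """One modest synthetic cohort shared by read-only tests."""
    return dg.make_cohort(seed=7, n_regions=30, n_targets=20, n_scans=2, n_frames=300)


@pytest.fixture(scope="session")
def small_truth(small_cohort):
    return small_cohort.truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
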