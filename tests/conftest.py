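import numpy as np
import pytest

from plvmotif.atlas import desk_atlas
from plvmotif.cohort import make_design


@pytest.fixture(scope="session")
def design39():
    """Default 39-subject roster (22 controls / 17 binge drinkers)."""
    return make_design(seed=0)


@pytest.fixture(scope="session")
def atlas24():
    """Desk-scale 24-node (4 per ROI) atlas."""
    return desk_atlas()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
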