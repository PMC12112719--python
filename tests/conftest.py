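import numpy as np
import pytest

from ubdesign.constants import UBIQUITIN_WT
from ubdesign.fixtures import FixtureConfig, make_library, make_pose_deck


@pytest.fixture(scope="session")
def small_library():
    """A 40-record scaffold library with scaled-down class marginals."""
    marginals = {
        "HER2": {"SB": 5, "MB": 4, "WB": 2},
        "FINC_EDB": {"SB": 3, "MB": 3, "WB": 2},
        "Others": {"SB": 7, "MB": 8, "WB": 6},
    }
    cfg = FixtureConfig(
        seed=11, library_size=40, monomer_count=18, class_marginals=marginals
    )
    return make_library(cfg), cfg


@pytest.fixture(scope="session")
def pose_deck():
    """A 60-pose fixture deck with its greedy ground truth."""
    return make_pose_deck(FixtureConfig(seed=5, pose_deck_size=60))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def wt():
    return UBIQUITIN_WT
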