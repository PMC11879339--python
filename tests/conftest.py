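import logging

import numpy as np
import pandas as pd
import pytest

from seepecol.io import CommunityTable, read_newick
from seepecol import simulate as sim

logging.getLogger("seepecol").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def three_tip_tree():
    """((A:1,B:1):1,C:2); — d(A,B)=2, d(A,C)=d(B,C)=4."""
    return read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def small_table():
    counts = pd.DataFrame(
        {"s1": [5, 2, 0], "s2": [0, 1, 4]},
        index=["ASV1", "ASV2", "ASV3"],
    )
    return CommunityTable(counts)


@pytest.fixture(scope="session")
def survey():
    """Small synthetic survey shared by the slower integration tests."""
    return sim.simulate_survey(n_tips=120, seed=1234, read_depth=3000, n_groups=6)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
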