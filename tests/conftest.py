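import numpy as np
import pandas as pd
import pytest

import phyloendemism as pe


@pytest.fixture
def three_tip_tree():
    return pe.DatedTree.from_string("((A:1,B:1):1,C:2);")


@pytest.fixture
def star_tree():
    """Star tree with four pendant branches of length 1."""
    return pe.DatedTree.from_string("(t1:1,t2:1,t3:1,t4:1);")


@pytest.fixture
def small_matrix():
    df = pd.DataFrame(
        [[1, 0], [1, 1], [0, 1]],
        index=["A", "B", "C"],
        columns=["west", "east"],
    )
    return pe.CommunityMatrix(df)


def random_matrix(species, areas, seed, p=0.4):
    """Random binary occupancy with every species present somewhere."""
    rng = np.random.default_rng(seed)
    arr = (rng.random((len(species), len(areas))) < p).astype(np.int8)
    for i in range(len(species)):
        if arr[i].sum() == 0:
            arr[i, rng.integers(len(areas))] = 1
    return pe.CommunityMatrix(
        pd.DataFrame(arr, index=list(species), columns=list(areas))
    )
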