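import numpy as np
import pandas as pd
import pytest

from phylopest import (
    collapse_to_genus,
    make_fixture,
    pairwise_distances,
    read_tree_string,
)


@pytest.fixture
def three_tip_tree():
    return read_tree_string("((A:10,B:10):5,C:15);")


@pytest.fixture(scope="session")
def yule50():
    from phylopest import simulate_tree

    return simulate_tree(50, 160.0, seed=42)


@pytest.fixture(scope="session")
def tiny_dataset():
    """12 genera x 30 pests synthetic dataset with known signal."""
    tree, records, truth = make_fixture("tiny", seed=5)
    incidence = collapse_to_genus(records, tree.tip_labels)
    distances = pairwise_distances(tree)
    return tree, records, truth, incidence, distances


@pytest.fixture(scope="session")
def paper_scale_dataset():
    """210 genera x 1670 pests in the published group proportions."""
    tree, records, truth = make_fixture("paper-scale", seed=1)
    incidence = collapse_to_genus(records, tree.tip_labels)
    return tree, records, truth, incidence


def incidence_from_hosts(host_map, genera, groups=None):
    """Build an IncidenceMatrix directly from pest -> host-list mappings."""
    from phylopest.incidence import IncidenceMatrix

    mat = pd.DataFrame(
        0,
        index=pd.Index(list(host_map), name="pest_id"),
        columns=list(genera),
        dtype=np.int8,
    )
    for pest, hosts in host_map.items():
        mat.loc[pest, list(hosts)] = 1
    grp = pd.Series(
        {p: (groups or {}).get(p, "fungi") for p in host_map}, name="pest_group"
    )
    return IncidenceMatrix(matrix=mat, groups=grp.loc[mat.index])
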