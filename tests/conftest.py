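import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from skullnet import SkullNetwork, BoneNode, toy_skull_fixture
from skullnet.network import SIDE_LEFT, SIDE_RIGHT, SIDE_MIDLINE


def net_from_edges(edges, labels=None, specimen_id="test"):
    """Build a SkullNetwork from an undirected edge list."""
    if labels is None:
        labels = sorted({x for e in edges for x in e})
    idx = {l: i for i, l in enumerate(labels)}
    adj = np.zeros((len(labels), len(labels)), dtype=int)
    for u, v in edges:
        adj[idx[u], idx[v]] = adj[idx[v], idx[u]] = 1
    nodes = [BoneNode.from_label(l) for l in labels]
    return SkullNetwork(specimen_id=specimen_id, nodes=nodes, adjacency=adj)


def net_from_adjacency(adj, specimen_id="test"):
    labels = [f"n{i:02d}" for i in range(adj.shape[0])]
    nodes = [BoneNode(l, l, SIDE_MIDLINE) for l in labels]
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return SkullNetwork(specimen_id=specimen_id, nodes=nodes, adjacency=np.asarray(adj))


@pytest.fixture
def toy_net():
    return toy_skull_fixture()


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)
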