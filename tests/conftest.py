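import numpy as np
import pytest

from dynconsensus import (
    BinaryConnectome,
    Cohort,
    WeightedConnectome,
)
from dynconsensus.synthetic import synthetic_node_table


def make_binary(adj, nodes=None):
    adj = np.asarray(adj)
    if nodes is None:
        nodes = synthetic_node_table(adj.shape[0], rng_seed=0)
    return BinaryConnectome(adjacency=adj, nodes=nodes)


def make_weighted(w, nodes=None):
    w = np.asarray(w, dtype=float)
    if nodes is None:
        nodes = synthetic_node_table(w.shape[0], rng_seed=0)
    return WeightedConnectome(weights=w, nodes=nodes)


def adjacency_from_edges(n, edges):
    a = np.zeros((n, n), dtype=np.int8)
    for i, j in edges:
        a[i, j] = a[j, i] = 1
    return a


def random_binary_cohort(n_subjects, n_nodes, p=0.5, seed=0):
    rng = np.random.default_rng(seed)
    nodes = synthetic_node_table(n_nodes, rng_seed=seed)
    members = []
    for _ in range(n_subjects):
        upper = rng.random((n_nodes, n_nodes)) < p
        a = np.triu(upper, k=1).astype(np.int8)
        a += a.T
        members.append(BinaryConnectome(adjacency=a, nodes=nodes))
    return Cohort(members=members, nodes=nodes)


@pytest.fixture
def nodes4():
    return synthetic_node_table(4, rng_seed=1)


@pytest.fixture
def k4(nodes4):
    a = 1 - np.eye(4, dtype=np.int8)
    return BinaryConnectome(adjacency=a, nodes=nodes4)
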