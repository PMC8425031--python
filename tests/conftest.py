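from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from tgso.io_formats import (
    ExpressionTable,
    LocalizationTable,
    OrthologyTable,
    PPINetwork,
)

COMPARTMENTS = [f"C{i:02d}" for i in range(11)]


def make_network(n, edges):
    """Network over all n nodes N000.. in identity index order (isolated
    nodes retained), with explicit index edges."""
    import scipy.sparse as sp

    ids = [f"N{i:03d}" for i in range(n)]
    rows, cols = [], []
    for i, j in set(map(lambda e: tuple(sorted(e)), edges)):
        rows += [i, j]
        cols += [j, i]
    adjacency = sp.csr_matrix(
        (np.ones(len(rows), dtype=np.int8), (rows, cols)), shape=(n, n)
    )
    return PPINetwork(node_ids=ids, adjacency=adjacency), ids


def random_graph(rng, n=12, p=0.3):
    """Erdős–Rényi edge list guaranteed non-empty."""
    while True:
        iu, ju = np.triu_indices(n, k=1)
        keep = rng.random(iu.size) < p
        edges = list(zip(iu[keep].tolist(), ju[keep].tolist()))
        if edges:
            return edges


def random_instance(seed, n=12, p=0.3, t=8, coverage=1.0, annotated=1.0):
    """A full random input set: network + expression + localization + orthology.

    ``coverage``/``annotated`` thin the expression and localization tables to
    exercise the missing-data conventions.
    """
    rng = np.random.default_rng(seed)
    edges = random_graph(rng, n, p)
    network, ids = make_network(n, edges)
    covered = [pid for pid in ids if rng.random() < coverage]
    expr = ExpressionTable(
        data=pd.DataFrame(rng.normal(size=(len(covered), t)), index=covered)
    )
    sets = {}
    for pid in ids:
        if rng.random() < annotated:
            k = int(rng.integers(1, 4))
            sets[pid] = frozenset(
                rng.choice(COMPARTMENTS, size=k, replace=False).tolist()
            )
    loc = LocalizationTable(sets=sets, vocabulary=list(COMPARTMENTS))
    orth = OrthologyTable(
        counts={pid: int(rng.integers(0, 100)) for pid in ids}, n_organisms=99
    )
    return network, expr, loc, orth


@pytest.fixture
def triangle():
    return make_network(3, [(0, 1), (1, 2), (0, 2)])


@pytest.fixture
def path3():
    return make_network(3, [(0, 1), (1, 2)])


@pytest.fixture
def star4():
    return make_network(4, [(0, 1), (0, 2), (0, 3)])
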