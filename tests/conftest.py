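"""Shared builders for small in-memory graph databases."""

import itertools

import numpy as np
import pytest

from braincliques.graph_io import BrainGraph, GraphDatabase, ROI


def make_db(edge_lists, n_vertices=None, groups=None, ids=None, labels=None):
    """Build a GraphDatabase from per-subject lists of (i, j) index pairs."""
    if n_vertices is None:
        n_vertices = 1 + max(
            (v for edges in edge_lists for e in edges for v in e), default=1
        )
    if labels is None:
        labels = [f"v{i:02d}" for i in range(n_vertices)]
    atlas = {i: ROI(name=labels[i], index=i) for i in range(n_vertices)}
    if ids is None:
        # numeric six-digit IDs with alternating parity at the second digit
        ids = [str(100000 + 10 * i) for i in range(len(edge_lists))]
    if groups is None:
        groups = ["all"] * len(edge_lists)
    graphs = [
        BrainGraph(
            subject_id=sid,
            n_vertices=n_vertices,
            edges=frozenset(tuple(sorted(e)) for e in edges),
        )
        for sid, edges in zip(ids, edge_lists)
    ]
    return GraphDatabase(
        graphs=graphs, atlas=atlas, group_of=dict(zip(ids, groups))
    )


def random_db(rng, n_vertices, n_graphs, p):
    """Erdos-Renyi database: each edge independently present per graph."""
    pairs = list(itertools.combinations(range(n_vertices), 2))
    edge_lists = [
        [e for e in pairs if rng.random() < p] for _ in range(n_graphs)
    ]
    return make_db(edge_lists, n_vertices=n_vertices)


@pytest.fixture
def rng():
    return np.random.default_rng(20240817)


@pytest.fixture
def triangle_db():
    """Five identical triangles on vertices {0,1,2} (4-vertex atlas)."""
    tri = [(0, 1), (0, 2), (1, 2)]
    return make_db([tri] * 5, n_vertices=4)
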