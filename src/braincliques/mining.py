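"""Frequent complete-subgraph (clique) mining over a graph database.

A *pattern* is a complete subgraph, identified by its strictly ascending
vertex-index tuple (the vertex set determines the edge set).  A pattern is
*frequent* when it is contained — every implied edge present — in at least a
threshold fraction of the database's graphs.

The miner is level-wise, in the apriori style for frequent item sets:
level 2 is the frequent edges; a ``(k+1)``-candidate is generated by joining
two frequent ``k``-patterns that share their first ``k-1`` vertices, and only
the single new edge needs verifying.  Downward closure (anti-monotonicity)
makes this complete: every sub-clique of a frequent clique is at least as
frequent, so every frequent ``(k+1)``-clique has both of its join parents in
level ``k``, and the ascending-order convention generates each candidate
exactly once.

Support counting keeps, for each pattern, the bitmask of supporting subjects;
a join candidate's mask is the AND of its parents' masks with the new edge's
mask, giving exact counts without rescanning graphs.

Frequency comparisons are exact: the threshold is held as a rational number
and compared as ``count * q >= p * N``, so borderline cases (e.g. support
4/5 at threshold 80%) never depend on floating-point rounding.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Sequence

import pandas as pd

from .graph_io import BrainGraph, GraphDatabase

__all__ = [
    "CliquePattern",
    "FrequencyRecord",
    "MiningConfig",
    "as_threshold",
    "contains_pattern",
    "count_support",
    "apriori_join",
    "mine_frequent_cliques",
    "brute_force_mine",
    "maximal_patterns",
    "downward_closure",
    "records_to_frame",
]

#: a complete subgraph in canonical form: strictly ascending vertex indices
CliquePattern = tuple[int, ...]


def _check_canonical(pattern: Sequence[int]) -> CliquePattern:
    pattern = tuple(pattern)
    if len(pattern) < 2:
        raise ValueError(f"pattern must have >= 2 vertices, got {pattern}")
    if any(a >= b for a, b in zip(pattern, pattern[1:])):
        raise ValueError(f"pattern {pattern} is not strictly ascending")
    return pattern


def implied_edges(pattern: Sequence[int]) -> list[tuple[int, int]]:
    """All (k choose 2) edges of the complete graph on ``pattern``."""
    return list(itertools.combinations(pattern, 2))


@dataclass(frozen=True)
class FrequencyRecord:
    """A pattern with its database-wide support count."""

    pattern: CliquePattern
    count: int
    n_graphs: int

    @property
    def frequency(self) -> Fraction:
        """Exact support fraction count / N."""
        return Fraction(self.count, self.n_graphs)

    @property
    def size(self) -> int:
        return len(self.pattern)


def as_threshold(value: "float | str | Fraction") -> Fraction:
    """Normalize a frequency threshold to an exact rational in (0, 1].

    Floats are interpreted through their decimal representation, so 0.8
    means exactly 4/5 rather than the nearest binary float.
    """
    if isinstance(value, Fraction):
        frac = value
    elif isinstance(value, float):
        frac = Fraction(str(value))
    elif isinstance(value, (str, int)):
        frac = Fraction(value)
    else:
        raise TypeError(f"cannot interpret threshold {value!r}")
    if not (0 < frac <= 1):
        raise ValueError(f"threshold must be in (0, 1], got {frac}")
    return frac


@dataclass
class MiningConfig:
    """Mining parameters: frequency threshold (default 80%) and size cap."""

    threshold: "float | str | Fraction" = 0.8
    max_size: int | None = None

    def __post_init__(self) -> None:
        self.threshold = as_threshold(self.threshold)
        if self.max_size is not None and self.max_size < 2:
            raise ValueError("max_size must be >= 2")


def contains_pattern(graph: BrainGraph, pattern: Sequence[int]) -> bool:
    """True iff every implied edge of the clique pattern is in the graph."""
    pattern = _check_canonical(pattern)
    if pattern[-1] >= graph.n_vertices:
        raise ValueError(
            f"pattern vertex {pattern[-1]} outside atlas of size {graph.n_vertices}"
        )
    return all((i, j) in graph.edges for i, j in itertools.combinations(pattern, 2))


def count_support(db: GraphDatabase, pattern: Sequence[int]) -> int:
    """Number of graphs in the database containing the pattern."""
    return sum(contains_pattern(g, pattern) for g in db.graphs)


def apriori_join(L1: Sequence[int], L2: Sequence[int]) -> CliquePattern | None:
    """Join two size-k patterns into a size-(k+1) candidate, or ``None``.

    The join fires only when the first k-1 vertices agree and the last
    vertices satisfy ``L1[-1] < L2[-1]``; each candidate is therefore
    generated from exactly one ordered parent pair.  The single new implied
    edge is ``(L1[-1], L2[-1])``.
    """
    L1 = _check_canonical(L1)
    L2 = _check_canonical(L2)
    if len(L1) != len(L2):
        raise ValueError("apriori join requires equal-size patterns")
    if L1[:-1] != L2[:-1] or L1[-1] >= L2[-1]:
        return None
    return L1 + (L2[-1],)


def _is_frequent(count: int, n: int, threshold: Fraction) -> bool:
    # exact rational comparison: count/n >= p/q  <=>  count*q >= p*n
    return count * threshold.denominator >= threshold.numerator * n


def _edge_masks(db: GraphDatabase) -> dict[tuple[int, int], int]:
    """Supporting-subject bitmask for every edge occurring in the database."""
    masks: dict[tuple[int, int], int] = {}
    for g_idx, graph in enumerate(db.graphs):
        bit = 1 << g_idx
        for e in graph.edges:
            masks[e] = masks.get(e, 0) | bit
    return masks


def mine_frequent_cliques(
    db: GraphDatabase, config: MiningConfig | None = None
) -> list[FrequencyRecord]:
    """All complete subgraphs frequent in the database, with exact counts.

    Returns the full downward-closed (redundant) family: every sub-clique of
    a reported clique is itself reported.  Patterns are sorted by size, then
    lexicographically; the result does not depend on graph order in the
    database or edge order within graphs.
    """
    if config is None:
        config = MiningConfig()
    if len(db) == 0:
        raise ValueError("cannot mine an empty database")
    n = len(db)
    threshold = as_threshold(config.threshold)

    edge_masks = _edge_masks(db)
    level: dict[CliquePattern, int] = {
        e: m for e, m in edge_masks.items() if _is_frequent(m.bit_count(), n, threshold)
    }
    records: list[FrequencyRecord] = [
        FrequencyRecord(pattern=e, count=m.bit_count(), n_graphs=n)
        for e, m in level.items()
    ]

    k = 2
    while level and (config.max_size is None or k < config.max_size):
        # group frequent k-patterns by their k-1 prefix; each ordered pair
        # within a group with ascending last vertices yields one candidate
        by_prefix: dict[CliquePattern, list[CliquePattern]] = {}
        for pat in level:
            by_prefix.setdefault(pat[:-1], []).append(pat)
        next_level: dict[CliquePattern, int] = {}
        for group in by_prefix.values():
            group.sort()
            for a_idx in range(len(group)):
                for b_idx in range(a_idx + 1, len(group)):
                    L1, L2 = group[a_idx], group[b_idx]
                    new_edge = (L1[-1], L2[-1])
                    edge_mask = edge_masks.get(new_edge, 0)
                    if not edge_mask:
                        continue
                    mask = level[L1] & level[L2] & edge_mask
                    if _is_frequent(mask.bit_count(), n, threshold):
                        next_level[L1 + (L2[-1],)] = mask
        records.extend(
            FrequencyRecord(pattern=p, count=m.bit_count(), n_graphs=n)
            for p, m in next_level.items()
        )
        level = next_level
        k += 1

    records.sort(key=lambda r: (r.size, r.pattern))
    return records


def brute_force_mine(
    db: GraphDatabase, config: MiningConfig | None = None
) -> list[FrequencyRecord]:
    """Exhaustive-enumeration reference miner for small atlases.

    Enumerates every vertex subset of size 2..n and tests containment
    per graph directly — no candidate generation, no shared state with
    :func:`mine_frequent_cliques`.  Guarded to atlases of at most 20
    vertices.
    """
    if config is None:
        config = MiningConfig()
    if len(db) == 0:
        raise ValueError("cannot mine an empty database")
    n_vertices = db.n_vertices
    if n_vertices > 20:
        raise ValueError(
            f"brute-force mining is limited to 20 vertices, atlas has {n_vertices}"
        )
    n = len(db)
    threshold = as_threshold(config.threshold)
    max_size = config.max_size or n_vertices

    # union adjacency: a subset absent here is a clique in no graph
    union_edges = frozenset().union(*(g.edges for g in db.graphs)) if db.graphs else frozenset()
    graph_edge_sets = [g.edges for g in db.graphs]

    records: list[FrequencyRecord] = []
    vertices = range(n_vertices)
    for k in range(2, min(n_vertices, max_size) + 1):
        found_any = False
        for subset in itertools.combinations(vertices, k):
            pairs = list(itertools.combinations(subset, 2))
            if any(e not in union_edges for e in pairs):
                continue
            count = sum(all(e in edges for e in pairs) for edges in graph_edge_sets)
            if _is_frequent(count, n, threshold):
                found_any = True
                records.append(
                    FrequencyRecord(pattern=subset, count=count, n_graphs=n)
                )
        if not found_any:
            break  # downward closure: no frequent k-clique => none larger
    records.sort(key=lambda r: (r.size, r.pattern))
    return records


def maximal_patterns(records: Iterable[FrequencyRecord]) -> list[FrequencyRecord]:
    """Records whose vertex set is not a proper subset of another record's.

    Maximality is within the mined family (the frequent patterns), not
    within any single graph.
    """
    recs = list(records)
    sets = [frozenset(r.pattern) for r in recs]
    out = []
    for i, r in enumerate(recs):
        if not any(i != j and sets[i] < sets[j] for j in range(len(recs))):
            out.append(r)
    out.sort(key=lambda r: (r.size, r.pattern))
    return out


def downward_closure(patterns: Iterable[Sequence[int]]) -> set[CliquePattern]:
    """All sub-cliques (size >= 2) of the given patterns, canonical form."""
    closed: set[CliquePattern] = set()
    for pat in patterns:
        pat = _check_canonical(pat)
        for k in range(2, len(pat) + 1):
            closed.update(itertools.combinations(pat, k))
    return closed


def records_to_frame(
    records: Iterable[FrequencyRecord], atlas: "dict | None" = None
) -> pd.DataFrame:
    """Tabulate records: k, vertices (semicolon-joined labels), count, frequency."""
    rows = []
    for r in records:
        if atlas is not None:
            vertices = ";".join(atlas[v].name for v in r.pattern)
        else:
            vertices = ";".join(str(v) for v in r.pattern)
        rows.append(
            {
                "k": r.size,
                "vertices": vertices,
                "count": r.count,
                "frequency": float(r.frequency),
            }
        )
    return pd.DataFrame(rows, columns=["k", "vertices", "count", "frequency"])
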