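"""Synthetic connectome databases with planted cliques.

The generator emulates the statistical structure the mining pipeline
assumes: a fixed atlas shared by all subjects, per-subject graphs built
from *planted cliques* — complete subgraphs whose full edge set is
included independently per subject with a group-specific Bernoulli
probability — over a sparse Erdos-Renyi background.  Edge semantics are
a union: background draws never remove planted edges, and planted
cliques may overlap.

Defaults mirror a two-group human cohort: 238 ``female`` and 175
``male`` subjects, ROI labels prefixed ``lh.``/``rh.`` (cortical) and
``Left-``/``Right-`` (subcortical) split evenly between hemispheres,
and numeric subject IDs whose second digit from the right takes both
parities, so the deterministic split-half filter is exercised.

Every database comes with its ground truth (the planted cliques and
their inclusion probabilities), so each pipeline stage can be checked
against what was actually planted.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .graph_io import BrainGraph, GraphDatabase, ROI
from .mining import CliquePattern, as_threshold, downward_closure

__all__ = [
    "PlantedClique",
    "SyntheticConfig",
    "default_atlas_labels",
    "generate_database",
    "ground_truth_frame",
    "expected_recovery",
    "AmbiguousConfigError",
]

DEFAULT_GROUP_SIZES: dict[str, int] = {"female": 238, "male": 175}


class AmbiguousConfigError(ValueError):
    """Raised when the background is too dense for a clean ground truth."""


@dataclass(frozen=True)
class PlantedClique:
    """A clique planted per subject with group-specific inclusion probability."""

    vertices: CliquePattern
    inclusion_prob: Mapping[str, float]

    def __post_init__(self) -> None:
        v = tuple(self.vertices)
        if len(v) < 2 or any(a >= b for a, b in zip(v, v[1:])):
            raise ValueError(f"planted clique {v} must be strictly ascending, size >= 2")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "inclusion_prob", dict(self.inclusion_prob))
        for g, p in self.inclusion_prob.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"inclusion probability {p} for group {g!r} not in [0,1]")

    def prob(self, group: str) -> float:
        return self.inclusion_prob[group]


@dataclass
class SyntheticConfig:
    """Parameters of one synthetic database."""

    n_vertices: int = 30
    group_sizes: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SIZES)
    )
    planted: Sequence[PlantedClique] = ()
    background_edge_prob: float = 0.02
    hemisphere_labels: bool = True
    subcortical_per_hemisphere: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        self.group_sizes = dict(self.group_sizes)
        if not self.group_sizes or any(s <= 0 for s in self.group_sizes.values()):
            raise ValueError("group sizes must be positive")
        if not (0.0 <= self.background_edge_prob < 1.0):
            raise ValueError("background_edge_prob must be in [0, 1)")
        if self.n_vertices < 2:
            raise ValueError("need at least 2 vertices")
        for pc in self.planted:
            if pc.vertices[-1] >= self.n_vertices:
                raise ValueError(
                    f"planted clique {pc.vertices} exceeds atlas size {self.n_vertices}"
                )
            missing = set(self.group_sizes) - set(pc.inclusion_prob)
            if missing:
                raise ValueError(
                    f"planted clique {pc.vertices} lacks probabilities "
                    f"for groups {sorted(missing)}"
                )

    @property
    def n_subjects(self) -> int:
        return sum(self.group_sizes.values())


def default_atlas_labels(
    n_vertices: int,
    hemisphere_labels: bool = True,
    subcortical_per_hemisphere: int = 2,
) -> list[str]:
    """Atlas label list: half left, half right, mixing both prefix styles.

    The first ``subcortical_per_hemisphere`` labels of each half use the
    ``Left-``/``Right-`` style, the rest the cortical ``lh.``/``rh.``
    style, so both hemisphere-prefix conventions are exercised.  Index
    order equals list order (labels are index-sorted by construction in
    each half).
    """
    if not hemisphere_labels:
        return [f"region_{i:03d}" for i in range(n_vertices)]
    n_left = n_vertices // 2 + n_vertices % 2
    labels = []
    for side, prefix_sub, prefix_cort, count in (
        ("left", "Left-", "lh.", n_left),
        ("right", "Right-", "rh.", n_vertices - n_left),
    ):
        n_sub = min(subcortical_per_hemisphere, count)
        labels += [f"{prefix_sub}Sub{i + 1:02d}" for i in range(n_sub)]
        labels += [f"{prefix_cort}region_{i + 1:03d}" for i in range(count - n_sub)]
    return labels


def _subject_ids(n: int) -> list[str]:
    """Six-digit numeric IDs whose second-from-right digit alternates parity."""
    return [str(100000 + 10 * i) for i in range(n)]


def generate_database(config: SyntheticConfig) -> GraphDatabase:
    """Generate one database per the config; deterministic under its seed.

    Per subject: each planted clique's full edge set is included with its
    group's probability (one coin per clique per subject), then each
    vertex pair independently receives a background edge with
    ``background_edge_prob``; the union is the subject's graph.
    """
    rng = np.random.default_rng(config.seed)
    labels = default_atlas_labels(
        config.n_vertices, config.hemisphere_labels,
        config.subcortical_per_hemisphere,
    )
    atlas = {i: ROI(name=lbl, index=i) for i, lbl in enumerate(labels)}

    # deterministic subject order: groups sorted by name, IDs interleaved
    memberships = [
        (group, idx)
        for group in sorted(config.group_sizes)
        for idx in range(config.group_sizes[group])
    ]
    ids = _subject_ids(len(memberships))

    all_pairs = list(itertools.combinations(range(config.n_vertices), 2))
    bg_p = config.background_edge_prob

    graphs = []
    group_of = {}
    for sid, (group, _) in zip(ids, memberships):
        edges: set[tuple[int, int]] = set()
        for pc in config.planted:
            if rng.random() < pc.prob(group):
                edges.update(itertools.combinations(pc.vertices, 2))
        if bg_p > 0:
            draws = rng.random(len(all_pairs))
            edges.update(
                pair for pair, u in zip(all_pairs, draws) if u < bg_p
            )
        graphs.append(
            BrainGraph(subject_id=sid, n_vertices=config.n_vertices,
                       edges=frozenset(edges))
        )
        group_of[sid] = group
    return GraphDatabase(graphs=graphs, atlas=atlas, group_of=group_of)


def ground_truth_frame(config: SyntheticConfig) -> pd.DataFrame:
    """Tabulate the planted cliques and their per-group probabilities."""
    groups = sorted(config.group_sizes)
    rows = []
    for pc in config.planted:
        row = {"vertices": ";".join(map(str, pc.vertices)),
               "k": len(pc.vertices)}
        for g in groups:
            row[f"prob_{g}"] = pc.prob(g)
        rows.append(row)
    return pd.DataFrame(rows, columns=["vertices", "k", *([f"prob_{g}" for g in groups])])


def expected_recovery(
    config: SyntheticConfig,
    threshold: "float | str | Fraction" = 0.8,
    margin: float = 0.05,
    max_expected_background_edges: float = 0.01,
) -> list[CliquePattern]:
    """Planted cliques expected frequent at the threshold (maximal list).

    A planted clique is expected when its cohort-mixed inclusion
    probability — the group-size-weighted mean of its per-group
    probabilities — is at least ``threshold + margin``; the margin keeps
    binomial sampling noise from straddling the cutoff.  The downward
    closure of the returned cliques is the expected mined family.

    Refuses (raises :class:`AmbiguousConfigError`) configs whose
    background alone is expected to make edges frequent: the expected
    number of frequent background-only edges, from the exact binomial
    tail at the cohort size, must stay below
    ``max_expected_background_edges``.
    """
    thr = as_threshold(threshold)
    n = config.n_subjects
    # minimal support count achieving the threshold
    min_count = -(-thr.numerator * n // thr.denominator)  # ceil

    bg_p = config.background_edge_prob
    if bg_p > 0:
        tail = float(stats.binom.sf(min_count - 1, n, bg_p))
        n_pairs = config.n_vertices * (config.n_vertices - 1) // 2
        expected_bg = n_pairs * tail
        if expected_bg > max_expected_background_edges:
            raise AmbiguousConfigError(
                f"background edge probability {bg_p} is too dense for a clean "
                f"ground truth: expected {expected_bg:.3g} frequent "
                f"background edges at threshold {thr} with {n} subjects"
            )

    cutoff = float(thr) + margin
    expected = []
    for pc in config.planted:
        mixed = sum(
            config.group_sizes[g] * pc.prob(g) for g in config.group_sizes
        ) / n
        if mixed >= cutoff:
            expected.append(pc.vertices)
    return sorted(expected, key=lambda p: (len(p), p))
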