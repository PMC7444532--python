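"""Split-half robustness filtering for frequent-clique families.

Two procedures harden the mined family against cohort-composition noise:

1. *Deterministic split-half*: partition the cohort by the parity of a
   digit of the numeric subject ID (default: second digit from the right),
   mine each half at the threshold, keep only the patterns frequent in
   *both* halves, then recount each survivor's frequency on the full
   cohort.  The full-cohort frequency may fall below the threshold and is
   reported as-is.

2. *Randomized equal-cohort crosscheck*: repeatedly draw two disjoint
   random subsets of equal size from one group, apply the same
   mine-both / intersect / recount procedure, and tabulate the retained
   patterns by clique size per run.  This controls for group-size
   imbalance when the two groups being compared have unequal sizes.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .graph_io import GraphDatabase
from .mining import (
    FrequencyRecord,
    MiningConfig,
    count_support,
    mine_frequent_cliques,
)

__all__ = [
    "SplitRule",
    "SplitSpec",
    "split_by_id_parity",
    "robust_frequent_cliques",
    "random_crosscheck",
]


class SplitRule(str, Enum):
    ID_DIGIT_PARITY = "id_digit_parity"
    RANDOM_DISJOINT = "random_disjoint"


@dataclass
class SplitSpec:
    """How to split the cohort for the robustness filter."""

    rule: SplitRule = SplitRule.ID_DIGIT_PARITY
    digit_position: int = 2  # 1 = last digit, 2 = second from the right
    subset_size: int | None = None  # for the random rule
    seed: int | None = None

    def __post_init__(self) -> None:
        self.rule = SplitRule(self.rule)
        if self.digit_position < 1:
            raise ValueError("digit_position must be >= 1")


def _id_digit(subject_id: str, position: int) -> int:
    """The ``position``-th decimal digit from the right of a numeric ID."""
    sid = subject_id.strip()
    if len(sid) < position:
        raise ValueError(
            f"subject ID {subject_id!r} has fewer than {position} characters"
        )
    ch = sid[-position]
    if not ch.isdigit():
        raise ValueError(
            f"subject ID {subject_id!r}: character {ch!r} at position "
            f"{position} from the right is not a decimal digit"
        )
    return int(ch)


def split_by_id_parity(
    db: GraphDatabase, digit_position: int = 2
) -> tuple[GraphDatabase, GraphDatabase]:
    """Partition subjects by parity of an ID digit (even set, odd set).

    The two halves are disjoint and their union is the database; either
    half may be empty in degenerate cases (all IDs sharing the parity).
    """
    even_ids, odd_ids = [], []
    for sid in db.subject_ids:
        (even_ids if _id_digit(sid, digit_position) % 2 == 0 else odd_ids).append(sid)
    even = db.subset(even_ids) if even_ids else _empty_like(db)
    odd = db.subset(odd_ids) if odd_ids else _empty_like(db)
    return even, odd


def _empty_like(db: GraphDatabase) -> GraphDatabase:
    return GraphDatabase(graphs=[], atlas=db.atlas, group_of={})


def _intersect_and_recount(
    db: GraphDatabase,
    half_a: GraphDatabase,
    half_b: GraphDatabase,
    config: MiningConfig,
) -> list[FrequencyRecord]:
    """Mine both halves, intersect pattern sets, recount on the full db."""
    patterns_a = {r.pattern for r in mine_frequent_cliques(half_a, config)}
    patterns_b = {r.pattern for r in mine_frequent_cliques(half_b, config)}
    retained = sorted(patterns_a & patterns_b, key=lambda p: (len(p), p))
    n = len(db)
    return [
        FrequencyRecord(pattern=p, count=count_support(db, p), n_graphs=n)
        for p in retained
    ]


def robust_frequent_cliques(
    db: GraphDatabase,
    config: MiningConfig | None = None,
    split: SplitSpec | None = None,
) -> list[FrequencyRecord]:
    """Patterns frequent in both halves of a split, recounted on the full set.

    The retained family is the intersection of two downward-closed families
    and is therefore itself downward-closed.  Full-set frequencies below
    the mining threshold are reported without re-filtering.
    """
    if config is None:
        config = MiningConfig()
    if split is None:
        split = SplitSpec()
    if split.rule is not SplitRule.ID_DIGIT_PARITY:
        raise ValueError(
            "robust_frequent_cliques uses the deterministic parity rule; "
            "use random_crosscheck for random splits"
        )
    half_a, half_b = split_by_id_parity(db, split.digit_position)
    if len(half_a) == 0 or len(half_b) == 0:
        raise ValueError(
            "parity split produced an empty half; cannot run the robustness filter"
        )
    return _intersect_and_recount(db, half_a, half_b, config)


def random_crosscheck(
    db: GraphDatabase,
    group: str,
    config: MiningConfig | None = None,
    subset_size: int = 50,
    runs: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Equal-size random split-half crosscheck within one group.

    Per run: draw two disjoint ``subset_size``-member subsets of the group
    (without replacement, seeded), mine each at the threshold, intersect,
    and recount survivors on the full database.  Returns a tidy table with
    one row per (run, clique size): columns ``run``, ``k``, ``n_retained``,
    plus ``n_total`` repeated per run.  Identical seeds give identical
    tables.
    """
    if config is None:
        config = MiningConfig()
    group_db = db.group_subset(group)
    ids = group_db.subject_ids
    if len(ids) < 2 * subset_size:
        raise ValueError(
            f"group {group!r} has {len(ids)} subjects; "
            f"need at least {2 * subset_size} for two disjoint subsets"
        )
    rng = np.random.default_rng(seed)
    rows = []
    for run in range(runs):
        chosen = rng.choice(len(ids), size=2 * subset_size, replace=False)
        set1 = [ids[i] for i in chosen[:subset_size]]
        set2 = [ids[i] for i in chosen[subset_size:]]
        retained = _intersect_and_recount(
            db, group_db.subset(set1), group_db.subset(set2), config
        )
        sizes = pd.Series([r.size for r in retained], dtype=int)
        counts = sizes.value_counts().sort_index()
        if len(retained) == 0:
            rows.append({"run": run, "k": 0, "n_retained": 0, "n_total": 0})
        for k, c in counts.items():
            rows.append(
                {"run": run, "k": int(k), "n_retained": int(c),
                 "n_total": len(retained)}
            )
    return pd.DataFrame(rows, columns=["run", "k", "n_retained", "n_total"])
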