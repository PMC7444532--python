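"""Two-group frequency comparison of clique patterns.

For each pattern F, let count_i(F) be its occurrences in group i, S_i the
group size, and supp_i(F) = count_i(F) / S_i the per-group support.  The
null hypothesis — equal appearance frequency in the two groups — is tested
with the Pearson chi-squared statistic on the 2x2 table

    [[count_1, S_1 - count_1],
     [count_2, S_2 - count_2]]

without continuity correction, referred to the chi-squared distribution
with one degree of freedom.  Multiple testing over the pattern family is
handled by the Holm step-down (Holm-Bonferroni) procedure, which controls
the family-wise error rate.

Only patterns whose *larger* group support reaches an inclusion threshold
(default 80%) enter the tested family: a difference between two rare
patterns is not of interest here, and restricting the family also shrinks
the multiplicity burden.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .graph_io import GraphDatabase
from .mining import (
    CliquePattern,
    FrequencyRecord,
    MiningConfig,
    as_threshold,
    count_support,
    mine_frequent_cliques,
)

__all__ = [
    "Direction",
    "ComparisonRecord",
    "chi_squared_stat",
    "p_value",
    "holm_bonferroni",
    "two_group_candidates",
    "compare_groups",
    "comparisons_to_frame",
]


class Direction(str, Enum):
    GROUP1_HIGHER = "group1_higher"
    GROUP2_HIGHER = "group2_higher"
    TIE = "tie"


def chi_squared_stat(count1: int, S1: int, count2: int, S2: int) -> float:
    """Pearson chi-squared statistic for two binomial supports.

    Computed as

        ((count1*(S2-count2) - count2*(S1-count1))^2 * (S1+S2))
        / (S1 * S2 * (count1+count2) * (S1+S2-count1-count2))

    which is algebraically the uncorrected Pearson chi-squared of the 2x2
    table [[count1, S1-count1], [count2, S2-count2]].  Degenerate margins
    (both supports exactly 0% or exactly 100%) have a zero denominator; no
    difference is claimable there and the statistic is defined as 0.
    Evaluated in exact integer arithmetic before the final division.
    """
    if S1 <= 0 or S2 <= 0:
        raise ValueError("group sizes must be positive")
    if not (0 <= count1 <= S1 and 0 <= count2 <= S2):
        raise ValueError("counts must satisfy 0 <= count_i <= S_i")
    num = (count1 * (S2 - count2) - count2 * (S1 - count1)) ** 2 * (S1 + S2)
    den = S1 * S2 * (count1 + count2) * (S1 + S2 - count1 - count2)
    if den == 0:
        return 0.0
    return num / den


def p_value(chi2: float) -> float:
    """Upper-tail probability of the chi-squared(1 df) distribution."""
    if chi2 < 0:
        raise ValueError("chi-squared statistic must be non-negative")
    return float(stats.chi2.sf(chi2, df=1))


def holm_bonferroni(
    p_values: Sequence[float], alpha: float = 0.01
) -> tuple[np.ndarray, np.ndarray]:
    """Holm step-down adjusted p-values and rejection flags.

    Sort the m raw p-values ascending, multiply the i-th smallest by
    (m - i), take the running maximum to enforce monotonicity, cap at 1.
    Rejections are ``adjusted <= alpha``.  Both arrays are returned in the
    original input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.min(p) < 0 or np.max(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    m = p.size
    if m == 0:
        return np.array([]), np.array([], dtype=bool)
    order = np.argsort(p, kind="stable")
    factors = m - np.arange(m)
    adjusted_sorted = np.maximum.accumulate(p[order] * factors)
    adjusted_sorted = np.minimum(adjusted_sorted, 1.0)
    adjusted = np.empty(m)
    adjusted[order] = adjusted_sorted
    return adjusted, adjusted <= alpha


@dataclass(frozen=True)
class ComparisonRecord:
    """One pattern's two-group comparison result."""

    pattern: CliquePattern
    group1: str
    group2: str
    count1: int
    count2: int
    S1: int
    S2: int
    chi2: float
    p_raw: float
    p_holm: float
    direction: Direction
    significant: bool

    @property
    def supp1(self) -> Fraction:
        return Fraction(self.count1, self.S1)

    @property
    def supp2(self) -> Fraction:
        return Fraction(self.count2, self.S2)


def two_group_candidates(
    db: GraphDatabase,
    config: MiningConfig | None = None,
    group1: str | None = None,
    group2: str | None = None,
) -> list[FrequencyRecord]:
    """Candidate family for a group comparison: union of per-group families.

    A pattern can reach 80% support in one group while staying below the
    whole-cohort threshold, so comparison candidates are mined within each
    group separately and the two families are merged.  Counts in the
    returned records are full-database counts; per-group counts are
    recomputed by :func:`compare_groups`.
    """
    if config is None:
        config = MiningConfig()
    groups = db.groups
    if group1 is None or group2 is None:
        if len(groups) != 2:
            raise ValueError(
                f"database has groups {groups}; need exactly two "
                "(or pass group1/group2 explicitly)"
            )
        group1, group2 = groups[0], groups[1]
    fam1 = {r.pattern for r in mine_frequent_cliques(db.group_subset(group1), config)}
    fam2 = {r.pattern for r in mine_frequent_cliques(db.group_subset(group2), config)}
    n = len(db)
    return [
        FrequencyRecord(pattern=p, count=count_support(db, p), n_graphs=n)
        for p in sorted(fam1 | fam2, key=lambda p: (len(p), p))
    ]


def compare_groups(
    records: Iterable[FrequencyRecord],
    db: GraphDatabase,
    group1: str | None = None,
    group2: str | None = None,
    alpha: float = 0.01,
    inclusion_threshold: "float | str | Fraction" = 0.8,
) -> list[ComparisonRecord]:
    """Per-pattern two-group frequency comparison with Holm correction.

    Parameters
    ----------
    records
        The mined pattern family (typically the output of
        :func:`~braincliques.mining.mine_frequent_cliques` or the
        robustness filter).
    db
        Database with exactly two groups (or pass ``group1``/``group2``
        explicitly).  Group assignment is by name, never by position.
    alpha
        Family-wise significance level for the Holm procedure
        (significance is ``p_holm <= alpha``, inclusive).
    inclusion_threshold
        A pattern enters the tested family only if the larger of its two
        group supports reaches this fraction (exact rational comparison).

    The Holm family is the set of all patterns passing the inclusion rule
    in this call, jointly across both directions of difference.
    """
    groups = db.groups
    if group1 is None or group2 is None:
        if len(groups) != 2:
            raise ValueError(
                f"database has groups {groups}; need exactly two "
                "(or pass group1/group2 explicitly)"
            )
        group1, group2 = groups[0], groups[1]
    for g in (group1, group2):
        if g not in groups:
            raise ValueError(f"group {g!r} not present in database")

    incl = as_threshold(inclusion_threshold)
    db1 = db.group_subset(group1)
    db2 = db.group_subset(group2)
    S1, S2 = len(db1), len(db2)

    tested: list[tuple[CliquePattern, int, int]] = []
    for rec in records:
        c1 = count_support(db1, rec.pattern)
        c2 = count_support(db2, rec.pattern)
        # inclusion: max(supp1, supp2) >= threshold, exactly
        if max(Fraction(c1, S1), Fraction(c2, S2)) >= incl:
            tested.append((rec.pattern, c1, c2))

    chi2s = [chi_squared_stat(c1, S1, c2, S2) for _, c1, c2 in tested]
    p_raws = [p_value(x) for x in chi2s]
    p_holms, rejected = holm_bonferroni(p_raws, alpha=alpha)

    out = []
    for (pattern, c1, c2), chi2, p_raw, p_holm, rej in zip(
        tested, chi2s, p_raws, p_holms, rejected
    ):
        s1, s2 = Fraction(c1, S1), Fraction(c2, S2)
        if s1 > s2:
            direction = Direction.GROUP1_HIGHER
        elif s2 > s1:
            direction = Direction.GROUP2_HIGHER
        else:
            direction = Direction.TIE
        out.append(
            ComparisonRecord(
                pattern=pattern,
                group1=group1,
                group2=group2,
                count1=c1,
                count2=c2,
                S1=S1,
                S2=S2,
                chi2=chi2,
                p_raw=p_raw,
                p_holm=float(p_holm),
                direction=direction,
                significant=bool(rej),
            )
        )
    out.sort(key=lambda r: (len(r.pattern), r.pattern))
    return out


def comparisons_to_frame(
    comparisons: Iterable[ComparisonRecord], atlas: "dict | None" = None
) -> pd.DataFrame:
    """Tabulate comparison records, labeling groups and direction by name."""
    rows = []
    for c in comparisons:
        if atlas is not None:
            vertices = ";".join(atlas[v].name for v in c.pattern)
        else:
            vertices = ";".join(str(v) for v in c.pattern)
        higher = {
            Direction.GROUP1_HIGHER: c.group1,
            Direction.GROUP2_HIGHER: c.group2,
            Direction.TIE: "tie",
        }[c.direction]
        rows.append(
            {
                "k": len(c.pattern),
                "vertices": vertices,
                f"count_{c.group1}": c.count1,
                f"count_{c.group2}": c.count2,
                f"freq_{c.group1}": float(c.supp1),
                f"freq_{c.group2}": float(c.supp2),
                "chi2": c.chi2,
                "p_raw": c.p_raw,
                "p_holm": c.p_holm,
                "higher_in": higher,
                "significant": c.significant,
            }
        )
    return pd.DataFrame(rows)
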