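"""Descriptive tabulations of a mined frequent-clique family.

Given the redundant (downward-closed) family of frequent complete
subgraphs, these helpers produce the standard descriptive views: the
clique-size histogram, hemisphere composition per size, the maximal
cliques present in *every* subject, cliques spanning both hemispheres,
and per-ROI appearance counts.

ROI appearance counts are taken over the redundant family — every
sub-clique counted — since that is the family the mining step reports;
counting only maximal patterns would give different (smaller) numbers.
The tables record which family was counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .graph_io import Hemisphere, ROI
from .mining import CliquePattern, FrequencyRecord, maximal_patterns

__all__ = [
    "PatternHemisphere",
    "SummaryTables",
    "hemisphere_of_pattern",
    "all_subject_maximal",
    "roi_appearance_counts",
    "cross_hemisphere_patterns",
    "size_histogram",
    "hemisphere_split",
    "largest_patterns",
    "summarize",
    "format_pattern",
]


#: pattern-level hemisphere classification (beyond the per-ROI enum):
#: "mixed" marks cliques with vertices in both hemispheres
PatternHemisphere = Hemisphere  # reuse left/right/unknown


def hemisphere_of_pattern(
    pattern: Sequence[int], atlas: Mapping[int, ROI]
) -> str:
    """Classify a clique as 'left', 'right', 'mixed' or 'unknown'.

    'left'/'right' when all vertices share that hemisphere; 'mixed' when
    both hemispheres occur; 'unknown' when any vertex is unclassifiable.
    """
    hemis = {atlas[v].hemisphere for v in pattern}
    if Hemisphere.UNKNOWN in hemis:
        return "unknown"
    if hemis == {Hemisphere.LEFT}:
        return "left"
    if hemis == {Hemisphere.RIGHT}:
        return "right"
    return "mixed"


def all_subject_maximal(
    records: Iterable[FrequencyRecord],
    db_size: int,
    min_vertices: int = 3,
) -> list[CliquePattern]:
    """Maximal cliques present in all subjects, with >= min_vertices nodes.

    Maximality is taken within the count == db_size subfamily: a clique in
    every subject is reported only if no strictly larger clique is also in
    every subject.
    """
    universal = [r for r in records if r.count == db_size]
    maximal = maximal_patterns(universal)
    return [r.pattern for r in maximal if r.size >= min_vertices]


def roi_appearance_counts(
    records: Iterable[FrequencyRecord],
    roi_names: Sequence[str],
    atlas: Mapping[int, ROI],
) -> pd.DataFrame:
    """Number of family patterns containing each named ROI.

    Counts are over the family exactly as given (normally the redundant,
    downward-closed family: every sub-clique is a pattern of its own).
    Unknown ROI names raise ``KeyError``.
    """
    index_of = {roi.name: roi.index for roi in atlas.values()}
    unknown = [n for n in roi_names if n not in index_of]
    if unknown:
        raise KeyError(f"unknown ROI name(s): {unknown}")
    recs = list(records)
    rows = []
    for name in roi_names:
        idx = index_of[name]
        n_patterns = sum(1 for r in recs if idx in r.pattern)
        rows.append({"roi": name,
                     "hemisphere": atlas[idx].hemisphere.value,
                     "n_patterns": n_patterns})
    return pd.DataFrame(rows, columns=["roi", "hemisphere", "n_patterns"])


def cross_hemisphere_patterns(
    records: Iterable[FrequencyRecord],
    atlas: Mapping[int, ROI],
    maximal_only: bool = True,
) -> list[CliquePattern]:
    """Cliques with vertices in both hemispheres.

    With ``maximal_only`` (default) only patterns maximal within the
    mixed subfamily are listed, which is how such cliques are usually
    reported.
    """
    mixed = [
        r for r in records if hemisphere_of_pattern(r.pattern, atlas) == "mixed"
    ]
    if maximal_only:
        mixed = maximal_patterns(mixed)
    return [r.pattern for r in sorted(mixed, key=lambda r: (r.size, r.pattern))]


def size_histogram(records: Iterable[FrequencyRecord]) -> dict[int, int]:
    """Clique size -> number of patterns of that size in the family."""
    hist: dict[int, int] = {}
    for r in records:
        hist[r.size] = hist.get(r.size, 0) + 1
    return dict(sorted(hist.items()))


def hemisphere_split(
    records: Iterable[FrequencyRecord], atlas: Mapping[int, ROI]
) -> pd.DataFrame:
    """Per clique size: counts of left-only, right-only, mixed, unknown patterns."""
    rows: dict[int, dict[str, int]] = {}
    for r in records:
        h = hemisphere_of_pattern(r.pattern, atlas)
        row = rows.setdefault(r.size, {"left": 0, "right": 0, "mixed": 0,
                                       "unknown": 0})
        row[h] += 1
    frame = pd.DataFrame(
        [{"k": k, **counts} for k, counts in sorted(rows.items())],
        columns=["k", "left", "right", "mixed", "unknown"],
    )
    return frame


def largest_patterns(
    records: Iterable[FrequencyRecord],
) -> tuple[int, list[CliquePattern]]:
    """The maximum clique size in the family and all patterns of that size."""
    recs = list(records)
    if not recs:
        return 0, []
    kmax = max(r.size for r in recs)
    return kmax, sorted(r.pattern for r in recs if r.size == kmax)


def format_pattern(pattern: Sequence[int], atlas: Mapping[int, ROI]) -> str:
    """Render a clique as parenthesized sorted labels: ``(a)(b)(c)``."""
    return "".join(f"({atlas[v].name})" for v in pattern)


@dataclass
class SummaryTables:
    """The bundle of descriptive tables for one mined family."""

    family: str  # which family was counted, e.g. "redundant (downward-closed)"
    size_histogram: dict[int, int]
    hemisphere_split: pd.DataFrame
    roi_counts: pd.DataFrame
    all_subject_maximal: list[CliquePattern]
    cross_hemisphere: list[CliquePattern]
    largest_size: int
    largest: list[CliquePattern]

    def to_markdown(self, atlas: Mapping[int, ROI]) -> str:
        lines = [f"# Frequent complete subgraph summary",
                 f"", f"Family counted: {self.family}", ""]
        lines += ["## Clique size histogram", ""]
        for k, c in self.size_histogram.items():
            lines.append(f"- size {k}: {c} patterns")
        lines += ["", "## Hemisphere composition by size", "",
                  self.hemisphere_split.to_string(index=False), ""]
        lines += ["## Largest frequent cliques",
                  f"(size {self.largest_size})", ""]
        lines += [f"- {format_pattern(p, atlas)}" for p in self.largest]
        lines += ["", "## Maximal cliques present in every subject", ""]
        lines += [f"- {format_pattern(p, atlas)}"
                  for p in self.all_subject_maximal] or ["- (none)"]
        lines += ["", "## Maximal cross-hemisphere cliques", ""]
        lines += [f"- {format_pattern(p, atlas)}"
                  for p in self.cross_hemisphere] or ["- (none)"]
        if len(self.roi_counts):
            lines += ["", "## ROI appearance counts", "",
                      self.roi_counts.to_string(index=False), ""]
        return "\n".join(lines) + "\n"


def summarize(
    records: Iterable[FrequencyRecord],
    db_size: int,
    atlas: Mapping[int, ROI],
    roi_names: Sequence[str] = (),
    min_all_subject_vertices: int = 3,
) -> SummaryTables:
    """Build all descriptive tables for a mined family in one pass."""
    recs = list(records)
    kmax, largest = largest_patterns(recs)
    return SummaryTables(
        family="redundant (downward-closed)",
        size_histogram=size_histogram(recs),
        hemisphere_split=hemisphere_split(recs, atlas),
        roi_counts=roi_appearance_counts(recs, roi_names, atlas),
        all_subject_maximal=all_subject_maximal(
            recs, db_size, min_vertices=min_all_subject_vertices
        ),
        cross_hemisphere=cross_hemisphere_patterns(recs, atlas),
        largest_size=kmax,
        largest=largest,
    )
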