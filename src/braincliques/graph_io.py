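"""Reading and writing connectome graph databases.

A *braingraph* is one subject's undirected, unweighted graph whose vertices
are atlas-defined gray-matter regions (ROIs) and whose edges mark axonal
fiber connections found by tractography.  A database is a collection of such
graphs over one shared atlas, together with a subject manifest assigning
each subject to a group (e.g. ``female`` / ``male``).

Supported on-disk formats:

* edge list — headerless two-column CSV/TSV of ROI label strings, one edge
  per line;
* GraphML — node ``name`` attribute carries the ROI label;
* manifest — CSV with columns ``subject_id,group``;
* atlas — optional two-column CSV ``index,label`` fixing vertex indices.

Everything is normalized to integer-indexed simple graphs: self-loops and
duplicate edges are dropped (with a warning), edge direction is ignored, and
edge weights in the input are ignored — the analysis uses edge presence only.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "Hemisphere",
    "ROI",
    "BrainGraph",
    "GraphDatabase",
    "classify_hemisphere",
    "load_database",
    "load_edge_list",
    "write_edge_list",
    "write_database",
]


class Hemisphere(str, Enum):
    LEFT = "left"
    RIGHT = "right"
    UNKNOWN = "unknown"


#: label prefixes marking each hemisphere in the Lausanne-style atlases:
#: cortical ROIs use "lh."/"rh.", subcortical ones "Left-"/"Right-".
_LEFT_PREFIXES = ("lh.", "Left-")
_RIGHT_PREFIXES = ("rh.", "Right-")


def classify_hemisphere(name: str) -> Hemisphere:
    """Classify an ROI label by its hemisphere prefix.

    ``lh.`` / ``Left-`` -> left, ``rh.`` / ``Right-`` -> right, anything
    else (e.g. ``Brain-Stem``) -> unknown.
    """
    if name.startswith(_LEFT_PREFIXES):
        return Hemisphere.LEFT
    if name.startswith(_RIGHT_PREFIXES):
        return Hemisphere.RIGHT
    return Hemisphere.UNKNOWN


@dataclass(frozen=True)
class ROI:
    """A named brain region: atlas label, integer index, hemisphere tag."""

    name: str
    index: int

    @property
    def hemisphere(self) -> Hemisphere:
        return classify_hemisphere(self.name)


@dataclass
class BrainGraph:
    """One subject's undirected simple graph over ROI indices.

    Edges are stored as a frozenset of ``(i, j)`` tuples with ``i < j``;
    vertices absent from the subject's file are simply isolated.
    """

    subject_id: str
    n_vertices: int
    edges: frozenset[tuple[int, int]]

    def __post_init__(self) -> None:
        for i, j in self.edges:
            if i >= j:
                raise ValueError(f"edge ({i},{j}) not in canonical i<j order")
            if j >= self.n_vertices:
                raise ValueError(
                    f"edge ({i},{j}) endpoint exceeds atlas size {self.n_vertices}"
                )

    def has_edge(self, i: int, j: int) -> bool:
        if i > j:
            i, j = j, i
        return (i, j) in self.edges

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def adjacency(self) -> dict[int, set[int]]:
        """Adjacency sets over the vertices that carry at least one edge."""
        adj: dict[int, set[int]] = {}
        for i, j in self.edges:
            adj.setdefault(i, set()).add(j)
            adj.setdefault(j, set()).add(i)
        return adj


@dataclass
class GraphDatabase:
    """A subject collection sharing one atlas, with group labels.

    ``atlas`` maps index -> ROI; ``group_of`` maps subject_id -> group
    label.  The group may be a single dummy label when no group comparison
    is requested.
    """

    graphs: list[BrainGraph]
    atlas: dict[int, ROI]
    group_of: dict[str, str]

    def __post_init__(self) -> None:
        ids = [g.subject_id for g in self.graphs]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate subject IDs in database")
        missing = [i for i in ids if i not in self.group_of]
        if missing:
            raise ValueError(f"subjects missing from manifest: {missing[:5]}")

    def __len__(self) -> int:
        return len(self.graphs)

    @property
    def n_vertices(self) -> int:
        return len(self.atlas)

    @property
    def subject_ids(self) -> list[str]:
        return [g.subject_id for g in self.graphs]

    @property
    def groups(self) -> list[str]:
        """Distinct group labels, in sorted order."""
        return sorted({self.group_of[g.subject_id] for g in self.graphs})

    def group_size(self, group: str) -> int:
        return sum(1 for g in self.graphs if self.group_of[g.subject_id] == group)

    def label_of(self, index: int) -> str:
        return self.atlas[index].name

    def index_of(self, name: str) -> int:
        for roi in self.atlas.values():
            if roi.name == name:
                return roi.index
        raise KeyError(f"unknown ROI label: {name!r}")

    def subset(self, subject_ids: Iterable[str]) -> "GraphDatabase":
        """A sub-database restricted to the given subjects (same atlas)."""
        wanted = set(subject_ids)
        graphs = [g for g in self.graphs if g.subject_id in wanted]
        if len(graphs) != len(wanted):
            found = {g.subject_id for g in graphs}
            raise KeyError(f"unknown subject IDs: {sorted(wanted - found)[:5]}")
        return GraphDatabase(
            graphs=graphs,
            atlas=self.atlas,
            group_of={g.subject_id: self.group_of[g.subject_id] for g in graphs},
        )

    def group_subset(self, group: str) -> "GraphDatabase":
        ids = [g.subject_id for g in self.graphs if self.group_of[g.subject_id] == group]
        if not ids:
            raise ValueError(f"no subjects in group {group!r}")
        return self.subset(ids)


# ---------------------------------------------------------------------------
# parsing


def _canonical_edges(
    pairs: Iterable[tuple[str, str]], source: str
) -> list[tuple[str, str]]:
    """Deduplicate label pairs, drop self-loops, orient each pair sorted."""
    seen: set[tuple[str, str]] = set()
    out: list[tuple[str, str]] = []
    n_loops = n_dups = 0
    for a, b in pairs:
        if a == b:
            n_loops += 1
            continue
        key = (a, b) if a < b else (b, a)
        if key in seen:
            n_dups += 1
            continue
        seen.add(key)
        out.append(key)
    if n_loops:
        logger.warning("%s: dropped %d self-loop(s)", source, n_loops)
    if n_dups:
        logger.warning("%s: dropped %d duplicate edge(s)", source, n_dups)
    return out


def _read_label_pairs(path: Path) -> list[tuple[str, str]]:
    """Read raw label pairs from an edge-list CSV/TSV or GraphML file."""
    if path.suffix.lower() == ".graphml":
        g = nx.read_graphml(path)
        name_of = {n: str(d.get("name", n)) for n, d in g.nodes(data=True)}
        return [(name_of[u], name_of[v]) for u, v in g.edges()]
    pairs: list[tuple[str, str]] = []
    with open(path, newline="") as fh:
        sample = fh.read(4096)
        fh.seek(0)
        first_line = sample.splitlines()[0] if sample else ""
        delimiter = "\t" if "\t" in first_line else ","
        for row in csv.reader(fh, delimiter=delimiter):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 2:
                raise ValueError(f"{path}: malformed edge line {row!r}")
            # extra columns (e.g. weights) are ignored
            pairs.append((row[0].strip(), row[1].strip()))
    return pairs


def _load_manifest(path: Path) -> dict[str, str]:
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        rows = [r for r in reader if r and any(c.strip() for c in r)]
    if not rows:
        raise ValueError(f"{path}: empty manifest")
    # tolerate a header line
    if [c.strip().lower() for c in rows[0][:2]] == ["subject_id", "group"]:
        rows = rows[1:]
    manifest: dict[str, str] = {}
    for row in rows:
        if len(row) < 2:
            raise ValueError(f"{path}: malformed manifest line {row!r}")
        manifest[row[0].strip()] = row[1].strip()
    return manifest


def _load_atlas_file(path: Path) -> dict[int, ROI]:
    atlas: dict[int, ROI] = {}
    with open(path, newline="") as fh:
        for row in csv.reader(fh):
            if not row or not any(c.strip() for c in row):
                continue
            if row[0].strip().lower() == "index":
                continue
            idx, name = int(row[0]), row[1].strip()
            if idx in atlas and atlas[idx].name != name:
                raise ValueError(f"{path}: conflicting labels for index {idx}")
            atlas[idx] = ROI(name=name, index=idx)
    names = [r.name for r in atlas.values()]
    if len(set(names)) != len(names):
        raise ValueError(f"{path}: duplicate labels in atlas")
    return atlas


def load_database(
    graph_paths: Sequence[str | Path],
    manifest_path: str | Path,
    atlas_path: str | Path | None = None,
    subject_id_of: "callable | None" = None,
) -> GraphDatabase:
    """Load subject graphs plus manifest into a :class:`GraphDatabase`.

    Parameters
    ----------
    graph_paths
        Edge-list (CSV/TSV) or GraphML files, one per subject.  The subject
        ID defaults to the file stem; pass ``subject_id_of`` to override.
    manifest_path
        CSV mapping every subject ID to a group label.
    atlas_path
        Optional CSV ``index,label`` fixing the vertex indexing.  Without
        it, the atlas is the sorted union of labels across all files,
        indexed 0-based in lexicographic order.
    """
    manifest = _load_manifest(Path(manifest_path))

    per_subject: list[tuple[str, list[tuple[str, str]]]] = []
    for p in graph_paths:
        p = Path(p)
        subject_id = str(subject_id_of(p)) if subject_id_of else p.stem
        try:
            raw = _read_label_pairs(p)
        except OSError as exc:
            raise OSError(f"cannot read graph file {p}: {exc}") from exc
        if subject_id not in manifest:
            raise ValueError(f"subject {subject_id!r} (file {p}) missing from manifest")
        per_subject.append((subject_id, _canonical_edges(raw, str(p))))

    if atlas_path is not None:
        atlas = _load_atlas_file(Path(atlas_path))
        index_of = {roi.name: roi.index for roi in atlas.values()}
    else:
        labels = sorted({lbl for _, edges in per_subject for e in edges for lbl in e})
        atlas = {i: ROI(name=lbl, index=i) for i, lbl in enumerate(labels)}
        index_of = {lbl: i for i, lbl in enumerate(labels)}

    n = len(atlas)
    graphs = []
    for subject_id, edges in per_subject:
        idx_edges = set()
        for a, b in edges:
            try:
                i, j = index_of[a], index_of[b]
            except KeyError as exc:
                raise ValueError(
                    f"subject {subject_id}: label {exc.args[0]!r} not in atlas"
                ) from exc
            idx_edges.add((i, j) if i < j else (j, i))
        graphs.append(BrainGraph(subject_id=subject_id, n_vertices=n,
                                 edges=frozenset(idx_edges)))

    group_of = {sid: manifest[sid] for sid, _ in per_subject}
    return GraphDatabase(graphs=graphs, atlas=atlas, group_of=group_of)


def load_edge_list(path: str | Path, n_vertices: int,
                   index_of: Mapping[str, int], subject_id: str) -> BrainGraph:
    """Load a single edge-list file against a fixed atlas."""
    edges = set()
    for a, b in _canonical_edges(_read_label_pairs(Path(path)), str(path)):
        i, j = index_of[a], index_of[b]
        edges.add((i, j) if i < j else (j, i))
    return BrainGraph(subject_id=subject_id, n_vertices=n_vertices,
                      edges=frozenset(edges))


# ---------------------------------------------------------------------------
# writing


def write_edge_list(graph: BrainGraph, atlas: Mapping[int, ROI],
                    path: str | Path) -> None:
    """Write one graph as a headerless two-column CSV of ROI labels."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        for i, j in sorted(graph.edges):
            writer.writerow([atlas[i].name, atlas[j].name])


def write_database(db: GraphDatabase, out_dir: str | Path) -> list[Path]:
    """Write a database as per-subject edge lists + manifest.csv + atlas.csv.

    Returns the list of per-subject graph file paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for g in db.graphs:
        p = out / f"{g.subject_id}.csv"
        write_edge_list(g, db.atlas, p)
        paths.append(p)
    with open(out / "manifest.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["subject_id", "group"])
        for g in db.graphs:
            writer.writerow([g.subject_id, db.group_of[g.subject_id]])
    with open(out / "atlas.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["index", "label"])
        for i in sorted(db.atlas):
            writer.writerow([i, db.atlas[i].name])
    return paths
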