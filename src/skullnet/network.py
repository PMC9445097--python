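"""Bone-contact network model.

A skull is modeled as an unweighted, undirected graph: nodes are bones (or
fused bone units), edges are physical bone-to-bone contacts.  Unpaired
midline bones are conventionally split sagittally into left and right
halves joined by an edge, so that every skull network is built from paired
elements; :func:`split_midline_bone` implements that convention.

Adjacency matrices arrive as square CSV tables with bone labels as both row
and column headers, entries 0/1.  Side annotation (left/right) is inferred
from label suffixes ``_L``/``_R`` (case-insensitive; trailing `` L``/`` R``
also accepted); labels without a recognized suffix are treated as unsplit
midline elements.
"""

from __future__ import annotations

import io
import re
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "BoneNode",
    "SkullNetwork",
    "read_adjacency",
    "read_trait_table",
    "split_midline_bone",
    "mirror_labels",
    "mirror_label",
    "write_edge_list",
    "write_graphml",
]

SIDE_LEFT = "left"
SIDE_RIGHT = "right"
SIDE_MIDLINE = "midline"  # unsplit midline element
SIDE_SPLIT_LEFT = "midline_split_left"
SIDE_SPLIT_RIGHT = "midline_split_right"

_SUFFIX_RE = re.compile(r"^(?P<base>.*?)[_ ](?P<side>[LR])$", re.IGNORECASE)


@dataclass(frozen=True)
class BoneNode:
    """One bone (or fused unit) in a skull network.

    ``label`` is the unique identifier used in adjacency tables; ``base_name``
    is the bone name without the side suffix; ``side`` is one of ``left``,
    ``right``, ``midline``, ``midline_split_left``, ``midline_split_right``.
    """

    label: str
    base_name: str
    side: str

    @classmethod
    def from_label(cls, label: str) -> "BoneNode":
        """Infer base name and side from a ``_L``/``_R`` style suffix."""
        m = _SUFFIX_RE.match(label)
        if m:
            side = SIDE_LEFT if m.group("side").upper() == "L" else SIDE_RIGHT
            return cls(label=label, base_name=m.group("base"), side=side)
        return cls(label=label, base_name=label, side=SIDE_MIDLINE)


class NetworkValidationError(ValueError):
    """Raised when an adjacency table or network violates its contract."""


@dataclass
class SkullNetwork:
    """A labeled, undirected, unweighted bone-contact graph for one specimen."""

    specimen_id: str
    nodes: list[BoneNode]
    adjacency: np.ndarray
    taxon: str = ""

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency)
        self.validate()

    # -- contract -----------------------------------------------------------
    def validate(self) -> None:
        a = self.adjacency
        n = len(self.nodes)
        labels = [b.label for b in self.nodes]
        if len(set(labels)) != n:
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise NetworkValidationError(f"duplicate bone labels: {dupes}")
        if a.shape != (n, n):
            raise NetworkValidationError(
                f"adjacency shape {a.shape} does not match {n} nodes"
            )
        if not np.isin(a, (0, 1)).all():
            bad = a[~np.isin(a, (0, 1))]
            raise NetworkValidationError(f"non-binary entry: {bad.flat[0]!r}")
        if np.any(np.diag(a) != 0):
            raise NetworkValidationError("nonzero diagonal (self-contact)")
        if not np.array_equal(a, a.T):
            i, j = np.argwhere(a != a.T)[0]
            raise NetworkValidationError(
                f"asymmetric adjacency at ({labels[i]}, {labels[j]})"
            )
        by_side: dict[tuple[str, str], str] = {}
        for b in self.nodes:
            by_side[(b.base_name, b.side)] = b.label
        for b in self.nodes:
            if b.side == SIDE_SPLIT_LEFT and (b.base_name, SIDE_SPLIT_RIGHT) not in by_side:
                raise NetworkValidationError(
                    f"midline-split node {b.label!r} lacks a right partner"
                )
            if b.side == SIDE_SPLIT_RIGHT and (b.base_name, SIDE_SPLIT_LEFT) not in by_side:
                raise NetworkValidationError(
                    f"midline-split node {b.label!r} lacks a left partner"
                )

    # -- views --------------------------------------------------------------
    @property
    def labels(self) -> list[str]:
        return [b.label for b in self.nodes]

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def index_of(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"no bone labeled {label!r}") from None

    def degree(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(int)

    def neighbors(self, label: str) -> set[str]:
        i = self.index_of(label)
        lab = self.labels
        return {lab[j] for j in np.flatnonzero(self.adjacency[i])}

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.labels)
        ii, jj = np.nonzero(np.triu(self.adjacency))
        lab = self.labels
        g.add_edges_from((lab[i], lab[j]) for i, j in zip(ii, jj))
        return g

    def edges(self) -> list[tuple[str, str]]:
        """Each undirected edge once, lexicographically smaller label first."""
        lab = self.labels
        ii, jj = np.nonzero(np.triu(self.adjacency))
        return sorted(tuple(sorted((lab[i], lab[j]))) for i, j in zip(ii, jj))

    def is_connected(self) -> bool:
        return nx.is_connected(self.to_networkx()) if self.n_nodes else True


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_adjacency(source, specimen_id: str, taxon: str = "") -> SkullNetwork:
    """Read a square 0/1 bone-contact matrix (labels on both axes).

    Separator is auto-detected among comma/semicolon/tab.  If only one
    triangle is populated the matrix is mirrored; conflicting asymmetric
    entries are an error.
    """
    df = pd.read_csv(source, sep=None, engine="python", index_col=0, dtype=str)
    df.index = df.index.astype(str).str.strip()
    df.columns = df.columns.astype(str).str.strip()
    if df.shape[0] != df.shape[1]:
        raise NetworkValidationError(
            f"{specimen_id}: non-square table {df.shape[0]}x{df.shape[1]}"
        )
    rows, cols = list(df.index), list(df.columns)
    if rows != cols:
        if sorted(rows) == sorted(cols):
            df = df.loc[:, rows]
        else:
            raise NetworkValidationError(
                f"{specimen_id}: row labels differ from column labels"
            )
    if len(set(rows)) != len(rows):
        raise NetworkValidationError(f"{specimen_id}: duplicated labels")

    raw = df.to_numpy()
    a = np.zeros(raw.shape, dtype=int)
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            cell = raw[i, j]
            if cell is None or (isinstance(cell, float) and np.isnan(cell)):
                continue
            s = str(cell).strip()
            if s in ("", "nan", "NA"):
                continue
            try:
                v = float(s)
            except ValueError:
                raise NetworkValidationError(
                    f"{specimen_id}: non-binary entry {s!r} at ({rows[i]}, {rows[j]})"
                ) from None
            if v not in (0.0, 1.0):
                raise NetworkValidationError(
                    f"{specimen_id}: non-binary entry {s!r} at ({rows[i]}, {rows[j]})"
                )
            a[i, j] = int(v)

    # symmetry completion: a one-triangle matrix is mirrored; populated
    # triangles that disagree are a data-entry fault, not a silent OR
    up, lo = np.triu(a, 1), np.tril(a, -1).T
    if up.any() and lo.any() and not np.array_equal(up, lo):
        i, j = np.argwhere(up != lo)[0]
        raise NetworkValidationError(
            f"{specimen_id}: asymmetric conflicting entries at ({rows[i]}, {rows[j]})"
        )
    sym = ((up + lo) > 0).astype(int)
    a = sym + sym.T
    np.fill_diagonal(a, 0)

    bones = [BoneNode.from_label(l) for l in rows]
    unmatched = [b.label for b in bones if b.side == SIDE_MIDLINE]
    if unmatched:
        warnings.warn(
            f"{specimen_id}: no side suffix on {unmatched}; treating as unsplit "
            "midline elements",
            stacklevel=2,
        )
    return SkullNetwork(specimen_id=specimen_id, nodes=bones, adjacency=a, taxon=taxon)


def read_trait_table(source, vocabulary: Mapping[str, set[str]] | None = None) -> pd.DataFrame:
    """Read the specimen trait table (categorical ecology/morphology columns).

    First column is the specimen id (index).  If ``vocabulary`` maps column
    names to allowed level sets, levels outside the vocabulary are an error.
    """
    df = pd.read_csv(source, sep=None, engine="python", index_col=0, dtype=str)
    df.index = df.index.astype(str).str.strip()
    if df.index.duplicated().any():
        dupes = sorted(df.index[df.index.duplicated()].unique())
        raise NetworkValidationError(f"duplicated specimen ids in trait table: {dupes}")
    df = df.apply(lambda c: c.str.strip())
    if vocabulary:
        for col, allowed in vocabulary.items():
            if col not in df.columns:
                raise NetworkValidationError(f"trait table missing column {col!r}")
            bad = sorted(set(df[col].dropna()) - set(allowed))
            if bad:
                raise NetworkValidationError(
                    f"trait column {col!r} has levels outside vocabulary: {bad}"
                )
    return df


def write_edge_list(net: SkullNetwork, sink) -> None:
    """Write one TSV line per undirected edge, smaller label first.

    Isolated nodes are declared in a leading comment block so that the node
    set round-trips even for edge-free networks.
    """
    own = isinstance(sink, str)
    fh = open(sink, "w") if own else sink
    try:
        fh.write("# skullnet edge list\n")
        fh.write(f"# specimen\t{net.specimen_id}\n")
        fh.write("# nodes\t" + "\t".join(net.labels) + "\n")
        for u, v in net.edges():
            fh.write(f"{u}\t{v}\n")
    finally:
        if own:
            fh.close()


def read_edge_list(source, specimen_id: str | None = None) -> SkullNetwork:
    """Inverse of :func:`write_edge_list`."""
    own = isinstance(source, str)
    fh = open(source) if own else source
    try:
        lines = fh.read().splitlines()
    finally:
        if own:
            fh.close()
    labels: list[str] = []
    sid = specimen_id or ""
    edges = []
    for line in lines:
        if line.startswith("# specimen\t"):
            sid = specimen_id or line.split("\t", 1)[1]
        elif line.startswith("# nodes\t"):
            labels = line.split("\t")[1:]
        elif line.startswith("#") or not line.strip():
            continue
        else:
            u, v = line.split("\t")
            edges.append((u, v))
    if not labels:
        labels = sorted({x for e in edges for x in e})
    idx = {l: i for i, l in enumerate(labels)}
    a = np.zeros((len(labels), len(labels)), dtype=int)
    for u, v in edges:
        a[idx[u], idx[v]] = a[idx[v], idx[u]] = 1
    return SkullNetwork(
        specimen_id=sid, nodes=[BoneNode.from_label(l) for l in labels], adjacency=a
    )


def write_graphml(net: SkullNetwork, sink) -> None:
    """Write GraphML (for Gephi/Cytoscape-style viewers)."""
    g = net.to_networkx()
    for b in net.nodes:
        g.nodes[b.label]["base_name"] = b.base_name
        g.nodes[b.label]["side"] = b.side
    nx.write_graphml(g, sink)


# ---------------------------------------------------------------------------
# midline splitting & mirroring
# ---------------------------------------------------------------------------

def split_midline_bone(
    net: SkullNetwork,
    bone: str,
    left_neighbors: Iterable[str],
    right_neighbors: Iterable[str],
) -> SkullNetwork:
    """Split an unpaired midline bone sagittally into left and right halves.

    The halves (``<bone>_L``, ``<bone>_R``) are joined by an edge; each
    inherits the explicitly assigned neighbor set (a neighbor may appear in
    both sets, in which case it connects to both halves).  The assignment is
    explicit because whether a neighbor spanning the midline touches one
    half or both is an anatomical judgment, not a graph property.
    """
    left_neighbors, right_neighbors = set(left_neighbors), set(right_neighbors)
    candidates = [b for b in net.nodes if b.label == bone or (b.base_name == bone and b.side == SIDE_MIDLINE)]
    if not candidates:
        raise KeyError(f"no midline bone named {bone!r}")
    node = candidates[0]
    current = net.neighbors(node.label)
    if left_neighbors | right_neighbors != current:
        extra = sorted((left_neighbors | right_neighbors) - current)
        missing = sorted(current - (left_neighbors | right_neighbors))
        if extra:
            raise NetworkValidationError(
                f"neighbors {extra} assigned to {bone!r} are not adjacent to it"
            )
        raise NetworkValidationError(
            f"neighbors {missing} of {bone!r} left unassigned to a side"
        )

    base = node.base_name
    keep = [b for b in net.nodes if b.label != node.label]
    new_nodes = keep + [
        BoneNode(f"{base}_L", base, SIDE_SPLIT_LEFT),
        BoneNode(f"{base}_R", base, SIDE_SPLIT_RIGHT),
    ]
    labels = [b.label for b in new_nodes]
    idx = {l: i for i, l in enumerate(labels)}
    n = len(labels)
    a = np.zeros((n, n), dtype=int)
    old_idx = {l: i for i, l in enumerate(net.labels)}
    for u, v in net.edges():
        if node.label in (u, v):
            continue
        a[idx[u], idx[v]] = a[idx[v], idx[u]] = 1
    li, ri = idx[f"{base}_L"], idx[f"{base}_R"]
    a[li, ri] = a[ri, li] = 1
    for nb in left_neighbors:
        a[li, idx[nb]] = a[idx[nb], li] = 1
    for nb in right_neighbors:
        a[ri, idx[nb]] = a[idx[nb], ri] = 1
    return SkullNetwork(
        specimen_id=net.specimen_id, nodes=new_nodes, adjacency=a, taxon=net.taxon
    )


def mirror_label(label: str) -> str:
    """Swap the left/right suffix of a label; midline labels pass through."""
    m = _SUFFIX_RE.match(label)
    if not m:
        return label
    sep = label[len(m.group("base"))]
    side = m.group("side")
    flipped = {"L": "R", "R": "L", "l": "r", "r": "l"}[side]
    return f"{m.group('base')}{sep}{flipped}"


def mirror_labels(net: SkullNetwork) -> SkullNetwork:
    """Relabel the network with all left/right suffixes swapped.

    The bone-contact coding does not distinguish left from right, so a
    well-formed skull network should be unchanged (up to isomorphism) under
    this map; the operation exists to test that symmetry.
    """
    sided = [b for b in net.nodes if b.side not in (SIDE_MIDLINE,)]
    partners = {(b.base_name, b.side) for b in sided}
    opposite = {
        SIDE_LEFT: SIDE_RIGHT,
        SIDE_RIGHT: SIDE_LEFT,
        SIDE_SPLIT_LEFT: SIDE_SPLIT_RIGHT,
        SIDE_SPLIT_RIGHT: SIDE_SPLIT_LEFT,
    }
    for b in sided:
        if (b.base_name, opposite[b.side]) not in partners:
            raise NetworkValidationError(
                f"unpaired side-annotated node {b.label!r} (no {opposite[b.side]} partner)"
            )
    new_nodes = [
        BoneNode(mirror_label(b.label), b.base_name, opposite.get(b.side, b.side))
        for b in net.nodes
    ]
    return SkullNetwork(
        specimen_id=net.specimen_id,
        nodes=new_nodes,
        adjacency=net.adjacency.copy(),
        taxon=net.taxon,
    )
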