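"""Hydrogen-suppressed molecular graphs and their edge partitions.

A molecule is modelled as a simple undirected graph on its heavy (non-hydrogen)
atoms; every covalent connection is one edge regardless of bond order, so the
degree of a vertex is the number of heavy-atom neighbours of that atom.  All
of the topological indices in :mod:`phytorank.indices` depend on the molecule
only through the *edge partition*: the multiset of unordered endpoint-degree
pairs ``(i, j)`` over all edges, with multiplicities.
"""

from __future__ import annotations

import io
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

import networkx as nx

__all__ = [
    "GraphValidationError",
    "MolecularGraph",
    "EdgePartition",
    "read_edge_list",
    "write_edge_list",
    "from_smiles",
    "edge_partition",
]


class GraphValidationError(ValueError):
    """Raised when input does not describe a valid hydrogen-suppressed graph."""


@dataclass(frozen=True)
class MolecularGraph:
    """A simple, loop-free graph on opaque vertex labels.

    Parameters
    ----------
    vertex_ids
        Vertex labels in a fixed (first-appearance) order.
    edges
        Unordered pairs of vertex labels.  Self-loops and duplicate edges are
        rejected; every vertex must carry at least one edge.
    element_labels
        Optional per-vertex atomic symbols.  Annotation only — no index
        depends on them.
    """

    vertex_ids: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]
    element_labels: Mapping[str, str] | None = None
    name: str = ""

    def __post_init__(self) -> None:
        seen: set[frozenset[str]] = set()
        vset = set(self.vertex_ids)
        if len(vset) != len(self.vertex_ids):
            raise GraphValidationError("duplicate vertex identifiers")
        for u, v in self.edges:
            if u == v:
                raise GraphValidationError(f"self-loop on vertex {u!r}")
            key = frozenset((u, v))
            if key in seen:
                raise GraphValidationError(f"duplicate edge {u!r}-{v!r}")
            seen.add(key)
            for w in (u, v):
                if w not in vset:
                    raise GraphValidationError(
                        f"edge endpoint {w!r} not in vertex set"
                    )
        if not self.edges:
            raise GraphValidationError("graph has no edges")
        touched = {w for e in self.edges for w in e}
        isolated = vset - touched
        if isolated:
            raise GraphValidationError(
                f"isolated vertices (degree 0): {sorted(isolated)}"
            )
        if not nx.is_connected(self.to_networkx()):
            warnings.warn(
                f"graph {self.name or '<unnamed>'} is disconnected; indices "
                "are still well-defined as sums over edges",
                stacklevel=2,
            )

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str]],
        element_labels: Mapping[str, str] | None = None,
        name: str = "",
    ) -> "MolecularGraph":
        """Build a graph from edges, vertices in first-appearance order."""
        edges = tuple((str(u), str(v)) for u, v in edges)
        order: dict[str, None] = {}
        for u, v in edges:
            order.setdefault(u)
            order.setdefault(v)
        return cls(tuple(order), edges, element_labels, name)

    @property
    def n_vertices(self) -> int:
        return len(self.vertex_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degrees(self) -> dict[str, int]:
        """Map vertex id -> degree (number of incident edges)."""
        deg = Counter()
        for u, v in self.edges:
            deg[u] += 1
            deg[v] += 1
        return {v: deg[v] for v in self.vertex_ids}

    def degree_sequence(self) -> tuple[int, ...]:
        """Degrees in vertex order."""
        deg = self.degrees()
        return tuple(deg[v] for v in self.vertex_ids)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.vertex_ids)
        g.add_edges_from(self.edges)
        return g

    def relabel(self, mapping: Mapping[str, str]) -> "MolecularGraph":
        """Return an isomorphic copy with vertices renamed through *mapping*."""
        return MolecularGraph(
            tuple(mapping[v] for v in self.vertex_ids),
            tuple((mapping[u], mapping[v]) for u, v in self.edges),
            (
                {mapping[v]: s for v, s in self.element_labels.items()}
                if self.element_labels
                else None
            ),
            self.name,
        )


@dataclass(frozen=True)
class EdgePartition:
    """Multiset of sorted endpoint-degree pairs with multiplicities.

    ``classes[(i, j)]`` with ``i <= j`` counts the edges whose endpoints have
    degrees ``i`` and ``j``.  The counts sum to the number of edges of the
    source graph.
    """

    classes: Mapping[tuple[int, int], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (i, j), c in self.classes.items():
            if i > j or i < 1:
                raise ValueError(f"malformed degree class ({i}, {j})")
            if c < 0:
                raise ValueError(f"negative count for class ({i}, {j})")

    @property
    def n_edges(self) -> int:
        return sum(self.classes.values())

    def sorted_items(self) -> list[tuple[tuple[int, int], int]]:
        """Classes in deterministic (i, j) order, for reproducible sums."""
        return sorted(self.classes.items())


def edge_partition(g: MolecularGraph) -> EdgePartition:
    """Partition the edges of *g* by sorted endpoint-degree pair."""
    deg = g.degrees()
    counts: Counter[tuple[int, int]] = Counter()
    for u, v in g.edges:
        i, j = sorted((deg[u], deg[v]))
        counts[(i, j)] += 1
    return EdgePartition(dict(counts))


_DIALECT_SEPS = {"csv": ",", "tsv": "\t", "whitespace": None}


def read_edge_list(
    source: str | Path | IO[str],
    dialect: str = "whitespace",
    name: str = "",
) -> MolecularGraph:
    """Read a molecular graph from an edge-list text stream or file.

    Each non-comment, non-blank line names the two endpoint labels of one
    edge, separated per *dialect* (``whitespace``, ``csv`` or ``tsv``).
    Lines starting with ``#`` are comments.  Duplicate edges and self-loops
    are rejected with the offending line number — they indicate data errors
    rather than multigraph intent.
    """
    if dialect not in _DIALECT_SEPS:
        raise ValueError(f"unknown dialect {dialect!r}")
    sep = _DIALECT_SEPS[dialect]
    if isinstance(source, (str, Path)):
        path = Path(source)
        stream: IO[str] = io.StringIO(path.read_text())
        name = name or path.stem
    else:
        stream = source

    edges: list[tuple[str, str]] = []
    seen: set[frozenset[str]] = set()
    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = [p.strip() for p in line.split(sep)]
        parts = [p for p in parts if p]
        if len(parts) != 2:
            raise GraphValidationError(
                f"line {lineno}: expected two vertex labels, got {len(parts)}"
            )
        u, v = parts
        if u == v:
            raise GraphValidationError(f"line {lineno}: self-loop on {u!r}")
        key = frozenset((u, v))
        if key in seen:
            raise GraphValidationError(f"line {lineno}: duplicate edge {u!r}-{v!r}")
        seen.add(key)
        edges.append((u, v))
    if not edges:
        raise GraphValidationError("empty edge list")
    return MolecularGraph.from_edges(edges, name=name)


def write_edge_list(
    g: MolecularGraph, target: str | Path | IO[str], header: str = ""
) -> None:
    """Write *g* as whitespace-separated edge-list text."""
    lines = []
    if header:
        lines.extend(f"# {h}" for h in header.splitlines())
    lines.extend(f"{u} {v}" for u, v in g.edges)
    text = "\n".join(lines) + "\n"
    if isinstance(target, (str, Path)):
        Path(target).write_text(text)
    else:
        target.write(text)


def from_smiles(smiles: str, name: str = "") -> MolecularGraph:
    """Heavy-atom skeleton of a SMILES string (requires RDKit).

    Hydrogens are suppressed and bond orders ignored: a double bond
    contributes a single edge, so vertex degree counts heavy-atom neighbours
    only.  The adapter is optional — the rest of the package never needs it.
    """
    try:
        from rdkit import Chem
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise ImportError(
            "the SMILES adapter requires rdkit (pip install phytorank[smiles])"
        ) from exc

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise GraphValidationError(f"unparsable SMILES: {smiles!r}")
    heavy = [a for a in mol.GetAtoms() if a.GetAtomicNum() > 1]
    ids = {a.GetIdx(): f"{a.GetSymbol()}{a.GetIdx() + 1}" for a in heavy}
    labels = {ids[a.GetIdx()]: a.GetSymbol() for a in heavy}
    edges = [
        (ids[b.GetBeginAtomIdx()], ids[b.GetEndAtomIdx()])
        for b in mol.GetBonds()
        if b.GetBeginAtomIdx() in ids and b.GetEndAtomIdx() in ids
    ]
    if not edges:
        raise GraphValidationError(
            f"SMILES {smiles!r} yields no heavy-atom edges"
        )
    return MolecularGraph.from_edges(edges, element_labels=labels, name=name)
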