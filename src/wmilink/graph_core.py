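"""Weighted-graph data model and edge-list I/O.

The central object is :class:`WeightedGraph`: a simple undirected graph
G(V, E, W) whose links carry strictly positive real weights.  Weights are
symmetric by construction (keyed on unordered pairs), self-loops and
multi-edges are rejected at the boundary.  Strict positivity matters because
the weak-tie exponent raises weights to arbitrary real powers: ``0**alpha``
is undefined or infinite for ``alpha <= 0``.

Two plain-text dialects are supported: whitespace-separated weighted edge
lists (``node node weight`` per line, ``#`` comments) and Pajek ``.net``
files (``*Vertices`` block followed by ``*Edges`` triples).
"""

from __future__ import annotations

import math
from typing import Hashable, Iterable, Iterator

import networkx as nx

Node = Hashable

__all__ = [
    "WeightedGraph",
    "GraphError",
    "canonical_pair",
    "load_edge_list",
    "write_edge_list",
    "neighbors",
    "common_neighbors",
    "node_strength",
]


class GraphError(ValueError):
    """Raised on invariant violations (self-loop, non-positive weight, ...)."""


def canonical_pair(x: Node, y: Node) -> tuple[Node, Node]:
    """Return the unordered pair (x, y) as a canonical tuple.

    Node identifiers are opaque; heterogeneous or unorderable identifiers
    fall back to a (type-name, repr) sort key so the canonical form is
    deterministic for any hashable pair.
    """
    if x == y:
        raise GraphError(f"self-pair ({x!r}, {x!r}) is not a valid node pair")
    try:
        return (x, y) if x <= y else (y, x)  # type: ignore[operator]
    except TypeError:
        key = ((type(x).__name__, repr(x)), (type(y).__name__, repr(y)))
        return (x, y) if key[0] <= key[1] else (y, x)


def _sort_key(node: Node):
    return (type(node).__name__, repr(node))


class WeightedGraph:
    """Undirected simple graph with strictly positive symmetric link weights.

    Invariants enforced on every mutation:

    * no self-loops, no duplicate edges;
    * every weight is a finite real > 0;
    * weights are symmetric: ``weight(x, y) == weight(y, x)`` by keying on
      the unordered pair.

    The number of possible node pairs ``M = |V|(|V|-1)/2`` is available as
    :attr:`m_possible` and depends on the node set alone.
    """

    def __init__(self, edges: Iterable[tuple[Node, Node, float]] = (),
                 nodes: Iterable[Node] = ()):
        self._g = nx.Graph()
        for n in nodes:
            self.add_node(n)
        for x, y, w in edges:
            self.add_edge(x, y, w)

    # -- mutation -----------------------------------------------------------

    def add_node(self, n: Node) -> None:
        self._g.add_node(n)

    def add_edge(self, x: Node, y: Node, w: float) -> None:
        if x == y:
            raise GraphError(f"self-loop on node {x!r} is not allowed")
        w = float(w)
        if not math.isfinite(w) or w <= 0:
            raise GraphError(
                f"weight of edge ({x!r}, {y!r}) must be a finite positive "
                f"real, got {w!r}")
        if self._g.has_edge(x, y):
            raise GraphError(f"duplicate edge ({x!r}, {y!r})")
        self._g.add_edge(x, y, weight=w)

    def remove_edge(self, x: Node, y: Node) -> None:
        self._g.remove_edge(x, y)

    # -- queries ------------------------------------------------------------

    @property
    def nodes(self) -> set[Node]:
        return set(self._g.nodes)

    def sorted_nodes(self) -> list[Node]:
        """Nodes in a deterministic (type-name, repr) order."""
        return sorted(self._g.nodes, key=_sort_key)

    @property
    def number_of_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def number_of_edges(self) -> int:
        return self._g.number_of_edges()

    @property
    def m_possible(self) -> int:
        """M = |V| (|V| - 1) / 2, the number of possible node pairs."""
        n = self._g.number_of_nodes()
        return n * (n - 1) // 2

    def has_node(self, n: Node) -> bool:
        return self._g.has_node(n)

    def has_edge(self, x: Node, y: Node) -> bool:
        return self._g.has_edge(x, y)

    def weight(self, x: Node, y: Node) -> float:
        try:
            return self._g.edges[x, y]["weight"]
        except KeyError:
            raise KeyError(f"no edge ({x!r}, {y!r})") from None

    def edges(self) -> Iterator[tuple[Node, Node, float]]:
        for x, y, data in self._g.edges(data=True):
            yield x, y, data["weight"]

    def edge_pairs(self) -> set[tuple[Node, Node]]:
        """All edges as canonical unordered pairs."""
        return {canonical_pair(x, y) for x, y in self._g.edges}

    def degree(self, n: Node) -> int:
        if not self._g.has_node(n):
            raise KeyError(f"unknown node {n!r}")
        return self._g.degree[n]

    def neighbors(self, x: Node) -> set[Node]:
        if not self._g.has_node(x):
            raise KeyError(f"unknown node {x!r}")
        return set(self._g.neighbors(x))

    def copy(self) -> "WeightedGraph":
        out = WeightedGraph()
        out._g = self._g.copy()
        return out

    def subgraph_with_edges(
            self, keep: Iterable[tuple[Node, Node]]) -> "WeightedGraph":
        """Graph on the full node set containing only the ``keep`` edges."""
        out = WeightedGraph(nodes=self._g.nodes)
        for x, y in keep:
            out.add_edge(x, y, self.weight(x, y))
        return out

    def to_networkx(self) -> nx.Graph:
        return self._g.copy()

    def adjacency_arrays(self):
        """Dense weight matrix in deterministic node order.

        Returns ``(nodes, index, W)`` where ``nodes`` is the sorted node
        list, ``index`` maps node -> row and ``W`` is the symmetric dense
        weight matrix with 0 for absent edges.
        """
        import numpy as np

        nodes = self.sorted_nodes()
        index = {n: i for i, n in enumerate(nodes)}
        W = np.zeros((len(nodes), len(nodes)))
        for x, y, w in self.edges():
            i, j = index[x], index[y]
            W[i, j] = W[j, i] = w
        return nodes, index, W

    # -- equality (round-trip testing) --------------------------------------

    def __eq__(self, other) -> bool:
        if not isinstance(other, WeightedGraph):
            return NotImplemented
        if self.nodes != other.nodes:
            return False
        if self.edge_pairs() != other.edge_pairs():
            return False
        return all(self.weight(x, y) == other.weight(x, y)
                   for x, y in self.edge_pairs())

    def __repr__(self) -> str:
        return (f"WeightedGraph(|V|={self.number_of_nodes}, "
                f"|E|={self.number_of_edges})")


# -- spec-level operations ---------------------------------------------------

def neighbors(g: WeightedGraph, x: Node) -> set[Node]:
    """Γ(x): the set of neighbors of ``x``; never contains ``x`` itself."""
    return g.neighbors(x)


def common_neighbors(g: WeightedGraph, pair: tuple[Node, Node]) -> set[Node]:
    """O_xy = Γ(x) ∩ Γ(y), the common-neighbor set of a node pair."""
    x, y = pair
    return g.neighbors(x) & g.neighbors(y)


def node_strength(g: WeightedGraph, z: Node, alpha: float = 1.0) -> float:
    """α-powered node strength S_z = Σ_{z'∈Γ(z)} W_zz'^α.

    ``alpha=1`` gives the plain strength (sum of incident weights);
    ``alpha=0`` gives the degree.  Isolated nodes have strength 0.
    """
    return sum(g.weight(z, nb) ** alpha for nb in g.neighbors(z))


# -- I/O ---------------------------------------------------------------------

_DIALECTS = ("tsv-edgelist", "pajek-net")


def _check_dialect(dialect: str) -> None:
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of "
                         f"{_DIALECTS}")


def _add_parsed_edge(g: WeightedGraph, x: Node, y: Node, w: float,
                     duplicate_policy: str, lineno: int) -> None:
    if x == y:
        raise GraphError(f"line {lineno}: self-loop on node {x!r}")
    if not math.isfinite(w) or w <= 0:
        raise GraphError(f"line {lineno}: weight must be positive, got {w}")
    if g.has_edge(x, y):
        if duplicate_policy == "sum":
            total = g.weight(x, y) + w
            g.remove_edge(x, y)
            g.add_edge(x, y, total)
            return
        raise GraphError(f"line {lineno}: duplicate edge ({x!r}, {y!r})")
    g.add_edge(x, y, w)


def load_edge_list(path, dialect: str = "tsv-edgelist",
                   duplicate_policy: str = "error") -> WeightedGraph:
    """Read a weighted graph from a plain-text file.

    Parameters
    ----------
    path : str or path-like
    dialect : {"tsv-edgelist", "pajek-net"}
        ``tsv-edgelist``: one ``node node weight`` triple per
        whitespace-separated line, ``#`` comments and blank lines allowed.
        ``pajek-net``: ``*Vertices n`` block (optional quoted labels,
        1-indexed) followed by a ``*Edges`` block of ``i j w`` triples.
    duplicate_policy : {"error", "sum"}
        ``error`` rejects repeated (x,y)/(y,x) records; ``sum`` aggregates
        their weights (raw multigraph exports).
    """
    _check_dialect(dialect)
    if duplicate_policy not in ("error", "sum"):
        raise ValueError(f"unknown duplicate_policy {duplicate_policy!r}")
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.readlines()
    if dialect == "tsv-edgelist":
        return _parse_edgelist(lines, duplicate_policy)
    return _parse_pajek(lines, duplicate_policy)


def _parse_edgelist(lines: list[str], duplicate_policy: str) -> WeightedGraph:
    g = WeightedGraph()
    for lineno, raw in enumerate(lines, start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) == 1:
            # bare node line: isolated node
            g.add_node(parts[0])
            continue
        if len(parts) != 3:
            raise GraphError(
                f"line {lineno}: expected 'node node weight', got {raw!r}")
        x, y, wtxt = parts
        try:
            w = float(wtxt)
        except ValueError:
            raise GraphError(
                f"line {lineno}: weight {wtxt!r} is not a number") from None
        _add_parsed_edge(g, x, y, w, duplicate_policy, lineno)
    return g


def _parse_pajek(lines: list[str], duplicate_policy: str) -> WeightedGraph:
    g = WeightedGraph()
    labels: dict[str, str] = {}
    section = None
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("%"):
            continue
        low = line.lower()
        if low.startswith("*vertices"):
            section = "vertices"
            continue
        if low.startswith("*edges") or low.startswith("*arcs"):
            section = "edges"
            continue
        if line.startswith("*"):
            raise GraphError(f"line {lineno}: unknown Pajek section {line!r}")
        if section == "vertices":
            parts = line.split(None, 1)
            idx = parts[0]
            label = idx
            if len(parts) > 1:
                label = parts[1].strip().strip('"')
            labels[idx] = label
            g.add_node(label)
        elif section == "edges":
            parts = line.split()
            if len(parts) < 3:
                raise GraphError(
                    f"line {lineno}: expected 'i j w' in *Edges block")
            i, j, wtxt = parts[0], parts[1], parts[2]
            try:
                w = float(wtxt)
            except ValueError:
                raise GraphError(
                    f"line {lineno}: weight {wtxt!r} is not a number"
                ) from None
            x = labels.get(i, i)
            y = labels.get(j, j)
            _add_parsed_edge(g, x, y, w, duplicate_policy, lineno)
        else:
            raise GraphError(
                f"line {lineno}: data before any *Vertices/*Edges section")
    return g


def write_edge_list(g: WeightedGraph, path,
                    dialect: str = "tsv-edgelist") -> None:
    """Write a graph so that ``load_edge_list(write_edge_list(g))`` round-trips.

    Weights are serialized with ``repr`` (full float precision).  Isolated
    nodes are preserved: as bare node lines in the edge-list dialect, and
    via the ``*Vertices`` block in Pajek.
    """
    _check_dialect(dialect)
    nodes = g.sorted_nodes()
    with open(path, "w", encoding="utf-8") as fh:
        if dialect == "tsv-edgelist":
            covered: set = set()
            for x, y in sorted((canonical_pair(a, b)
                                for a, b in g.edge_pairs()), key=str):
                fh.write(f"{x}\t{y}\t{g.weight(x, y)!r}\n")
                covered.add(x)
                covered.add(y)
            for n in nodes:
                if n not in covered:
                    fh.write(f"{n}\n")
        else:
            index = {n: i + 1 for i, n in enumerate(nodes)}
            fh.write(f"*Vertices {len(nodes)}\n")
            for n in nodes:
                fh.write(f'{index[n]} "{n}"\n')
            fh.write("*Edges\n")
            for x, y in sorted((canonical_pair(a, b)
                                for a, b in g.edge_pairs()), key=str):
                fh.write(f"{index[x]} {index[y]} {g.weight(x, y)!r}\n")
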