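"""Signed directed graphs and the reachability machinery built on them.

A gene regulatory network (GRN) is modelled as a signed digraph: genes are
nodes and a directed edge (i, j) with sign +1 (activation) or -1
(repression) states that the product of gene i regulates the transcription
of gene j.  This module provides the :class:`SignedDigraph` container, the
matrix views used by the inference algorithms (adjacency, accessibility),
strongly-connected-component condensation, transitive reduction of DAGs,
indirect-path queries, and TSV serialization in two dialects (DREAM
gold-standard edge lists and a signed extension).

Self-loops are never represented: knocking out gene i trivially silences
gene i, so self-regulation carries no information in KO data.  Cycle
membership (a node reaching itself through a cycle) is tracked on the
diagonal of the accessibility matrix instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import networkx as nx
import numpy as np

__all__ = [
    "SignedDigraph",
    "AdjacencyView",
    "AccessibilityView",
    "neighbors",
    "transitive_closure",
    "signed_closure",
    "condense",
    "transitive_reduction_dag",
    "has_indirect_path",
    "read_network",
    "write_network",
    "NetworkParseError",
]

Edge = tuple[str, str]
SignedEdge = tuple[str, str, int]


class NetworkParseError(ValueError):
    """Raised when a network file does not parse under the chosen dialect."""


class SignedDigraph:
    """A directed graph with one signed edge per ordered node pair.

    Parameters
    ----------
    nodes:
        Iterable of node identifiers.  Unless an explicit ordering is
        supplied the canonical node order used by matrix views is
        lexicographic, which keeps every matrix deterministic across runs.
    edges:
        Iterable of ``(source, target, sign)`` triples, sign in ``{+1, -1}``.
    weights:
        Optional mapping ``(source, target) -> weight`` with weights in
        ``[0, 1]``.
    ordered:
        If True, ``nodes`` is taken as the canonical order verbatim.
    """

    def __init__(
        self,
        nodes: Iterable[str] = (),
        edges: Iterable[SignedEdge] = (),
        weights: Mapping[Edge, float] | None = None,
        *,
        ordered: bool = False,
    ) -> None:
        node_list = list(dict.fromkeys(nodes))
        self._nodes: tuple[str, ...] = tuple(node_list if ordered else sorted(node_list))
        self._index = {v: k for k, v in enumerate(self._nodes)}
        self._edges: dict[Edge, int] = {}
        self._weights: dict[Edge, float] = {}
        for u, v, s in edges:
            self.add_edge(u, v, s)
        if weights:
            for (u, v), w in weights.items():
                self.set_weight(u, v, w)

    # -- basic container protocol -------------------------------------------------

    @property
    def nodes(self) -> tuple[str, ...]:
        return self._nodes

    @property
    def edges(self) -> set[SignedEdge]:
        """The signed edge set as ``(source, target, sign)`` triples."""
        return {(u, v, s) for (u, v), s in self._edges.items()}

    @property
    def edge_pairs(self) -> set[Edge]:
        """The unsigned edge set as ordered ``(source, target)`` pairs."""
        return set(self._edges)

    @property
    def n(self) -> int:
        """Order of the graph (number of nodes)."""
        return len(self._nodes)

    @property
    def m(self) -> int:
        """Size of the graph (number of edges)."""
        return len(self._edges)

    def __contains__(self, pair: Edge) -> bool:
        return tuple(pair) in self._edges

    def __iter__(self) -> Iterator[Edge]:
        return iter(self._edges)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SignedDigraph):
            return NotImplemented
        return set(self._nodes) == set(other._nodes) and self._edges == other._edges

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"SignedDigraph(n={self.n}, m={self.m})"

    # -- mutation -----------------------------------------------------------------

    def _check_node(self, node: str) -> None:
        if node not in self._index:
            raise KeyError(f"unknown node {node!r}")

    def add_node(self, node: str) -> None:
        if node not in self._index:
            nodes = sorted(self._nodes + (node,))
            self._nodes = tuple(nodes)
            self._index = {v: k for k, v in enumerate(self._nodes)}

    def add_edge(self, u: str, v: str, sign: int, weight: float | None = None) -> None:
        if u == v:
            raise ValueError(f"self-loop ({u!r}, {v!r}) is not allowed")
        if sign not in (1, -1):
            raise ValueError(f"sign must be +1 or -1, got {sign!r}")
        self.add_node(u)
        self.add_node(v)
        self._edges[(u, v)] = int(sign)
        if weight is not None:
            self.set_weight(u, v, weight)

    def remove_edge(self, u: str, v: str) -> None:
        del self._edges[(u, v)]
        self._weights.pop((u, v), None)

    def set_sign(self, u: str, v: str, sign: int) -> None:
        if (u, v) not in self._edges:
            raise KeyError(f"edge ({u!r}, {v!r}) not present")
        if sign not in (1, -1):
            raise ValueError(f"sign must be +1 or -1, got {sign!r}")
        self._edges[(u, v)] = int(sign)

    def set_weight(self, u: str, v: str, weight: float) -> None:
        if (u, v) not in self._edges:
            raise KeyError(f"edge ({u!r}, {v!r}) not present")
        if not 0.0 <= weight <= 1.0:
            raise ValueError(f"weight must lie in [0, 1], got {weight!r}")
        self._weights[(u, v)] = float(weight)

    # -- lookup -------------------------------------------------------------------

    def sign(self, u: str, v: str) -> int:
        return self._edges[(u, v)]

    def weight(self, u: str, v: str, default: float | None = None) -> float | None:
        return self._weights.get((u, v), default)

    @property
    def weights(self) -> dict[Edge, float]:
        return dict(self._weights)

    def parents(self, node: str) -> set[str]:
        self._check_node(node)
        return {u for (u, v) in self._edges if v == node}

    def children(self, node: str) -> set[str]:
        self._check_node(node)
        return {v for (u, v) in self._edges if u == node}

    def ancestors(self, node: str) -> set[str]:
        """Nodes with a directed path of length >= 1 to ``node``."""
        self._check_node(node)
        g = self.to_networkx()
        anc = nx.ancestors(g, node)
        # a node is its own ancestor iff it lies on a directed cycle
        if any(nx.has_path(g, c, node) for c in self.children(node)):
            anc.add(node)
        return anc

    def descendants(self, node: str) -> set[str]:
        """Nodes reachable from ``node`` by a directed path of length >= 1."""
        self._check_node(node)
        g = self.to_networkx()
        desc = nx.descendants(g, node)
        if any(nx.has_path(g, node, p) for p in self.parents(node)):
            desc.add(node)
        return desc

    # -- conversions --------------------------------------------------------------

    def copy(self) -> "SignedDigraph":
        g = SignedDigraph(self._nodes, ordered=True)
        g._edges = dict(self._edges)
        g._weights = dict(self._weights)
        return g

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self._nodes)
        for (u, v), s in self._edges.items():
            g.add_edge(u, v, sign=s, weight=self._weights.get((u, v)))
        return g

    def adjacency(self) -> "AdjacencyView":
        n = self.n
        adj = np.zeros((n, n), dtype=int)
        sgn = np.zeros((n, n), dtype=int)
        for (u, v), s in self._edges.items():
            i, j = self._index[u], self._index[v]
            adj[i, j] = 1
            sgn[i, j] = s
        return AdjacencyView(nodes=self._nodes, matrix=adj, signs=sgn)

    def index(self, node: str) -> int:
        return self._index[node]


@dataclass(frozen=True)
class AdjacencyView:
    """Adjacency matrix over a fixed node ordering, with a sign companion."""

    nodes: tuple[str, ...]
    matrix: np.ndarray
    signs: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diag(self.matrix)):
            raise ValueError("adjacency diagonal must be zero (no self-loops)")
        if not np.array_equal(self.signs != 0, self.matrix != 0):
            raise ValueError("sign entries must coincide with adjacency entries")


@dataclass(frozen=True)
class AccessibilityView:
    """Boolean reachability matrix: entry (u, v) = 1 iff a path u -> v exists.

    The diagonal entry is 1 only for nodes lying on a directed cycle; it is
    never materialized as a graph edge.
    """

    nodes: tuple[str, ...]
    matrix: np.ndarray
    signs: np.ndarray | None = field(default=None)

    def reaches(self, u: str, v: str) -> bool:
        i = self.nodes.index(u)
        j = self.nodes.index(v)
        return bool(self.matrix[i, j])


# ---------------------------------------------------------------------------
# Reachability and reduction algorithms
# ---------------------------------------------------------------------------


def neighbors(g: SignedDigraph, node: str, relation: str) -> set[str]:
    """One-step or transitive neighbourhoods of ``node``.

    ``relation`` is one of ``parents``, ``children`` (one step) or
    ``ancestors``, ``descendants`` (transitive).  A node is its own
    ancestor/descendant iff it lies on a directed cycle through itself.
    """
    if relation == "parents":
        return g.parents(node)
    if relation == "children":
        return g.children(node)
    if relation == "ancestors":
        return g.ancestors(node)
    if relation == "descendants":
        return g.descendants(node)
    raise ValueError(f"unknown relation {relation!r}")


def transitive_closure(g: SignedDigraph) -> AccessibilityView:
    """Accessibility matrix: (u, v) = 1 iff a path of length >= 1 exists."""
    gx = g.to_networkx()
    closure = nx.transitive_closure(gx, reflexive=False)
    n = g.n
    acc = np.zeros((n, n), dtype=int)
    for u, v in closure.edges():
        acc[g.index(u), g.index(v)] = 1
    return AccessibilityView(nodes=g.nodes, matrix=acc)


def signed_closure(g: SignedDigraph) -> SignedDigraph:
    """Signed transitive closure: edge (u, v) for every reachable ordered pair
    (u != v), signed by the cumulative sign product along directed paths.

    Raises ``ValueError`` when two paths between the same pair carry
    different cumulative signs (e.g. through a negative cycle): the net
    steady-state effect is then ambiguous and no single-signed closure
    exists.  Used to build ideal (noise-free) upper bounds in tests and in
    the bundled worked example.
    """
    # fixed-point propagation of the attainable sign set per ordered pair
    signs: dict[Edge, set[int]] = {(u, v): {s} for (u, v, s) in g.edges}
    changed = True
    while changed:
        changed = False
        for (u, k), s1 in list(signs.items()):
            for (k2, v), s2 in list(signs.items()):
                if k != k2 or u == v:
                    continue
                prod = {a * b for a in s1 for b in s2}
                cur = signs.setdefault((u, v), set())
                if not prod <= cur:
                    cur |= prod
                    changed = True
    out = SignedDigraph(g.nodes, ordered=True)
    for (u, v), ss in signs.items():
        if len(ss) > 1:
            raise ValueError(f"ambiguous cumulative sign for pair ({u!r}, {v!r})")
        out.add_edge(u, v, next(iter(ss)))
    return out


def condense(g: SignedDigraph) -> tuple[nx.DiGraph, dict[str, int]]:
    """Condense strongly connected components into a DAG.

    Returns the quotient DAG (networkx DiGraph whose nodes are component
    ids, each carrying its ``members`` set) and the node -> component map.
    Inter-component edges are deduplicated.
    """
    gx = g.to_networkx()
    dag = nx.condensation(gx)
    mapping = dict(dag.graph["mapping"])
    return dag, mapping


def transitive_reduction_dag(g: SignedDigraph | nx.DiGraph) -> set[Edge]:
    """Unique minimum edge set of a DAG preserving its transitive closure."""
    gx = g.to_networkx() if isinstance(g, SignedDigraph) else g
    if not nx.is_directed_acyclic_graph(gx):
        raise ValueError("transitive reduction requires an acyclic input")
    return set(nx.transitive_reduction(gx).edges())


def has_indirect_path(
    g: SignedDigraph, i: str, j: str, excluded: Iterable[str] = ()
) -> bool:
    """True iff a directed path i -> ... -> j of length >= 2 exists that
    avoids every node in ``excluded``.  The direct edge (i, j) is ignored;
    i and j themselves may not be excluded."""
    if i == j:
        raise ValueError("endpoints must differ")
    excluded = set(excluded)
    if i in excluded or j in excluded:
        raise ValueError("endpoints cannot be excluded")
    gx = g.to_networkx()
    gx.remove_nodes_from(excluded & set(gx.nodes))
    if gx.has_edge(i, j):
        gx.remove_edge(i, j)
    if i not in gx or j not in gx:
        return False
    return nx.has_path(gx, i, j)


# ---------------------------------------------------------------------------
# Network TSV I/O
# ---------------------------------------------------------------------------

_DIALECTS = ("dream", "signed")


def read_network(path, dialect: str = "signed") -> SignedDigraph:
    """Read a network edge list.

    ``signed`` dialect rows: ``source<TAB>target<TAB>sign(+1|-1)[<TAB>weight]``.
    ``dream`` dialect rows: ``source<TAB>target<TAB>{0,1}``; 0 rows denote
    absent edges and are dropped; present edges get sign +1.  Lines starting
    with ``#`` are comments.
    """
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    g = SignedDigraph()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise NetworkParseError(f"{path}:{lineno}: expected >= 3 columns")
            u, v = parts[0], parts[1]
            try:
                if dialect == "dream":
                    flag = int(parts[2])
                    if flag not in (0, 1):
                        raise ValueError
                    if flag == 0:
                        g.add_node(u)
                        g.add_node(v)
                        continue
                    sign = 1
                    weight = None
                else:
                    sign = int(parts[2])
                    if sign not in (1, -1):
                        raise ValueError
                    weight = float(parts[3]) if len(parts) > 3 else None
            except ValueError:
                raise NetworkParseError(
                    f"{path}:{lineno}: malformed row {line!r} for dialect {dialect!r}"
                ) from None
            if (u, v) in g and g.sign(u, v) != sign:
                raise NetworkParseError(
                    f"{path}:{lineno}: duplicate edge ({u}, {v}) with conflicting sign"
                )
            g.add_edge(u, v, sign, weight)
    return g


def write_network(g: SignedDigraph, path, dialect: str = "signed") -> None:
    """Write a network edge list (see :func:`read_network` for formats)."""
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path, "w") as fh:
        for u, v in sorted(g.edge_pairs):
            if dialect == "dream":
                fh.write(f"{u}\t{v}\t1\n")
            else:
                w = g.weight(u, v)
                row = f"{u}\t{v}\t{g.sign(u, v):+d}"
                if w is not None:
                    row += f"\t{w:.6g}"
                fh.write(row + "\n")
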