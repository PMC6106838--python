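"""Weighted protein–protein interaction networks.

A PPI network is modeled as an undirected graph ``G = (V, E, W)`` whose nodes
are opaque protein identifiers and whose edges carry a reliability weight in
``(0, 1]``.  Self-interactions are biologically meaningless here and are
dropped on load; isolated proteins cannot occur because nodes only enter the
network through edges.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import networkx as nx

__all__ = [
    "NetworkParseError",
    "UnknownNodeError",
    "WeightedNetwork",
    "NeighborhoodGraph",
    "NetworkStats",
    "load_network",
    "write_network",
    "neighborhood",
    "network_stats",
]


class NetworkParseError(ValueError):
    """Raised when an edge-list file is malformed or yields an empty network."""


class UnknownNodeError(KeyError):
    """Raised when a queried protein is not a node of the network."""


class WeightedNetwork:
    """Undirected, self-loop-free graph with edge weights in ``(0, 1]``.

    Thin validated wrapper around a :class:`networkx.Graph`; the underlying
    graph is exposed as :attr:`g` for algorithms that want networkx directly.
    """

    __slots__ = ("g",)

    def __init__(self, graph: nx.Graph):
        for u, v, w in graph.edges(data="weight"):
            if u == v:
                raise ValueError(f"self-loop on node {u!r}")
            if w is None or not (0.0 < w <= 1.0):
                raise ValueError(f"edge ({u!r}, {v!r}) weight {w!r} outside (0, 1]")
        for n in graph.nodes:
            if graph.degree(n) == 0:
                raise ValueError(f"isolated node {n!r}")
        self.g = graph

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str, float]]) -> "WeightedNetwork":
        """Build a network from ``(u, v, weight)`` triples.

        Self-loops are dropped; duplicate edges collapse to the maximum weight
        (the most reliable report of an interaction wins).
        """
        g = nx.Graph()
        for u, v, w in edges:
            if u == v:
                continue
            w = float(w)
            if not (0.0 < w <= 1.0):
                raise ValueError(f"edge ({u!r}, {v!r}) weight {w!r} outside (0, 1]")
            if g.has_edge(u, v):
                if w > g[u][v]["weight"]:
                    g[u][v]["weight"] = w
            else:
                g.add_edge(u, v, weight=w)
        return cls(g)

    # -- queries -----------------------------------------------------------
    @property
    def nodes(self) -> set[str]:
        return set(self.g.nodes)

    @property
    def num_nodes(self) -> int:
        return self.g.number_of_nodes()

    @property
    def num_edges(self) -> int:
        return self.g.number_of_edges()

    def __contains__(self, v: str) -> bool:
        return v in self.g

    def __len__(self) -> int:
        return self.g.number_of_nodes()

    def _require(self, v: str) -> None:
        if v not in self.g:
            raise UnknownNodeError(v)

    def neighbors(self, v: str) -> set[str]:
        self._require(v)
        return set(self.g[v])

    def degree(self, v: str) -> int:
        self._require(v)
        return self.g.degree(v)

    def weight(self, u: str, v: str) -> float:
        return self.g[u][v]["weight"]

    def has_edge(self, u: str, v: str) -> bool:
        return self.g.has_edge(u, v)

    def edges(self) -> Iterator[tuple[str, str, float]]:
        return iter(self.g.edges(data="weight"))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WeightedNetwork):
            return NotImplemented
        mine = {frozenset((u, v)): w for u, v, w in self.edges()}
        theirs = {frozenset((u, v)): w for u, v, w in other.edges()}
        return mine == theirs

    def __repr__(self) -> str:
        return f"WeightedNetwork(|V|={self.num_nodes}, |E|={self.num_edges})"


@dataclass(frozen=True)
class NeighborhoodGraph:
    """Induced local subgraph ``GN_v`` of a node and its direct neighbors.

    ``members = {v} ∪ N(v)``; edges among neighbors are included even when not
    incident to the center.
    """

    center: str
    members: frozenset[str]
    graph: nx.Graph

    @property
    def num_edges(self) -> int:
        return self.graph.number_of_edges()

    def edges(self) -> Iterator[tuple[str, str, float]]:
        return iter(self.graph.edges(data="weight"))


@dataclass(frozen=True)
class NetworkStats:
    num_nodes: int
    num_edges: int
    density: float
    avg_neighbors: float


def load_network(path: str | Path, default_weight: float = 1.0) -> WeightedNetwork:
    """Read a whitespace-delimited edge list into a :class:`WeightedNetwork`.

    Rows have two columns (``protein_a protein_b``, assigned *default_weight*)
    or three (explicit weight in ``(0, 1]``).  ``#``-prefixed comment lines and
    blank lines are skipped.  Self-loops are dropped, duplicates keep the
    maximum weight, and a file that yields no edges is an error.
    """
    path = Path(path)
    edges: list[tuple[str, str, float]] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) == 2:
                u, v = cols
                w = float(default_weight)
            elif len(cols) == 3:
                u, v = cols[0], cols[1]
                try:
                    w = float(cols[2])
                except ValueError:
                    raise NetworkParseError(
                        f"{path}:{lineno}: non-numeric weight {cols[2]!r}"
                    ) from None
            else:
                raise NetworkParseError(
                    f"{path}:{lineno}: expected 2 or 3 columns, got {len(cols)}"
                )
            if not (0.0 < w <= 1.0):
                raise NetworkParseError(
                    f"{path}:{lineno}: weight {w!r} outside (0, 1]"
                )
            edges.append((u, v, w))
    net = WeightedNetwork.from_edges(edges)
    if net.num_edges == 0:
        raise NetworkParseError(f"{path}: no usable edges (empty network)")
    return net


def write_network(net: WeightedNetwork, path: str | Path) -> None:
    """Write the edge list back in the input dialect, deterministically ordered.

    Weights are written with :func:`repr` so a load/write round trip is
    bit-exact.
    """
    lines = []
    for u, v, w in net.edges():
        a, b = sorted((u, v))
        lines.append((a, b, w))
    lines.sort()
    with Path(path).open("w") as fh:
        for a, b, w in lines:
            fh.write(f"{a}\t{b}\t{w!r}\n")


def neighborhood(net: WeightedNetwork, v: str) -> NeighborhoodGraph:
    """Local neighborhood graph ``GN_v`` induced by ``{v} ∪ N(v)``."""
    members = frozenset(net.neighbors(v) | {v})
    sub = net.g.subgraph(members)
    return NeighborhoodGraph(center=v, members=members, graph=sub)


def network_stats(net: WeightedNetwork) -> NetworkStats:
    """Node/edge counts, density ``2|E|/(|V|(|V|-1))`` and mean neighbor count."""
    n, m = net.num_nodes, net.num_edges
    if n < 2:
        raise ValueError("density undefined for networks with fewer than 2 nodes")
    return NetworkStats(
        num_nodes=n,
        num_edges=m,
        density=2.0 * m / (n * (n - 1)),
        avg_neighbors=2.0 * m / n,
    )
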