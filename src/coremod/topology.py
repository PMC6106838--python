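"""Per-node topological statistics driving seed selection.

For every protein ``v`` the detector needs its plain degree ``deg(v)``,
weighted degree ``deg_w(v) = Σ_u w(v,u)``, unweighted betweenness centrality
``B(v)``, local weighted clustering coefficient ``LWCC_w(v)``, and the averages
of those quantities over the local neighborhood ``V_v = {v} ∪ N(v)``.

Conventions:

* betweenness is computed on the unweighted topology (hop-count shortest
  paths), each unordered pair counted once, unnormalized; node pairs in
  different components contribute nothing;
* the neighborhood averages use full-network values of the averaged statistic,
  not values recomputed inside ``GN_v``;
* every denominator is ``|V_v| = deg(v) + 1``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import networkx as nx
import pandas as pd

from .network import WeightedNetwork

__all__ = [
    "NodeProfile",
    "NeighborhoodAverages",
    "weighted_degree",
    "weighted_degrees",
    "betweenness_all",
    "lwcc",
    "lwcc_all",
    "neighborhood_avdeg",
    "neighborhood_avg_betweenness",
    "neighborhood_avg_lwcc",
    "profile_table",
]


@dataclass(frozen=True)
class NodeProfile:
    node: str
    degree: int
    weighted_degree: float
    betweenness: float
    lwcc: float


@dataclass(frozen=True)
class NeighborhoodAverages:
    node: str
    avdeg: float
    avg_betweenness: float
    avg_lwcc: float


def weighted_degree(net: WeightedNetwork, v: str) -> float:
    """``deg_w(v) = Σ_{u∈N(v)} w(v, u)``.

    Summed in sorted neighbor order so the value is identical across runs and
    input-file permutations.
    """
    return sum(net.weight(v, u) for u in sorted(net.neighbors(v)))


def weighted_degrees(net: WeightedNetwork) -> dict[str, float]:
    return {v: weighted_degree(net, v) for v in net.g.nodes}


def betweenness_all(net: WeightedNetwork) -> dict[str, float]:
    """Unnormalized Brandes betweenness on the unweighted topology.

    ``B(v) = Σ_{{s,t}, s≠v≠t} δ_st(v)/δ_st`` over unordered pairs.
    """
    return dict(nx.betweenness_centrality(net.g, normalized=False, weight=None))


def lwcc(net: WeightedNetwork, v: str) -> float:
    """Local weighted clustering coefficient: weighted density of ``GN_v``.

    Equals (sum of ``GN_v`` edge weights) / (max possible edge count of
    ``GN_v``); the result is clamped to [0, 1].
    """
    if net.degree(v) == 0:
        raise ValueError(f"lwcc undefined for isolated node {v!r}")
    members = net.neighbors(v) | {v}
    n = len(members)
    edge_weight_sum = sum(
        w
        for u, x, w in sorted(
            net.g.subgraph(members).edges(data="weight"),
            key=lambda e: tuple(sorted(e[:2])),
        )
    )
    value = 2.0 * edge_weight_sum / (n * (n - 1))
    return min(1.0, max(0.0, value))


def lwcc_all(net: WeightedNetwork) -> dict[str, float]:
    return {v: lwcc(net, v) for v in net.g.nodes}


def _members(net: WeightedNetwork, v: str) -> set[str]:
    return net.neighbors(v) | {v}


def neighborhood_avdeg(net: WeightedNetwork, v: str) -> float:
    """Average plain degree over ``V_v``, degrees measured in the full network."""
    members = _members(net, v)
    return sum(net.degree(u) for u in sorted(members)) / len(members)


def neighborhood_avg_betweenness(
    net: WeightedNetwork, v: str, b: Mapping[str, float]
) -> float:
    """Average full-network betweenness over ``V_v``."""
    members = _members(net, v)
    try:
        return sum(b[u] for u in sorted(members)) / len(members)
    except KeyError as exc:
        raise KeyError(f"betweenness map missing node {exc.args[0]!r}") from None


def neighborhood_avg_lwcc(
    net: WeightedNetwork, v: str, lw: Mapping[str, float]
) -> float:
    """Average full-network LWCC over ``V_v``."""
    members = _members(net, v)
    try:
        return sum(lw[u] for u in sorted(members)) / len(members)
    except KeyError as exc:
        raise KeyError(f"lwcc map missing node {exc.args[0]!r}") from None


def profile_table(net: WeightedNetwork) -> pd.DataFrame:
    """Full per-node statistics table for inspection or export.

    Columns: ``node degree weighted_degree betweenness lwcc avdeg avgB avgLWCC``.
    """
    b = betweenness_all(net)
    lw = lwcc_all(net)
    rows = []
    for v in sorted(net.g.nodes):
        rows.append(
            {
                "node": v,
                "degree": net.degree(v),
                "weighted_degree": weighted_degree(net, v),
                "betweenness": b[v],
                "lwcc": lw[v],
                "avdeg": neighborhood_avdeg(net, v),
                "avgB": neighborhood_avg_betweenness(net, v, b),
                "avgLWCC": neighborhood_avg_lwcc(net, v, lw),
            }
        )
    return pd.DataFrame(rows)
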