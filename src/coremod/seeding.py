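"""Overlapping-node identification and seed-queue construction.

Proteins shared between complexes (hub-bottlenecks) have both high degree and
high betweenness relative to their local neighborhood; growing a cluster from
one of them tends to fuse two real complexes into a single fake prediction.
They are therefore detected first and barred from seeding:

* **overlapping node**: ``deg(v) ≥ Avdeg(GN_v)`` and ``B(v) > AvgB(GN_v)``;
* **seed node**: any non-overlapping ``v`` with ``LWCC_w(v) ≥ AvgLWCC_w(v)``
  or ``B(v) ≤ AvgB(GN_v)``.

The seed queue is ordered by descending weighted degree (ties broken by
ascending identifier) so that runs are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .network import WeightedNetwork
from .topology import (
    betweenness_all,
    lwcc_all,
    neighborhood_avdeg,
    neighborhood_avg_betweenness,
    neighborhood_avg_lwcc,
    weighted_degrees,
)

__all__ = ["NodeClassification", "identify_overlapping_nodes", "select_seeds", "classify"]


@dataclass(frozen=True)
class NodeClassification:
    overlapping: frozenset[str]
    seeds: tuple[str, ...]


def identify_overlapping_nodes(
    net: WeightedNetwork, betweenness: Mapping[str, float] | None = None
) -> set[str]:
    """Nodes with ``deg(v) ≥ Avdeg(GN_v)`` and ``B(v) > AvgB(GN_v)``."""
    b = betweenness_all(net) if betweenness is None else betweenness
    out = set()
    for v in net.g.nodes:
        if net.degree(v) >= neighborhood_avdeg(net, v) and b[v] > (
            neighborhood_avg_betweenness(net, v, b)
        ):
            out.add(v)
    return out


def select_seeds(
    net: WeightedNetwork,
    overlapping: set[str],
    betweenness: Mapping[str, float] | None = None,
    lw: Mapping[str, float] | None = None,
) -> list[str]:
    """Ordered seed queue of non-overlapping, locally cohesive or low-betweenness nodes.

    A node qualifies when ``LWCC_w(v) ≥ AvgLWCC_w(v)`` or ``B(v) ≤ AvgB(GN_v)``
    (non-strict, as both conditions admit equality).  Note the second condition
    can never hold for an overlapping node, whose definition required the
    strict opposite inequality.
    """
    b = betweenness_all(net) if betweenness is None else betweenness
    lw = lwcc_all(net) if lw is None else lw
    wdeg = weighted_degrees(net)
    seeds = []
    for v in net.g.nodes:
        if v in overlapping:
            continue
        cond1 = lw[v] >= neighborhood_avg_lwcc(net, v, lw)
        cond2 = b[v] <= neighborhood_avg_betweenness(net, v, b)
        if cond1 or cond2:
            seeds.append(v)
    seeds.sort(key=lambda v: (-wdeg[v], v))
    return seeds


def classify(net: WeightedNetwork) -> NodeClassification:
    """Run both stages, sharing the topology maps between them."""
    b = betweenness_all(net)
    lw = lwcc_all(net)
    overlapping = identify_overlapping_nodes(net, betweenness=b)
    seeds = select_seeds(net, overlapping, betweenness=b, lw=lw)
    return NodeClassification(overlapping=frozenset(overlapping), seeds=tuple(seeds))
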