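"""Greedy seed expansion under a noise-corrected local-modularity fitness.

A cluster ``C`` starts as a single seed protein and is grown by repeatedly
testing the border node most similar to it.  Similarity is the *support*
function — the fraction of a node's total incident weight that falls inside
the cluster::

    support(u, C) = Σ_{v ∈ C ∩ N(u)} w(u,v)  /  Σ_{v ∈ N(u)} w(u,v)

Acceptance is decided by the local-modularity fitness::

    F(C) = weight_in(C) / (weight_in(C) + weight_out(C) + δ·|C|)^α

where ``weight_in`` sums internal edge weights (each once), ``weight_out``
sums boundary edge weights, and the ``δ·|C|`` term charges each member for
roughly δ undiscovered/noisy interactions.  δ defaults to half the network's
average node degree, i.e. ``|E|/|V|``; α defaults to 1, making F the ratio of
internal weight to total boundary-corrected weight.

Growth proceeds in passes.  At the start of a pass the border set (non-member
neighbors of the cluster) is collected; within the pass, the border node with
maximum support with respect to the *current* members is tested, accepted when
F does not decrease, and the pass ends at the first rejection (or, with the
``fallback_next_best`` variant, after every border node has been tried).
Passes repeat until the cluster stops changing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .network import UnknownNodeError, WeightedNetwork
from .topology import weighted_degrees

__all__ = [
    "ModularityParams",
    "Cluster",
    "GrowthEvent",
    "support",
    "cluster_weights",
    "fitness",
    "default_delta",
    "grow_cluster",
    "generate_candidates",
]


@dataclass(frozen=True)
class ModularityParams:
    """Fitness parameters: per-node noise correction δ ≥ 0 and exponent α > 0."""

    delta: float
    alpha: float = 1.0

    def __post_init__(self) -> None:
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")

    @classmethod
    def for_network(cls, net: WeightedNetwork, alpha: float = 1.0) -> "ModularityParams":
        return cls(delta=default_delta(net), alpha=alpha)


@dataclass(frozen=True)
class Cluster:
    """A grown protein set with cached boundary weights and fitness."""

    members: frozenset[str]
    weight_in: float
    weight_out: float
    fitness: float


@dataclass(frozen=True)
class GrowthEvent:
    """One accept/reject decision of the greedy growth, for tracing."""

    node: str
    support: float
    fitness_before: float
    fitness_after: float
    accepted: bool


def default_delta(net: WeightedNetwork) -> float:
    """Half the average node degree: ``(2|E|/|V|)/2 = |E|/|V|``."""
    if net.num_nodes == 0:
        raise ValueError("delta undefined for an empty network")
    return net.num_edges / net.num_nodes


def support(net: WeightedNetwork, u: str, members: Iterable[str]) -> float:
    """Fraction of ``u``'s incident weight landing inside the cluster."""
    members = set(members)
    if u in members:
        raise ValueError(f"support undefined for cluster member {u!r}")
    # one accumulation pass in sorted order: exact 1.0 for enclosed nodes and
    # float sums independent of set-iteration order
    total = 0.0
    inside = 0.0
    for v in sorted(net.neighbors(u)):
        w = net.weight(u, v)
        total += w
        if v in members:
            inside += w
    return inside / total


def cluster_weights(net: WeightedNetwork, members: Iterable[str]) -> tuple[float, float]:
    """``(weight_in, weight_out)``: internal and boundary edge-weight sums."""
    members = set(members)
    w_in = 0.0
    w_out = 0.0
    for v in sorted(members):
        for u in sorted(net.neighbors(v)):
            w = net.weight(v, u)
            if u in members:
                w_in += w  # counted from both endpoints; halved below
            else:
                w_out += w
    return w_in / 2.0, w_out


def _fitness_value(w_in: float, w_out: float, size: int, p: ModularityParams) -> float:
    den = (w_in + w_out + p.delta * size) ** p.alpha
    return w_in / den if den > 0 else 0.0


def fitness(net: WeightedNetwork, members: Iterable[str], p: ModularityParams) -> float:
    """Local-modularity fitness ``F(C)`` of a member set."""
    members = set(members)
    if not members:
        raise ValueError("fitness undefined for an empty cluster")
    w_in, w_out = cluster_weights(net, members)
    return _fitness_value(w_in, w_out, len(members), p)


def grow_cluster(
    net: WeightedNetwork,
    seed: str,
    p: ModularityParams,
    *,
    fallback_next_best: bool = False,
    trace: list[GrowthEvent] | None = None,
) -> Cluster:
    """Grow one candidate cluster from *seed* to a local fitness optimum.

    Deterministic: support ties break toward the higher weighted degree, then
    the lexicographically smaller identifier.  When *fallback_next_best* is
    set, a rejected border node does not end the pass; the remaining border
    nodes are still tried in descending support order.
    """
    if seed not in net:
        raise UnknownNodeError(seed)
    wdeg = weighted_degrees(net)

    members = {seed}
    w_in = 0.0
    w_out = wdeg[seed]
    f = _fitness_value(w_in, w_out, 1, p)

    changed = True
    while changed:
        changed = False
        border = {u for m in members for u in net.neighbors(m)} - members
        while border:
            # support w.r.t. the *current* members, recomputed after each accept
            def _inside(u: str) -> float:
                return sum(
                    net.weight(u, v) for v in sorted(net.neighbors(u)) if v in members
                )

            u_max = min(border, key=lambda u: (-_inside(u) / wdeg[u], -wdeg[u], u))
            inside = _inside(u_max)
            new_in = w_in + inside
            new_out = w_out - inside + (wdeg[u_max] - inside)
            f_new = _fitness_value(new_in, new_out, len(members) + 1, p)
            accepted = f_new >= f
            if trace is not None:
                trace.append(
                    GrowthEvent(
                        node=u_max,
                        support=inside / wdeg[u_max],
                        fitness_before=f,
                        fitness_after=f_new,
                        accepted=accepted,
                    )
                )
            border.discard(u_max)
            if accepted:
                members.add(u_max)
                w_in, w_out, f = new_in, new_out, f_new
                changed = True
            elif not fallback_next_best:
                break
    return Cluster(
        members=frozenset(members), weight_in=w_in, weight_out=w_out, fitness=f
    )


def generate_candidates(
    net: WeightedNetwork,
    seeds: Sequence[str],
    p: ModularityParams,
    *,
    fallback_next_best: bool = False,
) -> list[Cluster]:
    """One :func:`grow_cluster` per seed, in queue order.

    Every seed is expanded exactly once, even when an earlier cluster already
    absorbed it; duplicate clusters are resolved downstream by the merge step.
    """
    return [
        grow_cluster(net, s, p, fallback_next_best=fallback_next_best) for s in seeds
    ]
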