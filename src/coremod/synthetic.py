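"""Synthetic test networks with known ground truth.

Two generators:

* :func:`example_network` — a frozen 22-node worked-example network containing a
  single complex with explicit core / peripheral / overlapping structure, used
  throughout the tests because several of its support-function values are
  fixed by construction (0.295, 2/3, 6/13, 1.0);
* :func:`generate_planted` — a parameterized benchmark that plants
  core-attachment complexes in a noisy weighted network and returns the
  ground-truth catalog alongside it.

The planted model mirrors how reliability-weighted yeast PPI maps look to a
clustering method: each complex has a densely connected high-weight core
(drawn as a clique), loosely attached peripheral proteins, and optional
two-node "modules" shared between a pair of complexes (the overlapping
proteins).  Noise enters as spurious background edges with low weights (false
positives) and random deletion of planted edges (false negatives).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from importlib import resources

import numpy as np

from .evaluation import ComplexCatalog
from .network import WeightedNetwork, load_network

__all__ = [
    "EXAMPLE_CORE",
    "EXAMPLE_COMPLEX",
    "PlantedParams",
    "PlantedBenchmark",
    "example_network",
    "generate_planted",
]

#: Core and full membership of the single complex in the worked-example network.
EXAMPLE_CORE = frozenset({"0", "1", "2", "3", "4"})
EXAMPLE_COMPLEX = frozenset(str(i) for i in range(10))


def example_network() -> WeightedNetwork:
    """The frozen 22-node worked-example network.

    Nodes 0–9 form one complex (core 0–4, peripherals 5–7, overlapping nodes
    8–9); nodes 10–21 are outside.  Every edge has weight 0.2 except the core
    edges.  The reconstruction pins every constrained quantity: node 1 has
    incident weights {0.98, 0.87, 0.87, 0.2×3} (weighted degree 3.32), node 5
    has 9 neighbors of which 6 are inside the complex, node 8 has 13 neighbors
    of which 6 are inside.
    """
    ref = resources.files("coremod").joinpath("data/example_network.tsv")
    with resources.as_file(ref) as path:
        return load_network(path)


@dataclass(frozen=True)
class PlantedParams:
    """Generator settings for the planted core-attachment benchmark.

    Defaults model a mid-sized noisy map: 10 complexes whose cores are cliques
    of 4–8 proteins with reliabilities 0.7–1.0, 1–4 peripherals per complex
    attached to the core at 0.2–0.6, three 2-protein modules each shared by
    two complexes, background edges appearing with probability 0.05 per node
    pair at weight 0.1–0.3, and 10% of planted edges deleted as false
    negatives.
    """

    n_complexes: int = 10
    core_size: tuple[int, int] = (4, 8)
    n_peripherals: tuple[int, int] = (1, 4)
    n_overlap_modules: int = 3
    module_size: int = 2
    core_weight: tuple[float, float] = (0.7, 1.0)
    attach_weight: tuple[float, float] = (0.2, 0.6)
    background_p: float = 0.05
    background_weight: tuple[float, float] = (0.1, 0.3)
    deletion_rate: float = 0.1

    def validate(self) -> None:
        if self.n_complexes < 1:
            raise ValueError("need at least one complex")
        if self.core_size[0] < 3 or self.core_size[0] > self.core_size[1]:
            raise ValueError("core_size must be an increasing range with min >= 3")
        if self.n_peripherals[0] < 0 or self.n_peripherals[0] > self.n_peripherals[1]:
            raise ValueError("invalid peripheral count range")
        if self.n_overlap_modules > 0:
            if self.module_size < 1 or self.module_size >= self.core_size[0]:
                raise ValueError("overlap module must be smaller than the smallest core")
            if self.n_complexes < 2:
                raise ValueError("overlap modules need at least two complexes")
        if not (0.0 <= self.background_p <= 1.0):
            raise ValueError("background_p must lie in [0, 1]")
        if not (0.0 <= self.deletion_rate < 1.0):
            raise ValueError("deletion_rate must lie in [0, 1)")
        for lo, hi in (self.core_weight, self.attach_weight, self.background_weight):
            if not (0.0 < lo <= hi <= 1.0):
                raise ValueError("weight ranges must satisfy 0 < lo <= hi <= 1")


@dataclass(frozen=True)
class PlantedBenchmark:
    network: WeightedNetwork
    truth: ComplexCatalog
    params: PlantedParams
    seed: int

    def params_dict(self) -> dict:
        return asdict(self.params)


def _uniform(rng: np.random.Generator, lo_hi: tuple[float, float]) -> float:
    lo, hi = lo_hi
    return float(rng.uniform(lo, hi)) if hi > lo else lo


def generate_planted(
    params: PlantedParams | None = None, rng_seed: int = 0
) -> PlantedBenchmark:
    """Generate a planted core-attachment benchmark, deterministic in *rng_seed*."""
    p = params or PlantedParams()
    p.validate()
    rng = np.random.default_rng(rng_seed)

    edges: dict[tuple[str, str], float] = {}

    def put(u: str, v: str, w: float) -> None:
        key = (u, v) if u < v else (v, u)
        edges[key] = max(w, edges.get(key, 0.0))

    counter = 0

    def fresh(prefix: str, k: int) -> list[str]:
        nonlocal counter
        out = [f"{prefix}{counter + i:04d}" for i in range(k)]
        counter += k
        return out

    cores: list[list[str]] = []
    complexes: list[set[str]] = []
    planted: list[tuple[str, str]] = []

    for _ in range(p.n_complexes):
        size = int(rng.integers(p.core_size[0], p.core_size[1] + 1))
        core = fresh("p", size)
        for i in range(size):
            for j in range(i + 1, size):
                put(core[i], core[j], _uniform(rng, p.core_weight))
                planted.append(tuple(sorted((core[i], core[j]))))
        members = set(core)
        n_per = int(rng.integers(p.n_peripherals[0], p.n_peripherals[1] + 1))
        for per in fresh("p", n_per):
            k = int(rng.integers(2, min(3, size) + 1))
            for c in rng.choice(core, size=k, replace=False):
                put(per, str(c), _uniform(rng, p.attach_weight))
                planted.append(tuple(sorted((per, str(c)))))
            members.add(per)
        cores.append(core)
        complexes.append(members)

    # overlap modules: small node sets shared by exactly two complexes,
    # attached to a few core members of each
    for _ in range(p.n_overlap_modules):
        a, b = rng.choice(p.n_complexes, size=2, replace=False)
        module = fresh("m", p.module_size)
        for i in range(p.module_size):
            for j in range(i + 1, p.module_size):
                put(module[i], module[j], _uniform(rng, p.attach_weight))
                planted.append(tuple(sorted((module[i], module[j]))))
        for idx in (int(a), int(b)):
            core = cores[idx]
            k = min(3, len(core))
            for node in module:
                for c in rng.choice(core, size=k, replace=False):
                    put(node, str(c), _uniform(rng, p.attach_weight))
                    planted.append(tuple(sorted((node, str(c)))))
            complexes[idx].update(module)

    # false negatives: delete planted edges, never isolating an endpoint;
    # per-edge uniforms are drawn in a fixed order so deletion sets at rate
    # r1 < r2 are nested for the same seed
    degree: dict[str, int] = {}
    for u, v in edges:
        degree[u] = degree.get(u, 0) + 1
        degree[v] = degree.get(v, 0) + 1
    for key in sorted(set(planted)):
        u_draw = rng.random()
        if u_draw < p.deletion_rate and key in edges:
            u, v = key
            if degree[u] > 1 and degree[v] > 1:
                del edges[key]
                degree[u] -= 1
                degree[v] -= 1

    # false positives: background edges over uniformly random node pairs
    nodes = sorted({n for c in complexes for n in c})
    if p.background_p > 0:
        for i in range(len(nodes)):
            for j in range(i + 1, len(nodes)):
                if rng.random() < p.background_p:
                    key = (nodes[i], nodes[j])
                    if key not in edges:
                        edges[key] = _uniform(rng, p.background_weight)

    net = WeightedNetwork.from_edges((u, v, w) for (u, v), w in edges.items())
    truth = ComplexCatalog.from_sets(
        [frozenset(c) for c in complexes],
        names=[f"T{i + 1:03d}" for i in range(len(complexes))],
    )
    return PlantedBenchmark(network=net, truth=truth, params=p, seed=rng_seed)
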