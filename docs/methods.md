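# Methods

## Model and assumptions

The detector treats a weighted PPI network as an undirected graph
`G = (V, E, W)` with edge reliabilities in (0, 1]. Its central modeling
assumption is that a protein complex is organized as **core + attachments**:
a small, densely interconnected, high-reliability core; peripheral proteins
bound to the core by fewer or weaker edges; and overlapping proteins shared
between two or more complexes. Complexes are therefore *not* assumed to be
dense subgraphs — the criterion optimized is **local modularity** (more
internal than external weight, after a noise correction), which admits
low-density complexes that plain density objectives discard.

Two topological signatures drive the node taxonomy:

* **Overlapping proteins** are hub-bottlenecks: shortest paths between the
  complexes they join must pass through them, so both their degree and their
  betweenness exceed their neighborhood averages
  (`deg(v) ≥ Avdeg(GN_v)` and, strictly, `B(v) > AvgB(GN_v)`).
* **Core/seed proteins** are hub-non-bottlenecks: highly clustered
  (`LWCC_w(v) ≥ AvgLWCC_w(v)`) or bypassable (`B(v) ≤ AvgB(GN_v)`).

Conventions fixed in this implementation (each is invisible to the results
wherever it cancels, and deterministic everywhere):

* Betweenness uses unweighted hop-count shortest paths (Brandes), each
  unordered pair counted once, unnormalized; disconnected pairs contribute 0.
  Since `B(v)` is only ever compared against an average of the same map, the
  pair-counting convention cancels out of every decision.
* `Avdeg(GN_v)` averages **plain** degrees, and all neighborhood averages
  divide by `|V_v| = deg(v) + 1` and use full-network statistics of the
  members (not statistics recomputed inside `GN_v`).
* Duplicate input edges keep the maximum weight (reliability semantics);
  zero-weight edges are rejected as indistinguishable from absence;
  unweighted 2-column files are assigned a configurable default weight (1.0).

## Growth procedure and numerical choices

Each seed grows one cluster. A pass collects the border set (non-member
neighbors of the cluster); within the pass the border node with maximum
support *with respect to the current members* is tested — supports are
recomputed after every acceptance, which is what makes the worked example
accept nodes 1, 2, 3, 4 in that order — and the pass ends at the first
rejection. Passes repeat until the cluster stops changing; since a pass
that changes nothing terminates the loop and the border set shrinks
monotonically within a pass, termination is guaranteed even on fitness
plateaus (acceptance is non-strict, `F' ≥ F`).

* Tie-breaks for the argmax: higher weighted degree, then lexicographically
  smaller identifier. Seed-queue order: descending weighted degree, same
  tie-break. Both are conventions chosen for determinism.
* `δ` is computed once per network from the **unweighted** average degree
  (`δ = |E|/|V|`), not per cluster; `α = 1` makes the fitness the ratio of
  internal weight to boundary-corrected total weight.
* A `fallback_next_best` variant (off by default) lets a pass continue down
  the support ranking after a rejection. The strict first-rejection reading
  is the default because the worked-example narrative requires the pass to
  end when its top candidate fails; with the variant enabled the same
  example still yields the same core (every remaining candidate fails the
  fitness test at the core).
* Merging: a single forward pass in candidate order; a survivor absorbs
  later candidates at `OS ≥ ω` and comparisons continue against the updated
  survivor. At the default `ω = 1` this is exactly set deduplication and is
  order-independent and idempotent; at `ω < 1` order matters and a single
  pass is the documented convention (it is not guaranteed to reach a merge
  fixed point, which only the default threshold makes moot).
* Fitness denominator of 0 (conceivable only with `δ = 0` on an all-external
  cluster) is defined as fitness 0.

## Evaluation

`Sn`, `PPV`, and `ACC = √(Sn·PPV)` follow the standard confusion-matrix
construction `t_ij = |N_i ∩ M_j|`; `PPV`'s denominator `Σ_j Σ_i t_ij`
deliberately retains its documented bias against overlapping predictions.
`Fraction` counts references matched by some prediction at `OS ≥ 0.25`
(non-strict); the `MMR` bipartite graph admits edges at `OS > 0.25`
(strict) and is solved exactly as a linear assignment problem. Reference
catalogs drop complexes with fewer than 3 members at load time; predictions
are size-filtered by the pipeline itself. Proteins present in the reference
but absent from the network are retained — the metrics are catalog-level.

## Synthetic benchmark

`generate_planted` emulates the structure the detector assumes, with noise:

| parameter | default | meaning |
|---|---|---|
| `n_complexes` | 10 | planted complexes |
| `core_size` | 4–8 | core drawn as a clique |
| `core_weight` | 0.7–1.0 | intra-core reliabilities |
| `n_peripherals` | 1–4 | per complex, each attached to 2–3 core members |
| `attach_weight` | 0.2–0.6 | peripheral/module attachment reliabilities |
| `n_overlap_modules` | 3 | 2-node modules shared by exactly two complexes |
| `background_p` | 0.05 | per-pair probability of a spurious edge |
| `background_weight` | 0.1–0.3 | spurious-edge reliabilities |
| `deletion_rate` | 0.1 | planted edges removed as false negatives |

The weight bands mirror how reliability-scored interaction maps look: real
complex edges score high, background co-purification noise scores low. False
negatives are drawn with one uniform per planted edge in a fixed order, so
for a fixed seed the deleted sets at increasing rates are nested (this is
what makes mean intra-complex weight provably non-increasing in the rate);
an edge whose removal would isolate a protein is kept, so every ground-truth
member remains in the network.

What the generator does **not** emulate: the heavy-tailed degree
distributions, size spectrum, and weight distributions of real
affinity-purification networks, complexes shared by three or more partners,
and correlated (non-uniform) noise. Passing the recovery tests therefore
demonstrates that the pipeline recovers core-attachment structure under
moderate uniform noise — not field performance on real yeast maps.

The frozen 22-node worked-example network is one concrete realization of a
partially constrained design: the pinned quantities (node 1's incident
weights and supports 0.295 / 2⁄3 / 6⁄13 / 1.0; the neighbor splits of nodes
5 and 8; the accept/reject trace from seed 0) are fixed exactly, while the
remaining neighbor lists (nodes 6, 7, 9 and the 12 outside nodes) are a
documented free choice. Tests depend only on the pinned quantities.

## Problem sizes

The test and acceptance workloads use the 22-node fixture, random graphs of
≤ 14 nodes for oracle-equivalence properties (100 instances each), and
planted benchmarks of ~70–90 nodes across 20 seeds — sizes at which every
kernel (exact betweenness, exhaustive matching oracles) is exact and fast.
Exact Brandes betweenness scales comfortably to the few-thousand-node
networks this method targets; no approximate betweenness is provided.

## Known limitations

* On the worked example, the full depicted complex (core plus peripherals
  and overlapping nodes 5–9) is *not* emitted: adding node 5 to the grown
  core strictly decreases the fitness, so no acceptance rule consistent with
  F can absorb it. The implementation grows the core only and surfaces the
  `fallback_next_best` flag rather than inventing a second-phase criterion
  that the fitness function cannot justify.
* At `ω < 1` the merge step is order-dependent (candidate order = seed-queue
  order) and single-pass by convention.
* Seed selection and growth are purely topological; no expression data or
  functional annotation is used.
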