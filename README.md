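# coremod

Detection of **overlapping protein complexes** in weighted protein–protein
interaction (PPI) networks, built on the core-attachment view of complex
organization, together with the standard catalog-matching evaluation suite
and a planted-complex benchmark generator.

## Who this is for

Systems biologists and method developers who have a reliability-weighted PPI
network (an edge list `protein_a  protein_b  weight`, weights in (0, 1]) and
want to (a) predict protein complexes that may **share members** and **vary in
density**, and (b) score any set of predicted complexes against a reference
catalog such as CYC2008 or MIPS-style membership files.

## The method

A protein complex is modeled as a *core* of densely interconnected,
high-reliability proteins plus *attachments*: peripheral proteins loosely
bound to the core, and *overlapping* proteins ("modules") shared with other
complexes. Detection proceeds in four stages on the network
`G = (V, E, W)`:

1. **Overlapping-node identification.** A node `v` is overlapping
   (hub-bottleneck) when `deg(v) ≥ Avdeg(GN_v)` **and** `B(v) > AvgB(GN_v)`,
   where `GN_v` is the subgraph induced by `v` and its neighbors, `B` is
   unweighted betweenness centrality, and the averages run over
   `V_v = {v} ∪ N(v)`. Such nodes sit between complexes; growing a cluster
   from one tends to fuse two real complexes into one false prediction, so
   they are barred from seeding.

2. **Seed selection.** Any non-overlapping `v` with
   `LWCC_w(v) ≥ AvgLWCC_w(v)` **or** `B(v) ≤ AvgB(GN_v)` enters the seed
   queue (ordered by descending weighted degree), where `LWCC_w` is the
   local weighted clustering coefficient — the weighted density of `GN_v`.

3. **Greedy expansion.** From each seed, border nodes are ranked by the
   *support function* — the fraction of a node's incident weight falling
   inside the cluster:

       support(u, C) = Σ_{v ∈ C∩N(u)} w(u,v) / Σ_{v ∈ N(u)} w(u,v)

   and the top-support node is accepted whenever the noise-corrected
   **local-modularity fitness** does not decrease:

       F(C) = weight_in(C) / (weight_in(C) + weight_out(C) + δ·|C|)^α

   with δ defaulting to half the network's average degree (`|E|/|V|`) — a
   per-node charge for undiscovered/noisy interactions — and α = 1. Growth
   repeats in passes until the cluster stops changing.

4. **Merge/remove.** Candidate clusters with overlap score
   `OS(A,B) = |A∩B|²/(|A||B|) ≥ ω` are unioned (default ω = 1, i.e. exact
   deduplication) and complexes with fewer than 3 members are dropped.

Evaluation against a reference catalog `R` reports clustering-wise
sensitivity `Sn`, positive predictive value `PPV`, geometric accuracy
`ACC = √(Sn·PPV)`, the `Fraction` of references matched at OS ≥ 0.25, the
maximum matching ratio `MMR` (total OS weight of a maximum one-to-one
bipartite matching, divided by |R|), and the composite score
`ACC + Fraction + MMR`.

## Worked example

The package ships a frozen 22-node example network containing one complex
(core `{0..4}`, peripherals `{5,6,7}`, overlapping nodes `{8,9}`) whose
support-function values are fixed by construction:

```python
import coremod as cm

net = cm.example_network()
print("support(1, {0})     =", round(cm.support(net, "1", {"0"}), 3))
print("support(5, complex) =", round(cm.support(net, "5", cm.EXAMPLE_COMPLEX - {"5"}), 3))

params = cm.ModularityParams.for_network(net)   # delta = |E|/|V|, alpha = 1
trace = []
core = cm.grow_cluster(net, "0", params, trace=trace)
print(sorted(core.members, key=int), f"F={core.fitness:.3f}")
print([(e.node, "accept" if e.accepted else "reject") for e in trace])
```

prints

```
support(1, {0})     = 0.295
support(5, complex) = 0.667
['0', '1', '2', '3', '4'] F=0.369
[('1', 'accept'), ('2', 'accept'), ('3', 'accept'), ('4', 'accept'), ('5', 'reject'), ('5', 'reject')]
```

Node 1 commits 29.5% of its incident weight to the seed cluster `{0}` — the
highest support among the seed's neighbors — so it is tested (and accepted)
first; nodes 2, 3, 4 follow, and node 5 is rejected because adding it lowers
the fitness, leaving exactly the planted complex core. On a synthetic
benchmark with 10 planted core-attachment complexes and noise:

```python
bench = cm.generate_planted(rng_seed=1)
pred = cm.detect(bench.network)
report = cm.evaluate(bench.truth, cm.ComplexCatalog.from_sets(pred.complexes))
print(f"ACC={report.acc:.3f}  Fraction={report.fraction:.3f}  MMR={report.mmr:.3f}")
```

```
ACC=0.851  Fraction=1.000  MMR=0.804
```

i.e. every planted complex is matched at OS ≥ 0.25 and the one-to-one
matching retains ~80% of the maximum possible overlap weight.

## Command line

```bash
coremod detect   --network net.tsv --out pred.txt [--delta X] [--omega X] [--min-size N]
coremod eval     --pred pred.txt --ref cyc2008.txt [--match-threshold 0.25]
coremod simulate --out-dir bench/ --seed 7 [--params params.yaml]
```

`detect` reads a 2- or 3-column edge list (2-column files get
`--default-weight`, default 1.0), writes one complex per line; `eval` prints
a single-row TSV report; `simulate` writes `network.tsv`, `truth.txt`, and
`params.yaml` for a planted benchmark.

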