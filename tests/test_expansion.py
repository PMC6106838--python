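"""Support function, local-modularity fitness, and greedy cluster growth."""

import itertools

import pytest

import coremod as cm
from coremod.expansion import GrowthEvent
from coremod.topology import weighted_degree
from conftest import net_from, random_network


def k4(weight=1.0):
    return net_from(
        [(f"n{i}", f"n{j}", weight) for i in range(4) for j in range(i + 1, 4)]
    )


class TestSupport:
    def test_worked_example_pinned_values(self, example_net):
        C = cm.EXAMPLE_COMPLEX
        assert cm.support(example_net, "1", {"0"}) == pytest.approx(0.295, abs=5e-4)
        assert cm.support(example_net, "5", C - {"5"}) == pytest.approx(2 / 3)
        assert cm.support(example_net, "8", C - {"8"}) == pytest.approx(6 / 13)

    def test_fully_enclosed_node_scores_one(self, example_net):
        assert cm.support(example_net, "1", cm.EXAMPLE_COMPLEX - {"1"}) == 1.0

    def test_member_node_rejected(self, triangle):
        with pytest.raises(ValueError):
            cm.support(triangle, "A", {"A", "B"})

    @pytest.mark.parametrize("seed", range(10))
    def test_bounded_and_one_iff_enclosed(self, seed):
        net = random_network(seed)
        nodes = sorted(net.nodes)
        cluster = set(nodes[: max(1, len(nodes) // 2)])
        for u in net.nodes - cluster:
            s = cm.support(net, u, cluster)
            assert 0.0 <= s <= 1.0 + 1e-12
            assert (abs(s - 1.0) < 1e-12) == (net.neighbors(u) <= cluster)


class TestClusterWeights:
    def test_triangle_whole(self, triangle):
        assert cm.expansion.cluster_weights(triangle, {"A", "B", "C"}) == (3.0, 0.0)

    def test_triangle_pair(self, triangle):
        w_in, w_out = cm.expansion.cluster_weights(triangle, {"A", "B"})
        assert (w_in, w_out) == (1.0, 2.0)

    def test_empty_set(self, triangle):
        assert cm.expansion.cluster_weights(triangle, set()) == (0.0, 0.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_weight_conservation(self, seed):
        net = random_network(seed)
        nodes = sorted(net.nodes)
        members = set(nodes[::2])
        w_in, w_out = cm.expansion.cluster_weights(net, members)
        total = sum(weighted_degree(net, v) for v in members)
        assert 2 * w_in + w_out == pytest.approx(total)


class TestFitness:
    @pytest.mark.parametrize(
        "members, delta, expected",
        [
            ({"A", "B", "C"}, 0.0, 1.0),
            ({"A", "B", "C"}, 1.0, 0.5),
            ({"A", "B"}, 0.5, 0.25),
        ],
    )
    def test_triangle_cases(self, triangle, members, delta, expected):
        p = cm.ModularityParams(delta=delta, alpha=1.0)
        assert cm.fitness(triangle, members, p) == pytest.approx(expected)

    def test_empty_cluster_rejected(self, triangle):
        with pytest.raises(ValueError):
            cm.fitness(triangle, set(), cm.ModularityParams(delta=0.0))

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            cm.ModularityParams(delta=-1.0)
        with pytest.raises(ValueError):
            cm.ModularityParams(delta=0.0, alpha=0.0)


class TestDefaultDelta:
    @pytest.mark.parametrize(
        "edges, expected",
        [
            ([("A", "B", 1.0), ("B", "C", 1.0), ("A", "C", 1.0)], 1.0),
            ([("A", "B", 1.0), ("B", "C", 1.0)], 2 / 3),
            (
                [(f"n{i}", f"n{j}", 1.0) for i in range(5) for j in range(i + 1, 5)],
                2.0,
            ),
        ],
    )
    def test_half_average_degree(self, edges, expected):
        assert cm.default_delta(net_from(edges)) == pytest.approx(expected)


class TestGrowCluster:
    def test_worked_example_core_recovery_with_trace(self, example_net):
        trace: list[GrowthEvent] = []
        p = cm.ModularityParams.for_network(example_net)
        cluster = cm.grow_cluster(example_net, "0", p, trace=trace)
        assert cluster.members == cm.EXAMPLE_CORE
        accepted = [e.node for e in trace if e.accepted]
        assert accepted == ["1", "2", "3", "4"]
        rejected = [e.node for e in trace if not e.accepted]
        assert rejected and set(rejected) == {"5"}

    def test_isolated_clique_fully_recovered(self):
        net = k4()
        p = cm.ModularityParams(delta=0.1)
        cluster = cm.grow_cluster(net, "n0", p)
        assert cluster.members == net.nodes
        # exhaustive check: of all member sets containing the seed, the full
        # clique maximizes F, so greedy acceptance is the global optimum here
        best = max(
            (
                cm.fitness(net, {"n0"} | set(extra), p)
                for r in range(4)
                for extra in itertools.combinations(net.nodes - {"n0"}, r)
            )
        )
        assert cluster.fitness == pytest.approx(best)

    def test_unknown_seed(self, triangle):
        with pytest.raises(cm.UnknownNodeError):
            cm.grow_cluster(triangle, "Z", cm.ModularityParams(delta=0.0))

    @pytest.mark.parametrize("seed", range(10))
    def test_fitness_monotone_along_accepted_trace(self, seed):
        net = random_network(seed)
        p = cm.ModularityParams.for_network(net)
        start = sorted(net.nodes)[0]
        trace: list[GrowthEvent] = []
        cluster = cm.grow_cluster(net, start, p, trace=trace)
        last = 0.0
        for e in trace:
            if e.accepted:
                assert e.fitness_after >= e.fitness_before - 1e-12
                last = e.fitness_after
        assert cluster.fitness == pytest.approx(last) or not any(
            e.accepted for e in trace
        )

    @pytest.mark.parametrize("seed", range(10))
    def test_result_locally_maximal_and_cached_weights_consistent(self, seed):
        net = random_network(seed)
        p = cm.ModularityParams.for_network(net)
        start = sorted(net.nodes)[0]
        cluster = cm.grow_cluster(net, start, p)
        w_in, w_out = cm.expansion.cluster_weights(net, cluster.members)
        assert cluster.weight_in == pytest.approx(w_in)
        assert cluster.weight_out == pytest.approx(w_out)
        border = {
            u for m in cluster.members for u in net.neighbors(m)
        } - cluster.members
        if border:
            from coremod.topology import weighted_degrees

            wdeg = weighted_degrees(net)
            u_max = min(
                border,
                key=lambda u: (-cm.support(net, u, cluster.members), -wdeg[u], u),
            )
            assert (
                cm.fitness(net, cluster.members | {u_max}, p)
                < cluster.fitness + 1e-12
            )

    def test_deterministic(self, example_net):
        p = cm.ModularityParams.for_network(example_net)
        a = cm.grow_cluster(example_net, "3", p)
        b = cm.grow_cluster(example_net, "3", p)
        assert a == b


class TestGenerateCandidates:
    def test_two_seeds_one_clique_duplicate_clusters(self):
        net = k4()
        p = cm.ModularityParams(delta=0.1)
        out = cm.generate_candidates(net, ["n0", "n1"], p)
        assert len(out) == 2 and out[0].members == out[1].members == net.nodes

    def test_empty_queue(self, triangle):
        assert cm.generate_candidates(triangle, [], cm.ModularityParams(delta=0.0)) == []

    def test_disjoint_cliques_one_cluster_each(self):
        edges = [(f"a{i}", f"a{j}", 0.9) for i in range(4) for j in range(i + 1, 4)]
        edges += [(f"b{i}", f"b{j}", 0.9) for i in range(4) for j in range(i + 1, 4)]
        net = net_from(edges)
        p = cm.ModularityParams.for_network(net)
        out = cm.generate_candidates(net, ["a0", "b0"], p)
        assert out[0].members == {f"a{i}" for i in range(4)}
        assert out[1].members == {f"b{i}" for i in range(4)}
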