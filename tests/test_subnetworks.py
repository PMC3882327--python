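"""Subnetwork growth, enumeration, ranking and conservation tests."""

import itertools

import networkx as nx
import numpy as np
import pytest

from conftest import make_scored_network, random_scored_network
from epistage.datatypes import ValidationError
from epistage.subnetworks import (
    Subnetwork,
    _max_spanning_edges,
    _qualifying_graph,
    enumerate_subnetworks,
    hub_profile,
    propagate_conserved,
    rank_subnetworks,
    seed_and_expand,
    subnetwork_strength,
)


def exhaustive_best(net, size, sim_threshold=0.6):
    """Oracle: max Eq-score over all valid gene sets of exactly `size`."""
    q = _qualifying_graph(net, sim_threshold)
    meth = net.methylated
    best = None
    for combo in itertools.combinations(sorted(q.nodes), size):
        genes = frozenset(combo)
        if not genes & meth:
            continue
        sub = q.subgraph(genes)
        if sub.number_of_nodes() != size or not nx.is_connected(sub):
            continue
        span = _max_spanning_edges(genes, q)
        score = subnetwork_strength(genes, span, net)
        if best is None or score > best[0]:
            best = (score, genes)
    return best


class TestStrength:
    def test_single_node_equals_node_strength(self):
        net = make_scored_network([], {"M": 0.7}, {}, {"M"})
        assert subnetwork_strength(["M"], [], net) == pytest.approx(0.7)

    def test_two_node_arithmetic(self):
        net = make_scored_network(
            [("A", "B")], {"A": 0.4, "B": 0.6}, {("A", "B"): 0.8}, {"A"}
        )
        assert subnetwork_strength(["A", "B"], [("A", "B")], net) == pytest.approx(0.9)

    def test_insertion_order_irrelevant(self):
        net = make_scored_network(
            [("A", "B"), ("B", "C")],
            {"A": 0.1, "B": 0.2, "C": 0.3},
            {("A", "B"): 0.7, ("B", "C"): 0.9},
            {"A"},
        )
        edges = [("A", "B"), ("B", "C")]
        assert subnetwork_strength(["A", "B", "C"], edges, net) == pytest.approx(
            subnetwork_strength(["C", "A", "B"], edges, net)
        )

    def test_empty_rejected(self):
        net = make_scored_network([], {"M": 0.5}, {}, {"M"})
        with pytest.raises(ValidationError):
            subnetwork_strength([], [], net)


class TestSeedAndExpand:
    def test_no_qualifying_neighbor_size_one(self):
        net = make_scored_network(
            [("M", "A")], {"M": 0.9, "A": 0.5}, {("M", "A"): 0.3}, {"M"}
        )
        sub = seed_and_expand(net, "M", target_size=4)
        assert sub.genes == ("M",) and sub.retained_edges == ()

    def test_hand_traced_greedy_sequence(self):
        # seed M (neighbors A, B). Step 1: B joins (0.8 > 0.6) via M-B.
        # Step 2: candidates {A, C}; C has the top node strength (0.95)
        # and joins via its only edge to the set, B-C. Step 3: A joins
        # via its strongest edge to the set, A-C (0.8 > 0.7).
        net = make_scored_network(
            [("M", "A"), ("M", "B"), ("A", "C"), ("B", "C")],
            {"M": 0.9, "A": 0.6, "B": 0.8, "C": 0.95},
            {
                ("M", "A"): 0.7,
                ("M", "B"): 0.9,
                ("A", "C"): 0.8,
                ("B", "C"): 0.65,
            },
            {"M"},
        )
        sub = seed_and_expand(net, "M", target_size=4)
        assert sub.genes == ("M", "B", "C", "A")
        assert sub.retained_edges == (("B", "M"), ("B", "C"), ("A", "C"))

    def test_unknown_seed_rejected(self):
        net = make_scored_network([], {"M": 0.5}, {}, {"M"})
        with pytest.raises(ValidationError):
            seed_and_expand(net, "X", 3)

    def test_deterministic(self):
        rng = np.random.default_rng(0)
        net = random_scored_network(rng, 8)
        seed = sorted(net.methylated)[0]
        a = seed_and_expand(net, seed, 5)
        b = seed_and_expand(net, seed, 5)
        assert a.genes == b.genes and a.retained_edges == b.retained_edges

    @pytest.mark.parametrize("seed", range(10))
    def test_greedy_bounded_by_exhaustive(self, seed):
        rng = np.random.default_rng(seed)
        net = random_scored_network(rng, int(rng.integers(5, 11)), p=0.6)
        start = sorted(net.methylated)[0]
        sub = seed_and_expand(net, start, 4, sim_threshold=0.3)
        best = exhaustive_best(net, sub.size, sim_threshold=0.3)
        if best is not None:
            assert sub.strength <= best[0] + 1e-9


class TestEnumeration:
    def test_path_definition_example(self):
        net = make_scored_network(
            [("M", "A"), ("A", "B")],
            {"M": 0.5, "A": 0.5, "B": 0.5},
            {("M", "A"): 0.9, ("A", "B"): 0.9},
            {"M"},
        )
        subs = enumerate_subnetworks(net, max_size=3)
        sets = {s.gene_set for s in subs}
        assert sets == {frozenset({"M", "A"}), frozenset({"M", "A", "B"})}

    def test_triangle_of_methylated(self):
        net = make_scored_network(
            [],
            {"A": 0.5, "B": 0.5, "C": 0.5},
            {("A", "B"): 0.9, ("B", "C"): 0.9, ("A", "C"): 0.9},
            {"A", "B", "C"},
        )
        subs = enumerate_subnetworks(net, max_size=3)
        assert sum(1 for s in subs if s.size == 2) == 3
        assert sum(1 for s in subs if s.size == 3) == 1

    def test_max_size_validation(self):
        net = make_scored_network([], {"M": 0.5}, {}, {"M"})
        with pytest.raises(ValidationError):
            enumerate_subnetworks(net, max_size=1)

    @pytest.mark.parametrize("seed", range(8))
    def test_count_matches_bruteforce(self, seed):
        rng = np.random.default_rng(100 + seed)
        net = random_scored_network(rng, int(rng.integers(4, 11)), p=0.5)
        subs = enumerate_subnetworks(net, max_size=4, sim_threshold=0.4)
        q = _qualifying_graph(net, 0.4)
        meth = net.methylated
        brute = set()
        for k in (2, 3, 4):
            for combo in itertools.combinations(sorted(q.nodes), k):
                sub = q.subgraph(combo)
                if nx.is_connected(sub) and set(combo) & meth and sub.number_of_nodes() == k:
                    brute.add(frozenset(combo))
        assert {s.gene_set for s in subs} == brute

    def test_monotone_in_max_size_and_threshold(self):
        rng = np.random.default_rng(5)
        net = random_scored_network(rng, 9, p=0.6)
        n3 = len(enumerate_subnetworks(net, max_size=3, sim_threshold=0.4))
        n4 = len(enumerate_subnetworks(net, max_size=4, sim_threshold=0.4))
        assert n4 >= n3
        strict = len(enumerate_subnetworks(net, max_size=4, sim_threshold=0.6))
        assert strict <= n4

    def test_outputs_satisfy_invariants(self):
        rng = np.random.default_rng(9)
        net = random_scored_network(rng, 9, p=0.6)
        for sub in enumerate_subnetworks(net, max_size=4, sim_threshold=0.5):
            assert set(sub.genes) & net.methylated
            span = nx.Graph(sub.retained_edges)
            span.add_nodes_from(sub.genes)
            assert nx.is_connected(span)
            for a, b in sub.retained_edges:
                assert net.edge_strength(a, b) >= 0.5


class TestRanking:
    def _sub(self, genes, strength):
        return Subnetwork(
            stage="I", genes=tuple(genes), seed=genes[0], strength=strength,
            retained_edges=(),
        )

    def test_descending_order(self):
        ranked = rank_subnetworks([self._sub("AB", 0.7), self._sub("CD", 0.9)])
        assert [s.strength for s in ranked] == [0.9, 0.7]

    def test_tie_larger_size_first(self):
        ranked = rank_subnetworks([self._sub("ABC", 0.5), self._sub("ABCD", 0.5)])
        assert ranked[0].size == 4

    def test_stable_under_shuffling(self):
        subs = [self._sub(g, s) for g, s in [("AB", 0.1), ("CD", 0.9), ("EF", 0.5)]]
        assert rank_subnetworks(subs) == rank_subnetworks(list(reversed(subs)))


class TestConserved:
    def _clique_net(self, stage="I"):
        genes = ["M1", "M2", "M3", "M4", "M5"]
        es = {e: 0.9 for e in itertools.combinations(genes, 2)}
        ns = {g: 0.8 for g in genes}
        db = {g: 0.4 for g in genes}
        return make_scored_network([], ns, es, set(genes), stage=stage, delta_beta=db)

    def test_identical_networks_self_intersection(self):
        nets = {"I": self._clique_net("I"), "II": self._clique_net("II")}
        conserved, supporting = propagate_conserved(nets, max_size=6)
        assert conserved == {"M1", "M2", "M3", "M4", "M5"}
        assert set(supporting) == {"I", "II"}

    def test_disjoint_networks_empty(self):
        a = self._clique_net("I")
        genes = ["X1", "X2", "X3", "X4"]
        es = {e: 0.9 for e in itertools.combinations(genes, 2)}
        b = make_scored_network(
            [], {g: 0.8 for g in genes}, es, set(genes), stage="II",
            delta_beta={g: 0.4 for g in genes},
        )
        conserved, _ = propagate_conserved({"I": a, "II": b})
        assert conserved == set()

    def test_single_network_rejected(self):
        with pytest.raises(ValidationError):
            propagate_conserved({"I": self._clique_net()})

    def test_stage_without_size4_warns_empty(self, caplog):
        small = make_scored_network(
            [("M", "A")], {"M": 0.5, "A": 0.5}, {("M", "A"): 0.9}, {"M"}
        )
        conserved, supporting = propagate_conserved(
            {"I": self._clique_net(), "II": small}
        )
        assert conserved == set() and supporting == {}


class TestHubProfile:
    def test_star_center_is_hub_and_counts_sum(self):
        import pandas as pd

        edges = [("H", x) for x in ("A", "B", "C", "D")]
        ns = {g: 0.5 for g in "HABCD"}
        es = {e: 0.9 for e in edges}
        net = make_scored_network(edges, ns, es, {"H"}, delta_beta={"H": 0.3})
        sub = Subnetwork(
            stage="I", genes=("H", "A"), seed="H", strength=1.0,
            retained_edges=(("A", "H"),),
        )
        pathways = pd.DataFrame(
            [
                ("L1", "lung_cancer", "A"),
                ("O1", "other_cancer", "B"),
                ("signaling_pw_1", "other", "C"),
                ("metab_pw_1", "other", "D"),
            ],
            columns=["pathway_id", "class", "gene"],
        )
        hub, counts = hub_profile(sub, net, pathways)
        assert hub == "H"
        assert counts == {
            "lung_cancer": 1,
            "other_cancer": 1,
            "signaling": 1,
            "metabolic_other": 1,
        }
        assert sum(counts.values()) == net.graph.degree("H")
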