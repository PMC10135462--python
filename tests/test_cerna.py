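import itertools
import warnings

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from cerna_forge.cerna import (
    Triplet,
    assemble_network,
    build_mrna_mirna_pairs,
    canonicalize_mirna,
    consensus_lncrna_pairs,
    enumerate_triplets,
    prune_by_validation,
    rank_hubs,
    validate_interaction_table,
    write_edge_list,
)


def _table(edges, target_class="mRNA", db="db"):
    return pd.DataFrame(
        [(m, t, target_class, db) for m, t in edges],
        columns=["mirna_id", "target_id", "target_class", "source_db"],
    )


def _de(directions):
    return pd.DataFrame({"direction": list(directions.values())}, index=list(directions))


def _random_network(rng, n_mrna=5, n_mirna=4, n_lnc=5, p_edge=0.5):
    mrna_pairs, lnc_pairs = [], []
    for m in range(n_mirna):
        for g in range(n_mrna):
            if rng.random() < p_edge:
                mrna_pairs.append((f"hsa-miR-{m}", f"GENE{g}"))
        for l in range(n_lnc):
            if rng.random() < p_edge:
                lnc_pairs.append((f"hsa-miR-{m}", f"LNC{l}"))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return assemble_network(mrna_pairs, lnc_pairs), mrna_pairs, lnc_pairs


class TestCanonicalization:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("hsa-mir-455-3p", "hsa-miR-455-3p"),
            (" hsa-miR-31-5p ", "hsa-miR-31-5p"),
            ("HSA-MIR-142-5p", "HSA-miR-142-5p"),
        ],
    )
    def test_mir_infix_normalised(self, raw, expected):
        assert canonicalize_mirna(raw) == expected

    def test_duplicate_edges_dropped(self):
        t = _table([("hsa-mir-1", "A"), ("hsa-miR-1", "A"), ("hsa-miR-1", "B")])
        out = validate_interaction_table(t)
        assert len(out) == 2


class TestBuildPairs:
    def test_opposite_directions_kept(self):
        targets = _table([("m1", "G1"), ("m2", "G2"), ("m3", "G3")])
        de_m = _de({"G1": "up", "G2": "up", "G3": "ns"})
        de_mi = _de({"m1": "down", "m2": "up", "m3": "down"})
        pairs = build_mrna_mirna_pairs(targets, de_m, de_mi, ["G1", "G2", "G3"])
        assert pairs == [("m1", "G1")]  # same-direction and ns pairs dropped

    def test_specific_set_restricts(self):
        targets = _table([("m1", "G1"), ("m1", "G2")])
        de_m = _de({"G1": "up", "G2": "up"})
        de_mi = _de({"m1": "down"})
        pairs = build_mrna_mirna_pairs(targets, de_m, de_mi, ["G2"])
        assert pairs == [("m1", "G2")]

    def test_mirrored_polarity_behind_flag(self):
        targets = _table([("m1", "G1")])
        de_m = _de({"G1": "down"})
        de_mi = _de({"m1": "up"})
        assert build_mrna_mirna_pairs(targets, de_m, de_mi, ["G1"]) == []
        pairs = build_mrna_mirna_pairs(
            targets, de_m, de_mi, ["G1"], polarity="down-up-down"
        )
        assert pairs == [("m1", "G1")]

    def test_empty_table_warns(self):
        targets = _table([], target_class="mRNA")
        with pytest.warns(UserWarning, match="empty"):
            out = build_mrna_mirna_pairs(targets, _de({}), _de({}), [])
        assert out == []


class TestConsensus:
    def test_disjoint_tables_empty(self):
        db1 = _table([("m1", "L1")], "lncRNA")
        db2 = _table([("m1", "L2")], "lncRNA")
        assert consensus_lncrna_pairs(db1, db2, ["m1"]) == []

    def test_intersection_rule(self):
        db1 = _table([("m1", "L1"), ("m1", "L2")], "lncRNA")
        db2 = _table([("m1", "L2"), ("m1", "L3")], "lncRNA")
        assert consensus_lncrna_pairs(db1, db2, ["m1"]) == [("m1", "L2")]

    def test_mirna_restriction(self):
        db = _table([("m1", "L1"), ("m2", "L2")], "lncRNA")
        assert consensus_lncrna_pairs(db, db, ["m2"]) == [("m2", "L2")]


class TestAssemble:
    def test_continuity_rule_drops_mirnas_without_both_sides(self):
        with pytest.warns(UserWarning, match="no continuous"):
            net = assemble_network([("m1", "G1")], [])
        assert net.number_of_nodes() == 0

    def test_smallest_network(self):
        net = assemble_network([("m1", "G1")], [("m1", "L1")])
        assert net.number_of_nodes() == 3
        assert net.number_of_edges() == 2
        assert dict(net.degree()) == {"m1": 2, "G1": 1, "L1": 1}

    def test_orphans_removed_with_their_mirna(self):
        net = assemble_network(
            [("m1", "G1"), ("m2", "G2")], [("m1", "L1")]
        )
        assert "m2" not in net and "G2" not in net

    def test_class_bipartite_invariant(self, rng):
        net, _, _ = _random_network(rng)
        for a, b in net.edges():
            classes = {net.nodes[a]["node_class"], net.nodes[b]["node_class"]}
            assert "miRNA" in classes and len(classes) == 2

    def test_matches_brute_force_assembler(self, rng):
        for _ in range(20):
            net, mrna_pairs, lnc_pairs = _random_network(rng)
            keep = {m for m, _ in mrna_pairs} & {m for m, _ in lnc_pairs}
            exp_edges = {
                frozenset(p) for p in mrna_pairs if p[0] in keep
            } | {frozenset(p) for p in lnc_pairs if p[0] in keep}
            assert {frozenset(e) for e in net.edges()} == exp_edges


class TestTriplets:
    def test_two_by_two_product(self):
        net = assemble_network(
            [("m1", "G1"), ("m1", "G2")], [("m1", "L1"), ("m1", "L2")]
        )
        assert len(enumerate_triplets(net)) == 4

    def test_no_lncrna_no_triplets(self):
        with pytest.warns(UserWarning):
            net = assemble_network([("m1", "G1")], [])
        assert enumerate_triplets(net) == []

    def test_matches_brute_force_triple_loop(self, rng):
        for _ in range(30):
            net, _, _ = _random_network(rng)
            nodes = dict(net.nodes(data=True))
            brute = set()
            for g, mi, l in itertools.product(nodes, nodes, nodes):
                if (
                    nodes[g]["node_class"] == "mRNA"
                    and nodes[mi]["node_class"] == "miRNA"
                    and nodes[l]["node_class"] == "lncRNA"
                    and net.has_edge(g, mi)
                    and net.has_edge(mi, l)
                ):
                    brute.add((g, mi, l))
            mine = {(t.mrna, t.mirna, t.lncrna) for t in enumerate_triplets(net)}
            assert mine == brute


class TestHubs:
    def test_star_graph_hub(self):
        net = assemble_network(
            [("m1", f"G{i}") for i in range(4)], [("m1", f"L{i}") for i in range(4)]
        )
        hubs = rank_hubs(net, 1)
        assert hubs.ranked[0][0] == "m1"

    def test_tie_broken_lexicographically(self):
        net = assemble_network([("m1", "G1")], [("m1", "L1")])
        hubs = rank_hubs(net, 2)
        assert [n for n, _ in hubs.ranked] == ["m1", "G1"]  # G1 before L1 at degree 1

    def test_k_exceeding_nodes_warns(self):
        net = assemble_network([("m1", "G1")], [("m1", "L1")])
        with pytest.warns(UserWarning, match="exceeds"):
            hubs = rank_hubs(net, 10)
        assert len(hubs.ranked) == 3

    def test_matches_brute_force_sort(self, rng):
        for _ in range(30):
            net, _, _ = _random_network(rng, n_mrna=8, n_mirna=6, n_lnc=8)
            if net.number_of_nodes() == 0:
                continue
            hubs = rank_hubs(net, min(15, net.number_of_nodes()))
            brute = sorted(net.degree(), key=lambda kv: (-kv[1], kv[0]))
            assert hubs.ranked == [(n, int(d)) for n, d in brute[: len(hubs.ranked)]]
            assert set(hubs.subnetwork.edges()) <= set(net.edges())


class TestPruning:
    def _hub_fixture(self):
        mrna_pairs = [("m1", "G1"), ("m2", "G1"), ("m3", "G2"), ("m4", "G2"), ("m5", "G3")]
        lnc_pairs = [
            ("m1", "L1"), ("m2", "L2"), ("m3", "L3"), ("m4", "L4"), ("m5", "L5"),
            ("m1", "L2"), ("m2", "L3"),
        ]
        net = assemble_network(mrna_pairs, lnc_pairs)
        return rank_hubs(net, net.number_of_nodes())

    def test_five_lncrnas_three_up_retained(self):
        hubs = self._hub_fixture()
        directions = {"L1": "up", "L2": "up", "L3": "up", "L4": "down", "L5": "ns"}
        pruned, triplets = prune_by_validation(hubs, directions)
        lncs = [
            n for n, d in pruned.subnetwork.nodes(data=True)
            if d["node_class"] == "lncRNA"
        ]
        assert sorted(lncs) == ["L1", "L2", "L3"]
        assert all(t.lncrna in {"L1", "L2", "L3"} for t in triplets)

    def test_all_ns_removes_everything(self):
        hubs = self._hub_fixture()
        directions = {f"L{i}": "ns" for i in range(1, 6)}
        pruned, triplets = prune_by_validation(hubs, directions)
        assert triplets == []
        lncs = [
            n for n, d in pruned.subnetwork.nodes(data=True)
            if d["node_class"] == "lncRNA"
        ]
        assert lncs == []

    def test_missing_direction_named(self):
        hubs = self._hub_fixture()
        with pytest.raises(ValueError, match="L5"):
            prune_by_validation(hubs, {f"L{i}": "up" for i in range(1, 5)})

    def test_pruning_never_adds_edges(self):
        hubs = self._hub_fixture()
        directions = {"L1": "up", "L2": "down", "L3": "up", "L4": "ns", "L5": "up"}
        pruned, _ = prune_by_validation(hubs, directions)
        assert set(pruned.subnetwork.edges()) <= set(hubs.subnetwork.edges())
        assert set(pruned.subnetwork.nodes()) <= set(hubs.subnetwork.nodes())


class TestExport:
    def test_edge_list_round_trip(self, tmp_path):
        net = assemble_network([("m1", "G1")], [("m1", "L1")])
        write_edge_list(net, tmp_path / "e.tsv")
        df = pd.read_csv(tmp_path / "e.tsv", sep="\t")
        assert len(df) == 2
        assert set(df["class_a"]) == {"miRNA"}
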