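"""Interactome loading, BFS distances, degree binning, set restriction."""

import networkx as nx
import numpy as np
import pytest

from herbnet.network import (
    build_degree_bins,
    load_edge_list,
    neighbors,
    restrict_to_network,
    shortest_path_lengths,
    write_edge_list,
)
from herbnet.weighting import WeightedProteinSet

from conftest import floyd_warshall, net_from_edges


def write_tsv(path, rows):
    path.write_text("".join(f"{a}\t{b}\n" for a, b in rows))


class TestLoadEdgeList:
    def test_duplicate_edges_merged(self, tmp_path):
        p = tmp_path / "e.tsv"
        write_tsv(p, [("A", "B"), ("B", "A"), ("B", "C")])
        net = load_edge_list(p)
        assert net.n_nodes == 3 and net.n_edges == 2

    def test_id_mapping_collapses_to_mapped_multigraph(self, tmp_path):
        # map {1->A, 2->B, 3->A}: (1,2)->(A,B); (2,3)->(B,A) merges with (A,B)
        e, m = tmp_path / "e.tsv", tmp_path / "m.tsv"
        write_tsv(e, [("1", "2"), ("2", "3")])
        write_tsv(m, [("1", "A"), ("2", "B"), ("3", "A")])
        net = load_edge_list(e, id_map=m)
        assert net.nodes == {"A", "B"}
        assert net.n_edges == 1

    def test_self_loop_dropped_node_kept(self, tmp_path):
        p = tmp_path / "e.tsv"
        write_tsv(p, [("A", "A"), ("A", "B")])
        net = load_edge_list(p)
        assert net.nodes == {"A", "B"} and net.n_edges == 1

    def test_malformed_row_reports_line_number(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("A\tB\nA\tB\tC\n")
        with pytest.raises(ValueError, match="line 2"):
            load_edge_list(p)

    def test_empty_network_is_an_error(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("# only comments\n")
        with pytest.raises(ValueError):
            load_edge_list(p)

    def test_unmapped_rows_dropped(self, tmp_path):
        e, m = tmp_path / "e.tsv", tmp_path / "m.tsv"
        write_tsv(e, [("1", "2"), ("2", "9")])
        write_tsv(m, [("1", "A"), ("2", "B")])
        net = load_edge_list(e, id_map=m)
        assert net.nodes == {"A", "B"} and net.n_edges == 1

    def test_roundtrip_is_idempotent(self, tmp_path, random_net_factory):
        net = random_net_factory(25, 0.15, seed=7)
        out1, out2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_edge_list(net, out1)
        reloaded = load_edge_list(out1)
        write_edge_list(reloaded, out2)
        assert out1.read_text() == out2.read_text()
        assert reloaded.nodes >= {n for n, d in net.degree_index.items() if d > 0}


class TestShortestPaths:
    def test_path_graph_end_to_end(self, path_net):
        table = shortest_path_lengths(path_net, {"A"}, {"D"})
        assert table.get("A", "D") == 3

    def test_self_distance_zero(self, path_net):
        assert shortest_path_lengths(path_net, {"B"}, {"B"}).get("B", "B") == 0

    def test_unreachable_is_marker_not_number(self):
        net = net_from_edges([("A", "B"), ("X", "Y")])
        table = shortest_path_lengths(net, {"A"}, {"Y"})
        assert table.get("A", "Y") is None

    def test_empty_sets_rejected(self, path_net):
        with pytest.raises(ValueError):
            shortest_path_lengths(path_net, set(), {"A"})

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_floyd_warshall(self, random_net_factory, seed):
        net = random_net_factory(30, 0.1, seed=seed)
        order, ref = floyd_warshall(net)
        table = shortest_path_lengths(net, set(order), set(order))
        for i, s in enumerate(order):
            for j, t in enumerate(order):
                got = table.get(s, t)
                expected = ref[i, j]
                if np.isinf(expected):
                    assert got is None
                else:
                    assert got == int(expected)


class TestNeighbors:
    def test_path_interior(self, path_net):
        assert neighbors(path_net, {"B"}) == {"A", "C"}

    def test_star_center(self):
        net = net_from_edges([("h", f"l{i}") for i in range(5)])
        assert neighbors(net, {"h"}) == {f"l{i}" for i in range(5)}

    def test_empty_set(self, path_net):
        assert neighbors(path_net, set()) == set()


class TestDegreeBins:
    def test_single_degree_class_single_bin(self):
        net = net_from_edges(
            [(f"c{i}", f"c{(i + 1) % 8}") for i in range(8)]
        )  # cycle: all degree 2
        bins = build_degree_bins(net, min_bin_size=1)
        assert len(bins.members) == 1
        assert set(bins.members[0]) == net.nodes

    def test_two_degree_classes_split(self):
        # 100 nodes of degree 2 (cycles) + hubs of high degree
        g = nx.Graph()
        for c in range(10):
            nodes = [f"c{c}_{i}" for i in range(10)]
            g.add_edges_from(zip(nodes, nodes[1:] + nodes[:1]))
        hubs = [f"hub{i}" for i in range(12)]
        for h in hubs:  # connect hubs to all cycle nodes of one cycle group
            g.add_edges_from((h, f"c{c}_{i}") for c in range(5) for i in range(10))
        from herbnet.network import InteractionNetwork

        net = InteractionNetwork(g)
        bins = build_degree_bins(net, min_bin_size=10)
        hub_bins = {bins.bin_of[h] for h in hubs}
        low_bins = {bins.bin_of[f"c{6}_{i}"] for i in range(10)}
        assert hub_bins.isdisjoint(low_bins)

    def test_min_bin_size_equal_to_network_gives_one_bin(self, random_net_factory):
        net = random_net_factory(20, 0.2, seed=3)
        bins = build_degree_bins(net, min_bin_size=net.n_nodes)
        assert len(bins.members) == 1

    def test_oversized_min_bin_size_rejected(self, path_net):
        with pytest.raises(ValueError):
            build_degree_bins(path_net, min_bin_size=10)

    @pytest.mark.parametrize("seed", range(3))
    def test_partition_properties(self, random_net_factory, seed):
        net = random_net_factory(60, 0.1, seed=seed)
        bins = build_degree_bins(net, min_bin_size=5)
        union = set()
        for members in bins.members:
            assert len(members) >= 5
            assert union.isdisjoint(members)
            union.update(members)
        assert union == net.nodes
        assert set(bins.bin_of) == net.nodes


class TestRestrictToNetwork:
    def test_outside_members_dropped_and_counted(self, path_net):
        S = WeightedProteinSet({"A": 0.5, "X": 0.9})
        kept, dropped = restrict_to_network(path_net, S)
        assert kept.weights == {"A": 0.5} and dropped == 1

    def test_inside_set_unchanged(self, path_net):
        S = WeightedProteinSet({"A": 0.5, "B": 1.0})
        kept, dropped = restrict_to_network(path_net, S)
        assert kept.weights == S.weights and dropped == 0

    def test_disjoint_set_is_error(self, path_net):
        with pytest.raises(ValueError):
            restrict_to_network(path_net, WeightedProteinSet({"X": 1.0}))
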