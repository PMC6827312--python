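"""SSN construction, components, threshold scan refinement, metanode contraction."""

import random

import pytest

from ssnfam.network import (
    DEFAULT_GRID,
    NetworkError,
    Partition,
    SSNGraph,
    build_graph,
    connected_components,
    contract_metanodes,
    threshold_scan,
    write_edge_list,
    write_graphml,
    write_partition,
)
from ssnfam.pairwise import HitTable, PairwiseHit

from .conftest import truth_blocks
from .oracles import bfs_components


def make_hits(pairs):
    """pairs: iterable of (a, b, evalue)."""
    t = HitTable()
    for a, b, e in pairs:
        t.add(PairwiseHit(a, b, e, 100.0, 50.0, 100))
    return t


def components_of(partition):
    return set(partition.clusters.values())


class TestBuildGraph:
    def test_edges_filtered_by_threshold(self):
        hits = make_hits([("A", "B", 1e-60), ("B", "C", 1e-30)])
        g = build_graph(hits, {"A", "B", "C"}, 1e-55)
        assert set(map(frozenset, g.graph.edges)) == {frozenset({"A", "B"})}
        assert components_of(connected_components(g)) == {
            frozenset({"A", "B"}),
            frozenset({"C"}),
        }

    def test_looser_threshold_joins_chain(self):
        hits = make_hits([("A", "B", 1e-60), ("B", "C", 1e-30)])
        g = build_graph(hits, {"A", "B", "C"}, 1e-25)
        assert len(connected_components(g)) == 1

    def test_isolated_nodes_retained(self):
        g = build_graph(HitTable(), {f"n{i}" for i in range(5)}, 1e-5)
        part = connected_components(g)
        assert len(part) == 5 and all(len(c) == 1 for c in part.clusters.values())

    def test_unknown_node_in_hits_rejected(self):
        hits = make_hits([("A", "B", 1e-60)])
        with pytest.raises(NetworkError):
            build_graph(hits, {"A"}, 1e-5)

    def test_threshold_inclusive_at_grid_value(self):
        hits = make_hits([("A", "B", 1e-55)])
        g = build_graph(hits, {"A", "B"}, 1e-55)
        assert g.n_edges == 1


class TestConnectedComponents:
    def test_path_graph_single_cluster(self):
        hits = make_hits([("A", "B", 1e-10), ("B", "C", 1e-10)])
        part = connected_components(build_graph(hits, {"A", "B", "C"}, 1e-5))
        assert components_of(part) == {frozenset({"A", "B", "C"})}

    def test_empty_graph_empty_partition(self):
        part = connected_components(build_graph(HitTable(), set(), 1e-5))
        assert len(part) == 0

    def test_cluster_ids_deterministic_by_size_then_member(self):
        hits = make_hits([("x1", "x2", 1e-10), ("a1", "a2", 1e-10), ("a2", "a3", 1e-10)])
        part = connected_components(
            build_graph(hits, {"x1", "x2", "a1", "a2", "a3"}, 1e-5)
        )
        assert part.clusters[1] == frozenset({"a1", "a2", "a3"})
        assert part.clusters[2] == frozenset({"x1", "x2"})

    def test_agrees_with_bfs_oracle_on_random_graphs(self):
        rng = random.Random(99)
        for _ in range(100):
            n = rng.randint(2, 50)
            nodes = [f"v{i:02d}" for i in range(n)]
            edges = []
            for i in range(n):
                for j in range(i + 1, n):
                    if rng.random() < 0.06:
                        edges.append((nodes[i], nodes[j]))
            hits = make_hits([(a, b, 1e-10) for a, b in edges])
            part = connected_components(build_graph(hits, nodes, 1e-5))
            assert components_of(part) == bfs_components(nodes, edges)


class TestThresholdScan:
    def test_default_grid_has_24_partitions(self):
        hits = make_hits([("A", "B", 1e-60)])
        scan = threshold_scan(hits, {"A", "B"})
        assert len(scan.thresholds) == 24
        assert scan.thresholds[0] == pytest.approx(1e-5)
        assert scan.thresholds[-1] == pytest.approx(1e-120)
        assert len(scan.partitions) == 24

    def test_non_monotone_grid_rejected(self):
        with pytest.raises(NetworkError):
            threshold_scan(HitTable(), {"A"}, thresholds=(1e-10, 1e-5))

    def test_five_family_fixture_refines_to_truth_plateau(self, five_family_bundle):
        records, truth, hits = five_family_bundle
        scan = threshold_scan(hits, [r.id for r in records])
        counts = [len(p) for p in scan.partitions]
        assert counts[0] == 1
        assert max(counts) >= 5
        assert all(c1 <= c2 for c1, c2 in zip(counts, counts[1:]))
        # truth partition appears on a contiguous window of the grid
        truth_parts = truth_blocks(truth)
        matches = [components_of(p) == truth_parts for p in scan.partitions]
        assert any(matches)
        first, last = matches.index(True), len(matches) - matches[::-1].index(True)
        assert all(matches[first:last])

    def test_every_cluster_refines_exactly_one_parent(self, five_family_bundle):
        records, _, hits = five_family_bundle
        scan = threshold_scan(hits, [r.id for r in records])
        for i in range(1, len(scan.thresholds)):
            parent_clusters = scan.partitions[i - 1].clusters
            for cid, members in scan.partitions[i].clusters.items():
                parents = {
                    pid
                    for pid, pmembers in parent_clusters.items()
                    if members & pmembers
                }
                assert len(parents) == 1
                assert members <= parent_clusters[parents.pop()]
                assert scan.parents[i][cid] in parent_clusters

    def test_scan_table_is_long_format_with_lineage(self):
        hits = make_hits([("A", "B", 1e-60), ("B", "C", 1e-30)])
        scan = threshold_scan(hits, {"A", "B", "C"}, thresholds=(1e-25, 1e-55))
        table = scan.to_table()
        assert list(table.columns) == ["threshold", "cluster", "size", "parent_cluster"]
        assert table[table.threshold == 1e-25]["size"].sum() == 3
        assert table[table.threshold == 1e-55]["size"].sum() == 3


class TestMetanodes:
    def test_tight_triangle_contracts_to_single_metanode(self):
        hits = make_hits(
            [("A", "B", 1e-90), ("B", "C", 1e-92), ("A", "C", 1e-95)]
        )
        g = build_graph(hits, {"A", "B", "C"}, 1e-55)
        meta = contract_metanodes(g, 1e-85)
        assert set(meta.graph.nodes) == {"A"}
        assert meta.graph.nodes["A"]["size"] == 3
        assert meta.n_edges == 0

    def test_chain_partially_contracts(self):
        hits = make_hits([("A", "B", 1e-90), ("B", "C", 1e-60)])
        g = build_graph(hits, {"A", "B", "C"}, 1e-55)
        meta = contract_metanodes(g, 1e-85)
        assert set(meta.graph.nodes) == {"A", "C"}
        assert meta.graph.nodes["A"]["size"] == 2
        assert meta.n_edges == 1

    def test_merge_looser_than_display_rejected(self):
        g = build_graph(make_hits([]), {"A"}, 1e-55)
        with pytest.raises(NetworkError):
            contract_metanodes(g, 1e-25)

    def test_contraction_preserves_component_count_random_graphs(self):
        rng = random.Random(7)
        for _ in range(100):
            n = rng.randint(2, 40)
            nodes = [f"v{i:02d}" for i in range(n)]
            pairs = []
            for i in range(n):
                for j in range(i + 1, n):
                    if rng.random() < 0.08:
                        e = 10.0 ** (-rng.uniform(5, 120))
                        pairs.append((nodes[i], nodes[j], e))
            display = 10.0 ** (-rng.uniform(5, 60))
            merge = display * 10.0 ** (-rng.uniform(0, 60))
            g = build_graph(make_hits(pairs), nodes, display)
            meta = contract_metanodes(g, merge)
            n_before = len(connected_components(g))
            n_after = len(connected_components(meta))
            assert n_before == n_after


class TestExports:
    def test_outputs_deterministic(self, tmp_path):
        hits = make_hits([("A", "B", 1e-60), ("B", "C", 1e-30)])
        g = build_graph(hits, {"A", "B", "C"}, 1e-25)
        part = connected_components(g)
        files = {}
        for name, writer, arg in [
            ("edges.tsv", write_edge_list, g),
            ("part.tsv", write_partition, part),
            ("g.graphml", write_graphml, g),
        ]:
            p1, p2 = tmp_path / ("1" + name), tmp_path / ("2" + name)
            writer(arg, p1)
            writer(arg, p2)
            assert p1.read_bytes() == p2.read_bytes()
            files[name] = p1
        assert "source\ttarget\tevalue" in files["edges.tsv"].read_text()
        assert files["part.tsv"].read_text().startswith("id\tthreshold\tcluster")
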