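"""Cluster map: edges, component calling vs brute force, novelty/outlier
criteria, force layout, CLANS round-trip."""

import itertools

import numpy as np
import pytest

from famscape.clustermap import (
    ClansParseError,
    Edge,
    EdgeList,
    allvsall_edges,
    connected_clusters,
    detect_novel_and_outliers,
    force_layout,
    read_clans,
    write_clans,
)
from famscape.records import SequenceRecord
from famscape.alphabet import decode, random_sequence

from .reference import transitive_clusters


def random_edgelist(rng, n_nodes: int, p_edge: float = 0.3) -> EdgeList:
    nodes = [f"n{i}" for i in range(n_nodes)]
    edges = []
    for i, j in itertools.combinations(range(n_nodes), 2):
        if rng.random() < p_edge:
            edges.append(Edge(nodes[i], nodes[j], 10.0, 1e-12, 10 ** -rng.uniform(1, 15)))
    return EdgeList(nodes=nodes, edges=edges)


class TestEdgeList:
    def test_self_edges_rejected(self):
        with pytest.raises(ValueError):
            EdgeList(nodes=["a"], edges=[Edge("a", "a", 1, 1e-3, 1e-3)])

    def test_duplicate_edges_rejected(self):
        with pytest.raises(ValueError):
            EdgeList(
                nodes=["a", "b"],
                edges=[Edge("a", "b", 1, 1e-3, 1e-3), Edge("b", "a", 1, 1e-3, 1e-3)],
            )

    def test_allvsall_identical_pair_and_bound(self, params, ka200):
        seq = decode(random_sequence(np.random.default_rng(0), 120))
        recs = [SequenceRecord("a", seq), SequenceRecord("b", seq), SequenceRecord("c", seq)]
        edges = allvsall_edges(recs, params, ka200, p_keep=0.1)
        assert len(edges.edges) <= 3  # n(n-1)/2 bound
        assert len(edges.edges) == 3  # identical sequences all connect
        assert all(e.p_value < 1e-10 for e in edges.edges)


class TestConnectedClusters:
    def test_chain_is_transitively_one_cluster(self):
        edges = EdgeList(
            nodes=["a", "b", "c"],
            edges=[Edge("a", "b", 1, 1e-12, 1e-12), Edge("b", "c", 1, 1e-12, 1e-12)],
        )
        assignment = connected_clusters(edges, p_cutoff=1e-10, min_size=3)
        assert assignment == {"a": 0, "b": 0, "c": 0}

    def test_min_size_suppresses_small_components(self):
        edges = EdgeList(
            nodes=["a", "b", "c"],
            edges=[Edge("a", "b", 1, 1e-12, 1e-12), Edge("b", "c", 1, 1e-12, 1e-12)],
        )
        assignment = connected_clusters(edges, p_cutoff=1e-10, min_size=10)
        assert all(c is None for c in assignment.values())

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_transitive_closure_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 13))
        edges = random_edgelist(rng, n)
        cutoff = 10 ** -rng.uniform(2, 12)
        assignment = connected_clusters(edges, cutoff, min_size=1)
        links = {(e.i, e.j) for e in edges.edges if e.p_value <= cutoff}
        expected = transitive_clusters(edges.nodes, links)
        got = {}
        for node, c in assignment.items():
            got.setdefault(c, set()).add(node)
        assert {frozenset(g) for g in got.values()} == set(expected)

    def test_cluster_ids_ordered_by_size_then_member(self):
        edges = EdgeList(
            nodes=["z", "y", "a", "b", "c"],
            edges=[
                Edge("z", "y", 1, 1e-12, 1e-12),
                Edge("a", "b", 1, 1e-12, 1e-12),
                Edge("b", "c", 1, 1e-12, 1e-12),
            ],
        )
        assignment = connected_clusters(edges, 1e-10, min_size=2)
        assert assignment["a"] == assignment["b"] == assignment["c"] == 0
        assert assignment["z"] == assignment["y"] == 1

    def test_invalid_cutoff_rejected(self):
        with pytest.raises(ValueError):
            connected_clusters(EdgeList(nodes=["a"]), p_cutoff=0.0)


class TestNovelAndOutliers:
    def _simple_map(self):
        nodes = [f"m{i}" for i in range(10)] + [f"u{i}" for i in range(10)] + ["lone"]
        edges = []
        for a, b in itertools.combinations(range(10), 2):
            edges.append(Edge(f"m{a}", f"m{b}", 1, 1e-12, 1e-12))
            edges.append(Edge(f"u{a}", f"u{b}", 1, 1e-12, 1e-12))
        return EdgeList(nodes=nodes, edges=edges)

    def test_seeded_cluster_not_novel_unseeded_cluster_novel(self):
        edges = self._simple_map()
        assignment = connected_clusters(edges, 1e-10, min_size=10)
        seed_membership = {n: ("m0" if n == "m0" else None) for n in edges.nodes}
        novel, outliers = detect_novel_and_outliers(
            assignment, edges, seed_membership, 1e-10
        )
        seeded_cluster = assignment["m0"]
        unseeded_cluster = assignment["u0"]
        assert novel[seeded_cluster] is False
        assert novel[unseeded_cluster] is True

    def test_isolated_node_is_outlier(self):
        edges = self._simple_map()
        assignment = connected_clusters(edges, 1e-10, min_size=10)
        _, outliers = detect_novel_and_outliers(
            assignment, edges, {n: None for n in edges.nodes}, 1e-10
        )
        assert outliers == {"lone"}

    def test_linked_noise_node_not_outlier_at_zero_fraction(self):
        nodes = [f"m{i}" for i in range(10)] + ["halo"]
        edges = [
            Edge(f"m{a}", f"m{b}", 1, 1e-12, 1e-12)
            for a, b in itertools.combinations(range(10), 2)
        ]
        edges.append(Edge("halo", "m0", 1, 1e-12, 1e-12))
        el = EdgeList(nodes=nodes, edges=edges)
        assignment = connected_clusters(el, 1e-10, min_size=10)
        # halo joins the component, so force it to noise via a higher cutoff graph
        assignment["halo"] = None
        _, outliers = detect_novel_and_outliers(
            assignment, el, {n: None for n in nodes}, 1e-10, max_link_fraction=0.0
        )
        assert "halo" not in outliers


class TestForceLayout:
    def test_single_node(self):
        coords = force_layout(EdgeList(nodes=["a"]), rng_seed=1)
        assert set(coords) == {"a"}

    def test_deterministic_under_seed(self, rng):
        edges = random_edgelist(rng, 8)
        c1 = force_layout(edges, rng_seed=5)
        c2 = force_layout(edges, rng_seed=5)
        assert c1 == c2

    def test_two_planted_clusters_separate(self):
        nodes = [f"a{i}" for i in range(8)] + [f"b{i}" for i in range(8)]
        edges = []
        for x, y in itertools.combinations(range(8), 2):
            edges.append(Edge(f"a{x}", f"a{y}", 1, 1e-20, 1e-20))
            edges.append(Edge(f"b{x}", f"b{y}", 1, 1e-20, 1e-20))
        el = EdgeList(nodes=nodes, edges=edges)
        coords = force_layout(el, rng_seed=2)
        pts = {n: np.array(c) for n, c in coords.items()}
        intra, inter = [], []
        for u, v in itertools.combinations(nodes, 2):
            d = np.linalg.norm(pts[u] - pts[v])
            (intra if u[0] == v[0] else inter).append(d)
        assert np.mean(intra) < 0.5 * np.mean(inter)


class TestClansRoundTrip:
    def _fixture_map(self, rng):
        recs = [
            SequenceRecord(f"r{i}", decode(random_sequence(rng, 40)), family=f"f{i%2}")
            for i in range(6)
        ]
        edges = EdgeList(
            nodes=[r.id for r in recs],
            edges=[
                Edge("r0", "r1", 12.0, 1e-8, 1e-8),
                Edge("r2", "r5", 30.0, 1e-22, 1e-22),
            ],
        )
        coords = {r.id: (float(rng.random()), float(rng.random())) for r in recs}
        return recs, edges, coords

    def test_round_trip_exact(self, rng, tmp_path):
        recs, edges, coords = self._fixture_map(rng)
        path = tmp_path / "map.clans"
        write_clans(recs, edges, coords, path)
        recs2, edges2, coords2 = read_clans(path)
        assert [(r.id, r.seq, r.family) for r in recs2] == [
            (r.id, r.seq, r.family) for r in recs
        ]
        assert {(e.i, e.j, e.p_value) for e in edges2.edges} == {
            (e.i, e.j, e.p_value) for e in edges.edges
        }
        for rid in coords:
            assert coords2[rid] == pytest.approx(coords[rid], abs=1e-9)

    def test_empty_edge_set_valid(self, rng, tmp_path):
        recs, _, coords = self._fixture_map(rng)
        path = tmp_path / "empty.clans"
        write_clans(recs, EdgeList(nodes=[r.id for r in recs]), coords, path)
        _, edges2, _ = read_clans(path)
        assert edges2.edges == []

    def test_parse_errors_name_the_block(self, tmp_path):
        bad = tmp_path / "bad.clans"
        bad.write_text("sequences=1\n<seq>\n>a\nACDE\n</seq>\n<pos>\nnot a pos line\n</pos>\n<hsp>\n</hsp>\n")
        with pytest.raises(ClansParseError, match="pos"):
            read_clans(bad)
        bad.write_text("nonsense\n")
        with pytest.raises(ClansParseError, match="sequences"):
            read_clans(bad)

    def test_header_count_mismatch_detected(self, tmp_path):
        bad = tmp_path / "bad.clans"
        bad.write_text("sequences=2\n<seq>\n>a\nACDE\n</seq>\n<pos>\n0 0.0 0.0 0.0\n</pos>\n<hsp>\n</hsp>\n")
        with pytest.raises(ClansParseError, match="seq"):
            read_clans(bad)
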