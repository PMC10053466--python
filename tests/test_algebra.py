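"""Union / intersection / high-confidence merging, topology and sub-networks."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import mogrn
from conftest import make_edges, make_matrix
from mogrn.algebra import (
    build_high_confidence,
    extract_subnetwork,
    intersect_networks,
    tissue_specific_subgrn,
    topology_metrics,
    union_networks,
)
from mogrn.atlas import detect_segs
from oracles import graph_metrics_bruteforce


def _random_edge_lists(rng, n_lists=6, n_edges=100):
    regulators = [f"tf{i}" for i in range(10)]
    targets = [f"g{i}" for i in range(60)]
    lists = []
    for _ in range(n_lists):
        pairs = set()
        while len(pairs) < n_edges:
            pairs.add((rng.choice(regulators), rng.choice(targets)))
        rows = [(r, t, float(rng.uniform(0.01, 1.0))) for r, t in sorted(pairs)]
        lists.append(make_edges(rows))
    return lists


class TestUnionIntersect:
    def test_union_of_disjoint_lists(self):
        u = union_networks([make_edges([("a", "x", 0.2)]), make_edges([("b", "y", 0.3)])])
        assert u.pairs == {("a", "x"), ("b", "y")}

    def test_union_weight_rules(self):
        lists = [make_edges([("a", "x", 0.2)]), make_edges([("a", "x", 0.5)]),
                 make_edges([("a", "x", 0.2)])]
        assert union_networks(lists, "max").edges["weight"].iloc[0] == pytest.approx(0.5)
        assert union_networks(lists, "mean").edges["weight"].iloc[0] == pytest.approx(0.3)

    def test_union_cardinality_matches_set_enumeration(self):
        rng = np.random.default_rng(42)
        lists = _random_edge_lists(rng)
        u = union_networks(lists)
        expected = set().union(*[el.pairs for el in lists])
        assert u.pairs == frozenset(expected)
        assert len(u) == len(expected)

    def test_union_provenance_flags(self):
        a = make_edges([("a", "x", 0.2)], grn_type="mm", source="mean")
        b = make_edges([("a", "x", 0.5), ("b", "y", 0.1)], grn_type="Tm", source="mean")
        u = union_networks([a, b])
        row = u.edges.set_index(["regulator", "target"])
        assert bool(row.loc[("a", "x"), "in_mm_mean"]) is True
        assert bool(row.loc[("b", "y"), "in_mm_mean"]) is False
        assert bool(row.loc[("b", "y"), "in_Tm_mean"]) is True

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            union_networks([])
        with pytest.raises(ValueError):
            intersect_networks([])

    def test_intersection_identity_and_disjoint(self):
        a = make_edges([("a", "x", 0.2), ("b", "y", 0.4)])
        assert intersect_networks([a, a]).pairs == a.pairs
        b = make_edges([("c", "z", 0.9)])
        with pytest.warns(UserWarning):
            assert len(intersect_networks([a, b])) == 0

    def test_three_way_intersection(self):
        base = [("a", "x", 0.2), ("b", "y", 0.4)]
        lists = [
            make_edges(base + [("c", "z", 0.1)]),
            make_edges(base + [("d", "w", 0.3)]),
            make_edges(base + [("e", "v", 0.6)]),
        ]
        inter = intersect_networks(lists)
        assert inter.pairs == {("a", "x"), ("b", "y")}
        # weight is the mean of member weights (identical here)
        assert np.allclose(sorted(inter.edges["weight"]), [0.2, 0.4])

    def test_set_algebra_invariants(self):
        rng = np.random.default_rng(7)
        a, b = _random_edge_lists(rng, n_lists=2, n_edges=50)
        u = union_networks([a, b])
        i = intersect_networks([a, b])
        assert a.pairs <= u.pairs and b.pairs <= u.pairs
        assert i.pairs <= a.pairs and i.pairs <= b.pairs
        assert len(u) <= len(a) + len(b)
        assert len(u) == len(a) + len(b) - len(i)


class TestHighConfidence:
    def _suite(self, pairs_by_type):
        return {t: make_edges([(r, g, 0.5) for r, g in pairs], grn_type=t)
                for t, pairs in pairs_by_type.items()}

    def test_per_source_intersection_then_cross_source_union(self):
        mean = self._suite({
            "mm": [("a", "x"), ("b", "y"), ("c", "z")],
            "TT": [("a", "x"), ("b", "y")],
            "Tm": [("a", "x"), ("b", "y"), ("d", "w")],
        })
        bulked = self._suite({
            "mm": [("b", "y"), ("e", "v")],
            "TT": [("b", "y"), ("e", "v")],
            "Tm": [("b", "y"), ("e", "v"), ("f", "u")],
        })
        hc = build_high_confidence(mean, bulked)
        assert hc.pairs == {("a", "x"), ("b", "y"), ("e", "v")}

    def test_missing_suite_member_errors(self):
        suite = self._suite({"mm": [("a", "x")], "TT": [("a", "x")]})
        with pytest.raises(ValueError):
            build_high_confidence(suite, suite)

    def test_high_confidence_subset_of_union(self):
        rng = np.random.default_rng(3)
        lists = _random_edge_lists(rng, n_lists=6, n_edges=80)
        mean = dict(zip(("mm", "TT", "Tm"), lists[:3]))
        bulked = dict(zip(("mm", "TT", "Tm"), lists[3:]))
        union = union_networks(lists)
        hc = build_high_confidence(mean, bulked)
        assert hc.pairs <= union.pairs


class TestTopology:
    def test_triangle(self):
        report = topology_metrics(make_edges([("a", "b", 1), ("b", "c", 1), ("a", "c", 1)]),
                                  min_nodes=3)
        assert report.transitivity == pytest.approx(1.0)
        assert report.average_path_length == pytest.approx(1.0)
        assert report.module_count == 1

    def test_path(self):
        report = topology_metrics(make_edges([("a", "b", 1), ("b", "c", 1)]), min_nodes=5)
        assert report.transitivity == pytest.approx(0.0)
        assert report.average_path_length == pytest.approx(4 / 3)
        assert report.module_count == 0

    def test_two_cliques_module_count(self):
        edges = []
        for prefix in ("p", "q"):
            nodes = [f"{prefix}{i}" for i in range(5)]
            for i, u in enumerate(nodes):
                for v in nodes[i + 1:]:
                    edges.append((u, v, 1.0))
        report = topology_metrics(make_edges(edges), min_nodes=5)
        assert report.module_count == 2
        assert report.transitivity == pytest.approx(1.0)

    @pytest.mark.parametrize("case_seed", range(40))
    def test_matches_bruteforce_on_small_graphs(self, case_seed):
        rng = np.random.default_rng(2000 + case_seed)
        n = int(rng.integers(3, 9))
        nodes = [f"n{i}" for i in range(n)]
        edges = []
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < 0.4:
                    edges.append((nodes[i], nodes[j]))
        if not edges:
            edges = [(nodes[0], nodes[1])]
        report = topology_metrics(make_edges([(u, v, 1.0) for u, v in edges]), min_nodes=3)
        oracle = graph_metrics_bruteforce(edges, min_nodes=3)
        assert report.transitivity == pytest.approx(oracle["transitivity"], abs=1e-12)
        assert report.average_path_length == pytest.approx(
            oracle["average_path_length"], abs=1e-12)
        assert report.module_count == oracle["module_count"]

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            topology_metrics(make_edges([]))


class TestSubnetworks:
    def _grn(self):
        return make_edges([
            ("tf1", "a", 0.9), ("tf1", "b", 0.06), ("tf2", "a", 0.5),
            ("tf2", "c", 0.04), ("tf3", "b", 0.3), ("tf3", "c", 0.2),
            ("tf4", "d", 0.15), ("tf4", "a", 0.12), ("tf5", "d", 0.11),
            ("tf5", "b", 0.08),
        ])

    def test_all_regulators_is_identity(self):
        grn = self._grn()
        sub = extract_subnetwork(grn, regulator_filter=set(grn.edges["regulator"]))
        assert sub.pairs == grn.pairs

    def test_min_weight_above_max_is_empty(self):
        with pytest.warns(UserWarning):
            sub = extract_subnetwork(self._grn(), min_weight=2.0)
        assert len(sub) == 0

    def test_known_tf_pair_extraction(self):
        sub = extract_subnetwork(self._grn(), regulator_filter={"tf1", "tf2"})
        assert sub.pairs == {("tf1", "a"), ("tf1", "b"), ("tf2", "a"), ("tf2", "c")}

    def test_weight_threshold_inclusive(self):
        sub = extract_subnetwork(self._grn(), min_weight=0.15)
        assert sub.pairs == {("tf1", "a"), ("tf2", "a"), ("tf3", "b"),
                             ("tf3", "c"), ("tf4", "d")}

    def test_idempotent_under_repeated_filters(self):
        grn = self._grn()
        once = extract_subnetwork(grn, regulator_filter={"tf1", "tf3"}, min_weight=0.1)
        twice = extract_subnetwork(once, regulator_filter={"tf1", "tf3"}, min_weight=0.1)
        pd.testing.assert_frame_equal(
            once.edges[["regulator", "target", "weight", "rank"]],
            twice.edges[["regulator", "target", "weight", "rank"]],
        )


class TestTissueSpecificSubgrn:
    def test_planted_leaf_pair_recovered_only_in_leaf(self):
        cats = ["root", "root", "leaf", "leaf"]
        rna = make_matrix(
            {
                "tf_leaf": [0, 0, 3, 2],
                "g_leaf": [0, 0, 1, 2],
                "tf_root": [4, 3, 0, 0],
                "g_root": [2, 2, 0, 0],
                "g_all": [1, 1, 1, 1],
            },
            categories=cats,
        )
        ribo = make_matrix(
            {
                "tf_leaf": [0, 0, 2, 2],
                "g_leaf": [0, 0, 1, 1],
                "tf_root": [3, 3, 0, 0],
                "g_root": [1, 2, 0, 0],
                "g_all": [1, 1, 1, 1],
            },
            categories=cats,
            omics="translatome",
        )
        segs = detect_segs(rna, ribo)
        grn = make_edges([
            ("tf_leaf", "g_leaf", 0.8), ("tf_root", "g_root", 0.7),
            ("tf_leaf", "g_all", 0.6), ("tf_root", "g_leaf", 0.5),
        ])
        leaf = tissue_specific_subgrn(grn, segs, "leaf")
        root = tissue_specific_subgrn(grn, segs, "root")
        assert leaf.pairs == {("tf_leaf", "g_leaf")}
        assert root.pairs == {("tf_root", "g_root")}

    def test_unknown_category_errors(self, small_atlas):
        segs = detect_segs(small_atlas.matrices["rna_mean"],
                           small_atlas.matrices["ribo_mean"])
        grn = make_edges([("TF0001", "G00001", 0.5)])
        with pytest.raises(ValueError):
            tissue_specific_subgrn(grn, segs, "not_a_tissue")
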