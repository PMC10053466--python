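"""Gold-standard benchmarking: overlaps, nulls, chi-square, AUROC/AUPR, paired t."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import roc_auc_score

import mogrn
from conftest import make_edges
from mogrn.benchmark import (
    GoldStandard,
    auroc_rank_sum,
    chisq_overlap,
    compare_weights,
    overlap_gold,
    per_tf_overlap_table,
    random_overlap_null,
    roc_pr_scores,
)
from oracles import auroc_all_pairs


def _gold(mapping, tf_universe=None, target_universe=None):
    tfs = tf_universe or sorted(mapping)
    targets = target_universe or sorted({t for ts in mapping.values() for t in ts})
    return GoldStandard({tf: frozenset(ts) for tf, ts in mapping.items()},
                        tuple(tfs), tuple(targets))


class TestOverlap:
    def test_basic_overlap(self):
        grn = make_edges([("T1", "g1", 0.5), ("T1", "g2", 0.3)])
        gold = _gold({"T1": {"g2", "g3"}})
        table, total = overlap_gold(grn, gold)
        assert total == 1
        assert table.set_index("tf").loc["T1", "overlap"] == 1

    def test_identical_sets_full_overlap(self):
        grn = make_edges([("T1", "g1", 0.5), ("T2", "g2", 0.3)])
        gold = _gold({"T1": {"g1"}, "T2": {"g2"}})
        _, total = overlap_gold(grn, gold)
        assert total == len(grn)

    def test_matches_set_intersection_oracle(self):
        rng = np.random.default_rng(12)
        tfs = [f"T{i}" for i in range(8)]
        genes = [f"g{i}" for i in range(40)]
        pairs = set()
        while len(pairs) < 100:
            pairs.add((rng.choice(tfs), rng.choice(genes)))
        grn = make_edges([(r, t, float(rng.random())) for r, t in sorted(pairs)])
        gold_pairs = set()
        while len(gold_pairs) < 50:
            gold_pairs.add((rng.choice(tfs), rng.choice(genes)))
        mapping = {}
        for tf, g in gold_pairs:
            mapping.setdefault(tf, set()).add(g)
        gold = _gold(mapping, tf_universe=tfs, target_universe=genes)
        _, total = overlap_gold(grn, gold)
        shared_tfs = set(grn.edges["regulator"]) & set(mapping)
        expected = len({(r, t) for r, t in pairs if r in shared_tfs} & gold_pairs)
        assert total == expected

    def test_no_shared_tfs_errors(self):
        grn = make_edges([("T1", "g1", 0.5)])
        gold = _gold({"T9": {"g1"}})
        with pytest.raises(ValueError):
            overlap_gold(grn, gold)


class TestRandomNull:
    def test_gold_covering_universe_saturates(self):
        genes = [f"g{i}" for i in range(10)]
        grn = make_edges([("T1", g, 0.5) for g in genes[:4]])
        gold = _gold({"T1": set(genes)}, target_universe=genes)
        null = random_overlap_null(grn, gold, n_iter=50, seed=0)
        assert (null.values == len(grn)).all()

    def test_empty_gold_gives_zero(self):
        genes = [f"g{i}" for i in range(10)]
        grn = make_edges([("T1", g, 0.5) for g in genes[:4]])
        gold = _gold({"T1": set()}, target_universe=genes)
        null = random_overlap_null(grn, gold, n_iter=50, seed=0)
        assert (null.values == 0).all()

    def test_mean_matches_hypergeometric_expectation(self):
        genes = [f"g{i}" for i in range(50)]
        k, m = 12, 20
        grn = make_edges([("T1", g, 0.5) for g in genes[:k]])
        gold = _gold({"T1": set(genes[:m])}, target_universe=genes)
        null = random_overlap_null(grn, gold, n_iter=1000, seed=3)
        expected = k * m / len(genes)
        se = null.values.std(ddof=1) / np.sqrt(null.n_iter)
        assert abs(null.mean - expected) < 3 * se + 1e-9

    def test_oversized_grn_errors(self):
        genes = ["g1", "g2"]
        grn = make_edges([("T1", "g1", 0.5), ("T1", "g2", 0.4), ("T1", "g3", 0.3)])
        gold = _gold({"T1": {"g1"}}, target_universe=genes)
        with pytest.raises(ValueError):
            random_overlap_null(grn, gold, n_iter=5, seed=0)

    def test_deterministic_given_seed(self):
        genes = [f"g{i}" for i in range(20)]
        grn = make_edges([("T1", g, 0.5) for g in genes[:6]])
        gold = _gold({"T1": set(genes[:5])}, target_universe=genes)
        a = random_overlap_null(grn, gold, n_iter=100, seed=7)
        b = random_overlap_null(grn, gold, n_iter=100, seed=7)
        assert np.array_equal(a.values, b.values)


class TestChisq:
    def test_observed_equals_expected(self):
        res = chisq_overlap(30, 30.0, 100)
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_matches_hand_computed_two_by_two(self):
        # table (30, 70) vs (10, 90): margins give expected [[20, 80], [20, 80]]
        # chi2 = 100/20 + 100/80 + 100/20 + 100/80 = 12.5
        res = chisq_overlap(30, 10.0, 100)
        assert res.chi2 == pytest.approx(12.5, abs=1e-10)
        assert res.p == pytest.approx(stats.chi2.sf(12.5, 1), abs=1e-12)

    def test_zero_expected_cell_masked(self):
        res = chisq_overlap(0, 0.0, 10)
        assert res.masked and res.chi2 is None

    def test_invalid_counts_error(self):
        with pytest.raises(ValueError):
            chisq_overlap(20, 5.0, 10)


class TestPerTfTable:
    def test_normalizations(self):
        grn = make_edges([("T1", f"g{i}", 0.5) for i in range(10)])
        gold = _gold({"T1": {"g0", "g1", "g2", "g3", "g90", "g91", "g92", "g93"}})
        by_grn = per_tf_overlap_table(grn, gold, "grn_size").set_index("tf")
        by_gold = per_tf_overlap_table(grn, gold, "gold_size").set_index("tf")
        assert by_grn.loc["T1", "value"] == pytest.approx(0.4)   # 4 / 10 predictions
        assert by_gold.loc["T1", "value"] == pytest.approx(0.5)  # 4 / 8 gold targets
        raw = per_tf_overlap_table(grn, gold, "none").set_index("tf")
        assert raw.loc["T1", "value"] == 4

    def test_matches_per_tf_set_enumeration(self):
        rng = np.random.default_rng(21)
        tfs = [f"T{i}" for i in range(5)]
        genes = [f"g{i}" for i in range(25)]
        grn_pairs = {(tf, g) for tf in tfs for g in rng.choice(genes, 6, replace=False)}
        mapping = {tf: set(rng.choice(genes, 8, replace=False)) for tf in tfs}
        grn = make_edges([(r, t, 0.5) for r, t in sorted(grn_pairs)])
        gold = _gold(mapping, tf_universe=tfs, target_universe=genes)
        table = per_tf_overlap_table(grn, gold, "none").set_index("tf")
        for tf in tfs:
            predicted = {t for r, t in grn_pairs if r == tf}
            assert table.loc[tf, "value"] == len(predicted & mapping[tf])


class TestRocPr:
    def test_perfect_ranking(self):
        genes = [f"g{i}" for i in range(10)]
        grn = make_edges([("T1", g, 1.0 - 0.01 * i) for i, g in enumerate(genes[:3])])
        gold = _gold({"T1": set(genes[:3])}, target_universe=genes)
        res = roc_pr_scores(grn, gold)
        assert res.mean_auroc == pytest.approx(1.0)
        assert res.mean_aupr == pytest.approx(1.0)

    def test_inverted_ranking_is_zero_auroc(self):
        scores = np.array([1.0, 2.0, 3.0, 4.0])
        labels = np.array([True, True, False, False])
        assert auroc_rank_sum(scores, labels) == pytest.approx(0.0)

    def test_reversal_sums_to_one_without_ties(self):
        rng = np.random.default_rng(4)
        scores = rng.permutation(np.arange(30, dtype=float))
        labels = rng.random(30) < 0.4
        a = auroc_rank_sum(scores, labels)
        b = auroc_rank_sum(-scores, labels)
        assert a + b == pytest.approx(1.0)

    @pytest.mark.parametrize("case_seed", range(30))
    def test_matches_all_pairs_oracle_and_reference(self, case_seed):
        rng = np.random.default_rng(3000 + case_seed)
        n = int(rng.integers(5, 51))
        scores = np.round(rng.random(n), 2)  # induce ties
        labels = rng.random(n) < 0.4
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        ours = auroc_rank_sum(scores, labels)
        assert ours == pytest.approx(auroc_all_pairs(scores, labels), abs=1e-12)
        assert ours == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_tf_without_negatives_excluded(self):
        genes = ["g1", "g2"]
        grn = make_edges([("T1", "g1", 0.5), ("T2", "g1", 0.4)])
        gold = _gold({"T1": {"g1", "g2"}, "T2": {"g1"}}, target_universe=genes)
        res = roc_pr_scores(grn, gold)
        assert res.excluded == ["T1"]
        assert set(res.per_tf["tf"]) == {"T2"}


class TestCompareWeights:
    def _suites(self, wa, wb):
        pairs = [(f"T{i}", f"g{i}") for i in range(len(wa))]
        return {
            "mm": make_edges([(r, t, w) for (r, t), w in zip(pairs, wa)]),
            "TT": make_edges([(r, t, w) for (r, t), w in zip(pairs, wb)]),
            "Tm": make_edges([(r, t, w) for (r, t), w in zip(pairs, wa)]),
        }

    def test_identical_weights_give_zero_t(self):
        w = [0.5, 0.4, 0.3, 0.2, 0.1]
        table = compare_weights(self._suites(w, w), thresholds=[5])
        assert (table["t"] == 0).all() and (table["p"] == 1).all()

    def test_constant_offset_masked(self):
        wa = [0.5, 0.4, 0.3, 0.2, 0.1]
        wb = [w + 0.01 for w in wa]
        table = compare_weights(self._suites(wa, wb), thresholds=[5]).set_index(["a", "b"])
        row = table.loc[("TT", "mm")] if ("TT", "mm") in table.index else table.loc[("mm", "TT")]
        assert bool(row["masked"]) and row["reason"] == "zero variance of differences"

    def test_matches_closed_form_paired_t(self):
        wa = [0.50, 0.40, 0.30, 0.20, 0.10]
        wb = [0.45, 0.42, 0.20, 0.19, 0.05]
        d = np.array(wa) - np.array(wb)
        expected_t = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        table = compare_weights(self._suites(wa, wb), thresholds=[5]).set_index(["a", "b"])
        row = table.loc[("TT", "mm")] if ("TT", "mm") in table.index else table.loc[("mm", "TT")]
        sign = 1.0 if row.name == ("mm", "TT") else -1.0
        assert row["t"] == pytest.approx(sign * expected_t, abs=1e-10)

    def test_too_few_shared_pairs_masked(self):
        suites = self._suites([0.5, 0.4], [0.3, 0.2])
        table = compare_weights(suites, thresholds=[2])
        assert table["masked"].all()


class TestGoldStandardContainer:
    def test_rejects_targets_outside_universe(self):
        with pytest.raises(ValueError):
            GoldStandard({"T1": frozenset({"gX"})}, ("T1",), ("g1",))

    def test_tsv_round_trip(self, tmp_path):
        gold = _gold({"T1": {"g1", "g2"}, "T2": {"g3"}})
        path = tmp_path / "gold.tsv"
        gold.to_tsv(path)
        back = GoldStandard.read_tsv(path, tf_universe=list(gold.tf_universe),
                                     target_universe=list(gold.target_universe))
        assert back.targets_by_tf == gold.targets_by_tf
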