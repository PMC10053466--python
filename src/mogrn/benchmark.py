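"""Benchmarking inferred GRNs against a gold-standard regulatome.

The gold standard is a TF -> target-set mapping of the kind produced by
ChIP-seq-style binding assays. Evaluation follows the usual repertoire:
raw and per-TF-normalized overlap counts, a randomized null in which each
TF's predicted targets are redrawn uniformly from the target universe,
a 2x2 chi-square test of observed versus null-expected overlap, AUROC /
AUPR of the weighted edge ranking, and paired-t comparisons of edge
weights between network types.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import average_precision_score

from .inference import EdgeList, truncate_edges

__all__ = [
    "GoldStandard",
    "overlap_gold",
    "random_overlap_null",
    "chisq_overlap",
    "per_tf_overlap_table",
    "roc_pr_scores",
    "compare_weights",
]


@dataclass
class GoldStandard:
    """TF -> target-gene sets with declared TF and target universes."""

    targets_by_tf: dict[str, frozenset[str]]
    tf_universe: tuple[str, ...]
    target_universe: tuple[str, ...]

    def __post_init__(self) -> None:
        self.targets_by_tf = {tf: frozenset(ts) for tf, ts in self.targets_by_tf.items()}
        self.tf_universe = tuple(self.tf_universe)
        self.target_universe = tuple(self.target_universe)
        universe = set(self.target_universe)
        for tf, targets in self.targets_by_tf.items():
            if tf not in self.tf_universe:
                raise ValueError(f"gold TF {tf!r} not in the declared TF universe")
            bad = targets - universe
            if bad:
                raise ValueError(f"gold targets outside the target universe: {sorted(bad)[:5]}")

    @property
    def pairs(self) -> frozenset[tuple[str, str]]:
        return frozenset((tf, t) for tf, ts in self.targets_by_tf.items() for t in ts)

    def n_pairs(self) -> int:
        return sum(len(ts) for ts in self.targets_by_tf.values())

    def to_tsv(self, path: str | Path) -> None:
        rows = [(tf, t) for tf in sorted(self.targets_by_tf) for t in sorted(self.targets_by_tf[tf])]
        pd.DataFrame(rows, columns=["tf", "target"]).to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(
        cls,
        path: str | Path,
        tf_universe: list[str] | None = None,
        target_universe: list[str] | None = None,
    ) -> "GoldStandard":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if list(df.columns[:2]) != ["tf", "target"]:
            df.columns = ["tf", "target"] + list(df.columns[2:])
        mapping: dict[str, set[str]] = {}
        for tf, t in zip(df["tf"], df["target"]):
            mapping.setdefault(tf, set()).add(t)
        tfs = tuple(tf_universe) if tf_universe is not None else tuple(sorted(mapping))
        targets = (
            tuple(target_universe)
            if target_universe is not None
            else tuple(sorted(set(df["target"])))
        )
        return cls({tf: frozenset(ts) for tf, ts in mapping.items()}, tfs, targets)


def _grn_targets_by_tf(grn: EdgeList) -> dict[str, frozenset[str]]:
    out: dict[str, set[str]] = {}
    for reg, tgt in zip(grn.edges["regulator"], grn.edges["target"]):
        out.setdefault(reg, set()).add(tgt)
    return {tf: frozenset(ts) for tf, ts in out.items()}


def _shared_tfs(grn: EdgeList, gold: GoldStandard) -> list[str]:
    grn_tfs = set(grn.edges["regulator"])
    shared = sorted(grn_tfs & set(gold.targets_by_tf))
    if not shared:
        raise ValueError("no TFs shared between the GRN and the gold standard")
    return shared


def overlap_gold(grn: EdgeList, gold: GoldStandard) -> tuple[pd.DataFrame, int]:
    """Per-TF and total overlap between GRN edges and gold-standard pairs.

    Counted on (TF, target) pairs, restricted to TFs present in both the
    network and the gold standard.
    """
    shared = _shared_tfs(grn, gold)
    by_tf = _grn_targets_by_tf(grn)
    rows = []
    for tf in shared:
        pred = by_tf.get(tf, frozenset())
        gold_t = gold.targets_by_tf[tf]
        rows.append(
            {
                "tf": tf,
                "grn_targets": len(pred),
                "gold_targets": len(gold_t),
                "overlap": len(pred & gold_t),
            }
        )
    table = pd.DataFrame(rows)
    return table, int(table["overlap"].sum())


@dataclass
class NullOverlap:
    values: np.ndarray
    mean: float
    n_iter: int
    seed: int


def random_overlap_null(
    grn: EdgeList, gold: GoldStandard, n_iter: int = 1000, seed: int = 0
) -> NullOverlap:
    """Null distribution of gold overlap under random target assignment.

    Each iteration redraws, for every shared TF, the same number of targets
    uniformly without replacement from the declared target universe (minus
    the TF itself), and counts the overlap with the gold standard. This is
    the "random TF-target pairs" control of the benchmark.
    """
    shared = _shared_tfs(grn, gold)
    by_tf = _grn_targets_by_tf(grn)
    universe = np.array(gold.target_universe, dtype=object)
    idx_of = {g: i for i, g in enumerate(universe)}
    rng = np.random.default_rng(seed)
    draws = []
    for tf in shared:
        k = len(by_tf.get(tf, frozenset()))
        allowed = np.array([i for g, i in idx_of.items() if g != tf], dtype=int)
        if k > len(allowed):
            raise ValueError(
                f"TF {tf!r} has {k} predicted targets but the universe holds only {len(allowed)}"
            )
        gold_mask = np.zeros(len(universe), dtype=bool)
        for g in gold.targets_by_tf[tf]:
            gold_mask[idx_of[g]] = True
        draws.append((allowed, k, gold_mask))
    values = np.zeros(n_iter, dtype=int)
    for it in range(n_iter):
        total = 0
        for allowed, k, gold_mask in draws:
            if k == 0:
                continue
            pick = rng.choice(allowed, size=k, replace=False)
            total += int(gold_mask[pick].sum())
        values[it] = total
    return NullOverlap(values=values, mean=float(values.mean()), n_iter=n_iter, seed=seed)


@dataclass
class ChisqResult:
    chi2: float | None
    p: float | None
    masked: bool = False
    reason: str = ""


def chisq_overlap(observed_overlap: float, null_mean_overlap: float, n_pairs: int) -> ChisqResult:
    """2x2 chi-square of observed vs null-expected overlap, df=1, no correction.

    Rows are (GRN prediction, random control); columns are (overlapping,
    non-overlapping) out of ``n_pairs`` considered pairs.
    """
    if n_pairs < observed_overlap or n_pairs < null_mean_overlap:
        raise ValueError("n_pairs must be at least the overlap counts")
    table = np.array(
        [
            [observed_overlap, n_pairs - observed_overlap],
            [null_mean_overlap, n_pairs - null_mean_overlap],
        ],
        dtype=float,
    )
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    if (expected == 0).any():
        return ChisqResult(None, None, masked=True, reason="zero expected cell")
    chi2 = float(((table - expected) ** 2 / expected).sum())
    p = float(stats.chi2.sf(chi2, df=1))
    return ChisqResult(chi2=chi2, p=p)


def per_tf_overlap_table(
    grn: EdgeList, gold: GoldStandard, normalization: str = "none"
) -> pd.DataFrame:
    """Per-TF overlap counts, optionally normalized.

    ``normalization="grn_size"`` divides each TF's overlap by its number of
    predicted targets; ``"gold_size"`` by its number of gold targets; both
    emit NaN (masked) on division by zero.
    """
    if normalization not in ("none", "grn_size", "gold_size"):
        raise ValueError("normalization must be none, grn_size or gold_size")
    table, _ = overlap_gold(grn, gold)
    if normalization == "none":
        table["value"] = table["overlap"].astype(float)
    else:
        denom = table["grn_targets"] if normalization == "grn_size" else table["gold_targets"]
        with np.errstate(divide="ignore", invalid="ignore"):
            table["value"] = np.where(denom > 0, table["overlap"] / denom, np.nan)
    table["normalization"] = normalization
    return table


def auroc_rank_sum(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUROC via the Mann-Whitney rank-sum formulation with midrank ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    m = int(labels.sum())
    n = int((~labels).sum())
    if m == 0 or n == 0:
        raise ValueError("AUROC needs at least one positive and one negative")
    ranks = stats.rankdata(scores)
    return float((ranks[labels].sum() - m * (m + 1) / 2) / (m * n))


@dataclass
class RocPrResult:
    per_tf: pd.DataFrame
    mean_auroc: float | None
    mean_aupr: float | None
    scope: str
    excluded: list[str] = field(default_factory=list)


def roc_pr_scores(grn: EdgeList, gold: GoldStandard, scope: str = "per_tf") -> RocPrResult:
    """AUROC and AUPR of the weighted ranking against gold-standard positives.

    For each shared TF, candidates are the declared target universe minus
    the TF itself; positives are its gold targets; candidates missing from
    the GRN score 0. ``scope="per_tf"`` averages over TFs that have at least
    one positive and one negative; ``scope="pooled"`` scores all candidate
    pairs jointly.
    """
    if scope not in ("per_tf", "pooled"):
        raise ValueError("scope must be per_tf or pooled")
    shared = _shared_tfs(grn, gold)
    weights = {
        (r, t): w
        for r, t, w in zip(grn.edges["regulator"], grn.edges["target"], grn.edges["weight"])
    }
    rows = []
    excluded: list[str] = []
    pooled_scores: list[np.ndarray] = []
    pooled_labels: list[np.ndarray] = []
    for tf in shared:
        candidates = [t for t in gold.target_universe if t != tf]
        gold_t = gold.targets_by_tf[tf]
        labels = np.array([t in gold_t for t in candidates], dtype=bool)
        scores = np.array([weights.get((tf, t), 0.0) for t in candidates], dtype=float)
        n_pos = int(labels.sum())
        n_neg = int((~labels).sum())
        pooled_scores.append(scores)
        pooled_labels.append(labels)
        if n_pos == 0 or n_neg == 0:
            excluded.append(tf)
            continue
        rows.append(
            {
                "tf": tf,
                "auroc": auroc_rank_sum(scores, labels),
                "aupr": float(average_precision_score(labels, scores)),
                "n_pos": n_pos,
                "n_neg": n_neg,
            }
        )
    per_tf = pd.DataFrame(rows, columns=["tf", "auroc", "aupr", "n_pos", "n_neg"])
    if scope == "pooled":
        scores = np.concatenate(pooled_scores)
        labels = np.concatenate(pooled_labels)
        if labels.any() and (~labels).any():
            mean_auroc = auroc_rank_sum(scores, labels)
            mean_aupr = float(average_precision_score(labels, scores))
        else:
            mean_auroc = mean_aupr = None
    else:
        mean_auroc = float(per_tf["auroc"].mean()) if len(per_tf) else None
        mean_aupr = float(per_tf["aupr"].mean()) if len(per_tf) else None
    return RocPrResult(
        per_tf=per_tf, mean_auroc=mean_auroc, mean_aupr=mean_aupr, scope=scope, excluded=excluded
    )


def _paired_t(x: np.ndarray, y: np.ndarray) -> dict:
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    n = len(d)
    if n < 3:
        return {"n": n, "t": None, "p": None, "masked": True, "reason": "fewer than 3 pairs"}
    if np.allclose(d, 0.0):
        return {"n": n, "t": 0.0, "p": 1.0, "masked": False, "reason": "",
                "mean_diff": 0.0}
    if np.allclose(d, d[0], rtol=1e-9, atol=1e-12):
        return {
            "n": n,
            "t": None,
            "p": None,
            "masked": True,
            "reason": "zero variance of differences",
        }
    t, p = stats.ttest_rel(x, y)
    return {"n": n, "t": float(t), "p": float(p), "masked": False, "reason": "",
            "mean_diff": float(d.mean())}


def compare_weights(
    suites: dict[str, EdgeList], thresholds: list[int], test: str = "paired_t"
) -> pd.DataFrame:
    """Compare edge weights between network types over shared pairs.

    For each top-k threshold, every suite member is truncated to its top-k
    edges, the (regulator, target) pairs present in *all* members are taken,
    and for each pair of network types a two-sided paired t statistic is
    computed on the two weight vectors over those shared pairs.
    """
    if test != "paired_t":
        raise ValueError("only the paired t test is implemented")
    names = sorted(suites)
    rows = []
    for k in thresholds:
        trunc = {name: truncate_edges(suites[name], "top_k", k) for name in names}
        pair_sets = [trunc[name].pairs for name in names]
        common = sorted(frozenset.intersection(*pair_sets))
        weight_maps = {
            name: {
                (r, t): w
                for r, t, w in zip(
                    trunc[name].edges["regulator"],
                    trunc[name].edges["target"],
                    trunc[name].edges["weight"],
                )
            }
            for name in names
        }
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                wa = np.array([weight_maps[a][p] for p in common])
                wb = np.array([weight_maps[b][p] for p in common])
                res = _paired_t(wa, wb) if len(common) >= 3 else {
                    "n": len(common), "t": None, "p": None, "masked": True,
                    "reason": "fewer than 3 shared pairs",
                }
                rows.append({"threshold": k, "a": a, "b": b, **res})
    return pd.DataFrame(rows)
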