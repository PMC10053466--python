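"""Tree-ensemble inference of weighted regulator -> target networks.

Follows the GENIE3 scheme: for every target gene, a random-forest regression
of its expression profile on the profiles of all candidate regulators (TFs)
is fitted, and each regulator's importance is the total variance reduction
attributed to its splits, averaged over trees and normalized to sum to one
across regulators. Concatenating the per-target importances and ranking by
weight yields a directed weighted edge list.

Because the regulator matrix and the target matrix may come from different
omics layers, the same routine produces the three network types:

- ``mm``: transcriptome TFs -> transcriptome targets (intra-omics),
- ``TT``: translatome TFs -> translatome targets (intra-omics),
- ``Tm``: translatome TFs -> transcriptome targets (inter-omics).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .atlas import ExpressionMatrix

__all__ = [
    "EdgeList",
    "rank_regulators_for_target",
    "infer_grn",
    "truncate_edges",
    "grn_type_for",
]

GRN_TYPES = ("mm", "TT", "Tm", "mT")

EDGE_COLUMNS = ["regulator", "target", "weight", "rank"]


def grn_type_for(regulator_omics: str, target_omics: str) -> str:
    """Network-type label from the omics layers of regulators and targets."""
    key = {
        ("transcriptome", "transcriptome"): "mm",
        ("translatome", "translatome"): "TT",
        ("translatome", "transcriptome"): "Tm",
        ("transcriptome", "translatome"): "mT",
    }
    try:
        return key[(regulator_omics, target_omics)]
    except KeyError:
        raise ValueError(f"unknown omics pairing ({regulator_omics}, {target_omics})") from None


def _rank_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Sort by (weight desc, regulator asc, target asc) and assign ranks 1..N."""
    out = df.sort_values(
        ["weight", "regulator", "target"], ascending=[False, True, True], kind="mergesort"
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


@dataclass
class EdgeList:
    """Ranked, weighted regulator -> target edges with provenance labels.

    ``edges`` has columns regulator, target, weight, rank (plus optional
    provenance flags); ranks are 1..N consistent with non-increasing weight
    under the tie-break (weight desc, regulator asc, target asc).
    """

    edges: pd.DataFrame
    grn_type: str | None = None
    source: str | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.edges
        for col in ("regulator", "target", "weight"):
            if col not in df.columns:
                raise ValueError(f"edge table missing column {col!r}")
        if (df["regulator"] == df["target"]).any():
            raise ValueError("self-edges are not allowed")
        if df.duplicated(subset=["regulator", "target"]).any():
            raise ValueError("duplicate (regulator, target) pairs")
        if (df["weight"].to_numpy() < 0).any():
            raise ValueError("edge weights must be nonnegative")
        if "rank" not in df.columns:
            self.edges = _rank_frame(df.copy())
        if self.grn_type is not None and self.grn_type not in GRN_TYPES:
            raise ValueError(f"grn_type must be one of {GRN_TYPES}")

    def __len__(self) -> int:
        return len(self.edges)

    @property
    def pairs(self) -> frozenset[tuple[str, str]]:
        return frozenset(zip(self.edges["regulator"], self.edges["target"]))

    @property
    def label(self) -> str:
        return f"{self.grn_type or 'grn'}_{self.source or 'na'}"

    def reranked(self) -> "EdgeList":
        return EdgeList(
            _rank_frame(self.edges.drop(columns=["rank"], errors="ignore")),
            grn_type=self.grn_type,
            source=self.source,
            params=dict(self.params),
        )

    def to_tsv(self, path: str | Path) -> None:
        out = self.edges.copy()
        out["grn_type"] = self.grn_type or ""
        out["source"] = self.source or ""
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "EdgeList":
        df = pd.read_csv(path, sep="\t", dtype={"regulator": str, "target": str})
        grn_type = None
        source = None
        if "grn_type" in df.columns:
            vals = df["grn_type"].dropna().unique()
            grn_type = str(vals[0]) if len(vals) == 1 and str(vals[0]) else None
            df = df.drop(columns=["grn_type"])
        if "source" in df.columns:
            vals = df["source"].dropna().unique()
            source = str(vals[0]) if len(vals) == 1 and str(vals[0]) else None
            df = df.drop(columns=["source"])
        return cls(df, grn_type=grn_type, source=source)


def _max_features(k, n_regulators: int):
    if k == "sqrt":
        return "sqrt"
    if k == "all":
        return None
    k = int(k)
    if not 1 <= k <= n_regulators:
        raise ValueError(f"k={k} out of range for {n_regulators} regulators")
    return k


def rank_regulators_for_target(
    target_profile: np.ndarray | pd.Series,
    regulators: ExpressionMatrix | pd.DataFrame,
    n_trees: int = 1000,
    k: str | int = "sqrt",
    seed: int = 0,
    max_depth: int | None = None,
    bootstrap: bool = True,
    normalize: bool = True,
) -> pd.Series:
    """Importance score per regulator for one target gene.

    Fits ``n_trees`` regression trees predicting the target profile from the
    regulator profiles, each split drawing ``k`` candidate regulators
    ("sqrt", "all" or an int). A regulator's raw importance is the total
    impurity (variance) reduction attributed to it, averaged over trees; with
    ``normalize=True`` (default) the vector is rescaled to sum to one. A
    constant target profile yields an all-zero vector.
    """
    reg_values = regulators.values if isinstance(regulators, ExpressionMatrix) else regulators
    y = np.asarray(target_profile, dtype=float)
    if y.ndim != 1 or y.shape[0] != reg_values.shape[1]:
        raise ValueError("target profile length must equal the number of samples")
    if y.shape[0] < 3:
        raise ValueError("at least 3 samples are required")
    reg_ids = list(reg_values.index)
    if np.allclose(y, y[0]):
        return pd.Series(np.zeros(len(reg_ids)), index=reg_ids, name="importance")
    X = reg_values.to_numpy(dtype=float).T  # samples x regulators
    forest = RandomForestRegressor(
        n_estimators=int(n_trees),
        max_features=_max_features(k, len(reg_ids)),
        max_depth=max_depth,
        bootstrap=bootstrap,
        random_state=int(seed) % (2**31 - 1),
        n_jobs=1,
    )
    forest.fit(X, y)
    raw = np.zeros(len(reg_ids))
    for tree in forest.estimators_:
        raw += tree.tree_.compute_feature_importances(normalize=False)
    raw /= len(forest.estimators_)
    if normalize:
        total = raw.sum()
        if total > 0:
            raw = raw / total
    return pd.Series(raw, index=reg_ids, name="importance")


def _target_seed(seed: int, target: str) -> int:
    return (int(seed) + zlib.crc32(target.encode("utf-8"))) % (2**31 - 1)


def infer_grn(
    regulator_matrix: ExpressionMatrix,
    target_matrix: ExpressionMatrix,
    regulator_ids: list[str],
    target_ids: list[str],
    n_trees: int = 1000,
    k: str | int = "sqrt",
    seed: int = 0,
) -> EdgeList:
    """Infer a weighted GRN from a (regulator matrix, target matrix) pairing.

    Both matrices must cover the identical tissue/sample set (inter-omics
    inference pairs a TF's translatome profile with a target's transcriptome
    profile in the *same* tissues). A TF appearing among the targets is
    excluded from its own candidate regulators, so no self-edges arise. Each
    target gets its own deterministic seed derived from ``seed``.
    """
    if list(regulator_matrix.samples) != list(target_matrix.samples):
        if set(regulator_matrix.samples) != set(target_matrix.samples):
            raise ValueError("regulator and target matrices must share the same sample set")
        target_matrix = ExpressionMatrix(
            target_matrix.values[regulator_matrix.samples],
            target_matrix.omics,
            target_matrix.source,
            target_matrix.metadata,
        )
    missing = [r for r in regulator_ids if r not in regulator_matrix.genes]
    if missing:
        raise ValueError(f"regulators absent from regulator matrix: {missing[:5]}")
    missing = [t for t in target_ids if t not in target_matrix.genes]
    if missing:
        raise ValueError(f"targets absent from target matrix: {missing[:5]}")
    reg_values = regulator_matrix.values.loc[list(regulator_ids)]
    records: list[pd.DataFrame] = []
    for target in target_ids:
        candidates = reg_values.drop(index=target, errors="ignore")
        if candidates.empty:
            continue
        imp = rank_regulators_for_target(
            target_matrix.values.loc[target],
            candidates,
            n_trees=n_trees,
            k=k,
            seed=_target_seed(seed, target),
        )
        records.append(
            pd.DataFrame(
                {"regulator": imp.index, "target": target, "weight": imp.to_numpy()}
            )
        )
    edges = pd.concat(records, ignore_index=True) if records else pd.DataFrame(
        columns=["regulator", "target", "weight"]
    )
    params = {"n_trees": int(n_trees), "k": str(k), "seed": int(seed),
              "n_regulators": len(regulator_ids), "n_targets": len(target_ids)}
    return EdgeList(
        _rank_frame(edges),
        grn_type=grn_type_for(regulator_matrix.omics, target_matrix.omics),
        source=regulator_matrix.source if regulator_matrix.source == target_matrix.source else None,
        params=params,
    )


def truncate_edges(edges: EdgeList, mode: str, value: float) -> EdgeList:
    """Keep the top-k ranks (``mode="top_k"``) or weights >= value
    (``mode="min_weight"``, inclusive); the result is re-ranked 1..N."""
    if value <= 0:
        raise ValueError("truncation value must be positive")
    df = edges.reranked().edges
    if mode == "top_k":
        kept = df[df["rank"] <= int(value)]
    elif mode == "min_weight":
        kept = df[df["weight"] >= value]
    else:
        raise ValueError("mode must be 'top_k' or 'min_weight'")
    return EdgeList(
        _rank_frame(kept.drop(columns=["rank"])),
        grn_type=edges.grn_type,
        source=edges.source,
        params={**edges.params, "truncate": {"mode": mode, "value": value}},
    )
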