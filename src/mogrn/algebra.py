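"""Set algebra and topology of regulatory edge lists.

Union and intersection of truncated networks across types (mm / TT / Tm)
and data sources (mean / bulked), the high-confidence network (per-source
intersection of the three types, merged across sources), global topology
metrics on the undirected projection, and sub-network extraction by TF /
target / weight filters or tissue specificity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .atlas import SegReport
from .inference import EdgeList, _rank_frame, truncate_edges

__all__ = [
    "union_networks",
    "intersect_networks",
    "build_high_confidence",
    "TopologyReport",
    "topology_metrics",
    "extract_subnetwork",
    "tissue_specific_subgrn",
]


def _labels(lists: list[EdgeList]) -> list[str]:
    labels = []
    for i, el in enumerate(lists):
        label = el.label if el.grn_type or el.source else f"grn{i}"
        if label in labels:
            label = f"{label}_{i}"
        labels.append(label)
    return labels


def union_networks(lists: list[EdgeList], weight_rule: str = "max") -> EdgeList:
    """Deduplicated union of edge lists on (regulator, target).

    The weight of a pair present in several inputs is aggregated with
    ``weight_rule`` ("max" or "mean"); boolean provenance columns
    (``in_<label>``) record which inputs contained each pair. Inputs are
    expected to be truncated beforehand (e.g. to their top-k edges).
    """
    if not lists:
        raise ValueError("union of an empty collection of networks")
    if weight_rule not in ("max", "mean"):
        raise ValueError("weight_rule must be 'max' or 'mean'")
    labels = _labels(list(lists))
    frames = []
    for el, label in zip(lists, labels):
        df = el.edges[["regulator", "target", "weight"]].copy()
        df["member"] = label
        frames.append(df)
    stacked = pd.concat(frames, ignore_index=True)
    agg = (
        stacked.groupby(["regulator", "target"], as_index=False)["weight"]
        .agg(weight_rule)
    )
    membership = (
        stacked.assign(flag=True)
        .pivot_table(
            index=["regulator", "target"], columns="member", values="flag", aggfunc="any",
            fill_value=False,
        )
        .reset_index()
    )
    membership.columns = ["regulator", "target"] + [
        f"in_{c}" for c in membership.columns[2:]
    ]
    merged = agg.merge(membership, on=["regulator", "target"], how="left")
    return EdgeList(
        _rank_frame(merged),
        grn_type=None,
        source=None,
        params={"operation": "union", "weight_rule": weight_rule, "members": labels},
    )


def intersect_networks(lists: list[EdgeList]) -> EdgeList:
    """Pairs present in every input; weight is the mean of member weights."""
    if not lists:
        raise ValueError("intersection of an empty collection of networks")
    labels = _labels(list(lists))
    common = frozenset.intersection(*[el.pairs for el in lists])
    if not common:
        warnings.warn("intersection is empty", stacklevel=2)
        empty = pd.DataFrame(columns=["regulator", "target", "weight"])
        return EdgeList(
            _rank_frame(empty),
            params={"operation": "intersection", "members": labels},
        )
    rows = []
    maps = [
        {(r, t): w for r, t, w in zip(el.edges["regulator"], el.edges["target"], el.edges["weight"])}
        for el in lists
    ]
    for pair in sorted(common):
        rows.append(
            {
                "regulator": pair[0],
                "target": pair[1],
                "weight": float(np.mean([m[pair] for m in maps])),
            }
        )
    return EdgeList(
        _rank_frame(pd.DataFrame(rows)),
        params={"operation": "intersection", "members": labels},
    )


def build_high_confidence(
    mean_suite: dict[str, EdgeList],
    bulked_suite: dict[str, EdgeList],
    top_k: int | None = None,
) -> EdgeList:
    """High-confidence network: per-source type intersection, merged sources.

    Within each data source the three network types (mm, TT, Tm) are
    truncated (optionally) to their top-k edges and intersected; the two
    per-source intersections are then merged (union).
    """
    for name, suite in (("mean", mean_suite), ("bulked", bulked_suite)):
        missing = {"mm", "TT", "Tm"} - set(suite)
        if missing:
            raise ValueError(f"{name} suite is missing network types: {sorted(missing)}")
    per_source = []
    for suite in (mean_suite, bulked_suite):
        members = [suite[t] for t in ("mm", "TT", "Tm")]
        if top_k is not None:
            members = [truncate_edges(m, "top_k", top_k) for m in members]
        per_source.append(intersect_networks(members))
    nonempty = [el for el in per_source if len(el)]
    if not nonempty:
        warnings.warn("high-confidence network is empty", stacklevel=2)
        return per_source[0]
    merged = union_networks(nonempty, weight_rule="max")
    merged.params["operation"] = "high_confidence"
    return merged


@dataclass
class TopologyReport:
    """Global topology of the undirected simple graph induced by the edges."""

    n_nodes: int
    n_edges: int
    transitivity: float
    average_path_length: float
    module_count: int
    min_nodes: int

    def to_dict(self) -> dict:
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "transitivity": self.transitivity,
            "average_path_length": self.average_path_length,
            "module_count": self.module_count,
            "min_nodes": self.min_nodes,
        }


def topology_metrics(edges: EdgeList, min_nodes: int = 5) -> TopologyReport:
    """Transitivity, average shortest-path length and module count.

    Computed on the undirected simple graph: transitivity is 3 x triangles /
    connected triples; average path length is the mean shortest-path length
    over connected, ordered-distinct node pairs (disconnected pairs are
    ignored); modules are connected components with at least ``min_nodes``
    nodes.
    """
    if not len(edges):
        raise ValueError("topology of an empty edge list")
    g = nx.Graph()
    g.add_edges_from(zip(edges.edges["regulator"], edges.edges["target"]))
    total, count = 0, 0
    modules = 0
    for comp in nx.connected_components(g):
        if len(comp) >= min_nodes:
            modules += 1
        sub = g.subgraph(comp)
        for _, dists in nx.all_pairs_shortest_path_length(sub):
            for d in dists.values():
                if d > 0:
                    total += d
                    count += 1
    apl = total / count if count else float("nan")
    return TopologyReport(
        n_nodes=g.number_of_nodes(),
        n_edges=g.number_of_edges(),
        transitivity=float(nx.transitivity(g)),
        average_path_length=float(apl),
        module_count=modules,
        min_nodes=min_nodes,
    )


def extract_subnetwork(
    grn: EdgeList,
    regulator_filter: set[str] | None = None,
    target_filter: set[str] | None = None,
    min_weight: float | None = None,
) -> EdgeList:
    """Edges passing regulator / target / minimum-weight filters (all optional).

    ``min_weight`` is inclusive. An empty result is valid and flagged with a
    warning.
    """
    df = grn.edges
    keep = pd.Series(True, index=df.index)
    if regulator_filter is not None:
        keep &= df["regulator"].isin(set(regulator_filter))
    if target_filter is not None:
        keep &= df["target"].isin(set(target_filter))
    if min_weight is not None:
        keep &= df["weight"] >= min_weight
    kept = df[keep]
    if kept.empty:
        warnings.warn("sub-network filters eliminated all edges", stacklevel=2)
    return EdgeList(
        _rank_frame(kept.drop(columns=["rank"], errors="ignore")),
        grn_type=grn.grn_type,
        source=grn.source,
        params={
            **grn.params,
            "subnetwork": {
                "n_regulators": None if regulator_filter is None else len(set(regulator_filter)),
                "n_targets": None if target_filter is None else len(set(target_filter)),
                "min_weight": min_weight,
            },
        },
    )


def tissue_specific_subgrn(grn: EdgeList, seg_report: SegReport, category: str) -> EdgeList:
    """Sub-network expected to operate in one tissue category.

    Keeps edges whose regulator is *specifically translated* in the category
    and whose target is specifically expressed there at either omics layer —
    i.e. TF and target are simultaneously detected only in that tissue.
    """
    if category not in seg_report.n_samples:
        raise ValueError(f"unknown tissue category {category!r}")
    regulators = seg_report.translated[category]
    targets = seg_report.segs(category)
    sub = extract_subnetwork(grn, regulator_filter=set(regulators), target_filter=set(targets))
    sub.params["tissue_category"] = category
    return sub
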