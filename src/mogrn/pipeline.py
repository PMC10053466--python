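"""Configuration-driven orchestration of the full workflow.

simulate (or load) -> QC -> six network inferences (mm/TT/Tm x mean/bulked)
-> truncation -> union and high-confidence networks -> topology ->
benchmarking against the gold standard, with per-stage seed substreams,
stage-level logging and a manifest of content-hashed artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._util import substream_seed
from .algebra import (
    build_high_confidence,
    extract_subnetwork,
    topology_metrics,
    union_networks,
)
from .atlas import (
    ExpressionMatrix,
    compute_te,
    correlation_report,
    detect_segs,
    filter_grn_genes,
    select_regulators,
)
from .benchmark import (
    GoldStandard,
    chisq_overlap,
    compare_weights,
    overlap_gold,
    per_tf_overlap_table,
    random_overlap_null,
    roc_pr_scores,
)
from .inference import EdgeList, infer_grn, truncate_edges
from .simulate import (
    DEFAULT_CATEGORIES,
    generate_truth_network,
    make_gold_standard,
    simulate_atlas,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]


def _from_dict(cls, data: dict):
    if not isinstance(data, dict):
        raise ValueError(f"expected a mapping for {cls.__name__}, got {type(data).__name__}")
    names = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(names)
    if unknown:
        raise ValueError(f"unknown keys for {cls.__name__}: {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        if dataclasses.is_dataclass(_RESOLVED.get(key)) and isinstance(value, dict):
            kwargs[key] = _from_dict(_RESOLVED[key], value)
        else:
            kwargs[key] = value
    return cls(**kwargs)


@dataclass
class SimulationConfig:
    n_tf: int = 20
    n_target: int = 200
    mean_out_degree: float = 6.0
    n_tissues: int = 12
    categories: list[str] = field(default_factory=lambda: list(DEFAULT_CATEGORIES))
    te_sigma: float = 1.0
    noise_sd: float = 0.25
    detection_dropout: float = 0.02
    gold_observed_fraction: float = 1.0
    gold_spurious_fraction: float = 0.0


@dataclass
class InferenceConfig:
    n_trees: int = 100
    k: str = "sqrt"


@dataclass
class TruncationConfig:
    top_k: int = 1_000_000


@dataclass
class BenchmarkConfig:
    null_iters: int = 1000
    # top-k thresholds for the weight comparison; None = 20%/60%/100% of
    # the truncated network size
    thresholds: list[int] | None = None


@dataclass
class SeedsConfig:
    simulate: int | None = None
    inference: int | None = None
    benchmark: int | None = None


_RESOLVED = {
    "simulation": SimulationConfig,
    "inference": InferenceConfig,
    "truncation": TruncationConfig,
    "benchmark": BenchmarkConfig,
    "seeds": SeedsConfig,
}


@dataclass
class PipelineConfig:
    seed: int = 1
    output_dir: str = "mogrn_run"
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    inference: InferenceConfig = field(default_factory=InferenceConfig)
    truncation: TruncationConfig = field(default_factory=TruncationConfig)
    benchmark: BenchmarkConfig = field(default_factory=BenchmarkConfig)
    seeds: SeedsConfig = field(default_factory=SeedsConfig)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        return _from_dict(cls, data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def fingerprint(self) -> str:
        # output_dir is a location, not a parameter: two runs of the same
        # analysis into different directories share a fingerprint
        payload = {k: v for k, v in self.to_dict().items() if k != "output_dir"}
        canonical = json.dumps(payload, sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()


def load_config(path: str | Path) -> PipelineConfig:
    """Load a pipeline configuration from a YAML file (unknown keys rejected)."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig.from_dict(data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


GRN_PAIRINGS = {
    # grn_type -> (regulator layer, target layer)
    "mm": ("rna", "rna"),
    "TT": ("ribo", "ribo"),
    "Tm": ("ribo", "rna"),
}


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full workflow and return the artifact manifest.

    Stages run in order (simulate, qc, infer x6, merge, topology, benchmark);
    any failure aborts with the stage name. Every artifact is written under
    ``config.output_dir`` and listed in the manifest with its SHA-256.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    stage = "setup"
    try:
        sim_seed = (
            config.seeds.simulate
            if config.seeds.simulate is not None
            else substream_seed(config.seed, "simulate")
        )
        inf_seed = (
            config.seeds.inference
            if config.seeds.inference is not None
            else substream_seed(config.seed, "inference")
        )
        bench_seed = (
            config.seeds.benchmark
            if config.seeds.benchmark is not None
            else substream_seed(config.seed, "benchmark")
        )

        stage = "simulate"
        sim = config.simulation
        truth = generate_truth_network(
            sim.n_tf, sim.n_target, sim.mean_out_degree, seed=sim_seed
        )
        atlas = simulate_atlas(
            truth,
            n_tissues=sim.n_tissues,
            categories=tuple(sim.categories),
            te_sigma=sim.te_sigma,
            noise_sd=sim.noise_sd,
            detection_dropout=sim.detection_dropout,
            seed=sim_seed,
        )
        gold = make_gold_standard(
            truth,
            observed_fraction=sim.gold_observed_fraction,
            spurious_fraction=sim.gold_spurious_fraction,
            seed=sim_seed,
        )
        logger.info("simulate: %d TFs, %d targets, %d truth edges, %d tissues",
                    sim.n_tf, sim.n_target, len(truth.edges), sim.n_tissues)
        for name, path in atlas.write(outdir / "atlas").items():
            artifacts[f"atlas/{name}"] = path
        gold_path = outdir / "gold_standard.tsv"
        gold.to_tsv(gold_path)
        artifacts["gold_standard"] = gold_path

        stage = "qc"
        qc: dict = {"filters": {}, "regulators": {}, "correlations": {}, "segs": {}}
        tf_ids = list(truth.regulators)
        for source in ("mean", "bulked"):
            rna = atlas.matrices[f"rna_{source}"]
            ribo = atlas.matrices[f"ribo_{source}"]
            qc["filters"][source] = {
                "rna_pass": len(filter_grn_genes(rna)),
                "ribo_pass": len(filter_grn_genes(ribo)),
            }
            regs = select_regulators(tf_ids, rna, ribo)
            qc["regulators"][source] = {"n": len(regs), "ids": regs}
        te = compute_te(atlas.matrices["ribo_mean"], atlas.matrices["rna_mean"])
        unmasked = te.unmasked().to_numpy().ravel()
        unmasked = unmasked[~np.isnan(unmasked)]
        qc["te"] = {
            "median": float(np.median(unmasked)) if unmasked.size else None,
            "fraction_in_quarter_to_four": (
                float(((unmasked >= 0.25) & (unmasked <= 4.0)).mean()) if unmasked.size else None
            ),
        }
        rep_corr = correlation_report(
            atlas.matrices["rna_rep1"], atlas.matrices["rna_rep2"], axis="per_sample_pair"
        )
        gene_corr = correlation_report(
            atlas.matrices["rna_mean"], atlas.matrices["ribo_mean"], axis="per_gene"
        )
        qc["correlations"] = {
            "rna_rep1_vs_rep2_median_r": float(rep_corr["r"].median()),
            "rna_vs_ribo_per_gene_median_r": float(gene_corr["r"].median()),
        }
        segs = detect_segs(atlas.matrices["rna_mean"], atlas.matrices["ribo_mean"])
        qc["segs"] = {
            c: {
                "seg": len(segs.segs(c)),
                "mean_seg": segs.mean_seg(c),
                "n_samples": segs.n_samples[c],
            }
            for c in segs.categories()
        }
        qc_path = outdir / "qc_report.json"
        qc_path.write_text(json.dumps(qc, indent=1, default=_json_default))
        artifacts["qc_report"] = qc_path

        stage = "infer"
        grns: dict[str, dict[str, EdgeList]] = {"mean": {}, "bulked": {}}
        for source in ("mean", "bulked"):
            rna = atlas.matrices[f"rna_{source}"]
            ribo = atlas.matrices[f"ribo_{source}"]
            regulators = qc["regulators"][source]["ids"]
            if not regulators:
                raise RuntimeError(f"no regulators pass the filter in source {source!r}")
            layer_matrix = {"rna": rna, "ribo": ribo}
            for grn_type, (reg_layer, tgt_layer) in GRN_PAIRINGS.items():
                target_matrix = layer_matrix[tgt_layer]
                targets = filter_grn_genes(target_matrix)
                grn = infer_grn(
                    layer_matrix[reg_layer],
                    target_matrix,
                    regulators,
                    targets,
                    n_trees=config.inference.n_trees,
                    k=config.inference.k,
                    seed=substream_seed(inf_seed, f"{grn_type}_{source}"),
                )
                grn = truncate_edges(grn, "top_k", config.truncation.top_k)
                logger.info("infer %s/%s: %d regulators, %d targets, %d edges kept",
                            grn_type, source, len(regulators), len(targets), len(grn))
                path = outdir / f"grn_{grn_type}_{source}.tsv"
                grn.to_tsv(path)
                artifacts[f"grn_{grn_type}_{source}"] = path
                grns[source][grn_type] = grn

        stage = "merge"
        all_lists = [grns[s][t] for s in ("mean", "bulked") for t in ("mm", "TT", "Tm")]
        union = union_networks(all_lists, weight_rule="max")
        hc = build_high_confidence(grns["mean"], grns["bulked"])
        union_path = outdir / "union_grn.tsv"
        union.to_tsv(union_path)
        artifacts["union_grn"] = union_path
        hc_path = outdir / "high_confidence_grn.tsv"
        hc.to_tsv(hc_path)
        artifacts["high_confidence_grn"] = hc_path
        logger.info("merge: union %d pairs, high-confidence %d pairs", len(union), len(hc))

        stage = "topology"
        topo = {}
        for source in ("mean", "bulked"):
            for grn_type in ("mm", "TT", "Tm"):
                topo[f"{grn_type}_{source}"] = topology_metrics(grns[source][grn_type]).to_dict()
        topo["union"] = topology_metrics(union).to_dict()
        if len(hc):
            topo["high_confidence"] = topology_metrics(hc).to_dict()
        topo_path = outdir / "topology.json"
        topo_path.write_text(json.dumps(topo, indent=1, default=_json_default))
        artifacts["topology"] = topo_path

        stage = "benchmark"
        bench: dict = {"seed": bench_seed, "null_iters": config.benchmark.null_iters, "grns": {}}
        per_tf_frames = []
        gold_universe = set(gold.target_universe)
        for source in ("mean", "bulked"):
            for grn_type in ("mm", "TT", "Tm"):
                # benchmark on the edges whose targets the gold standard can
                # possibly contain (TF genes are regulators, not gold targets)
                grn = extract_subnetwork(
                    grns[source][grn_type], target_filter=gold_universe
                )
                label = f"{grn_type}_{source}"
                table, total = overlap_gold(grn, gold)
                null = random_overlap_null(
                    grn,
                    gold,
                    n_iter=config.benchmark.null_iters,
                    seed=substream_seed(bench_seed, label),
                )
                chi = chisq_overlap(total, null.mean, n_pairs=len(grn))
                rocpr = roc_pr_scores(grn, gold, scope="per_tf")
                bench["grns"][label] = {
                    "n_edges": len(grn),
                    "overlap": total,
                    "null_mean": null.mean,
                    "chi2": chi.chi2,
                    "chi2_p": chi.p,
                    "chi2_masked": chi.masked,
                    "mean_auroc": rocpr.mean_auroc,
                    "mean_aupr": rocpr.mean_aupr,
                }
                for norm in ("none", "grn_size", "gold_size"):
                    tf_table = per_tf_overlap_table(grn, gold, normalization=norm)
                    tf_table.insert(0, "grn", label)
                    per_tf_frames.append(tf_table)
            sizes = sorted({len(grns[source][t]) for t in ("mm", "TT", "Tm")})
            thresholds = config.benchmark.thresholds or [
                max(1, int(round(f * sizes[0]))) for f in (0.2, 0.6, 1.0)
            ]
            cmp_table = compare_weights(grns[source], thresholds)
            bench["grns"][f"weight_comparison_{source}"] = cmp_table.to_dict(orient="records")
        bench_path = outdir / "benchmark.json"
        bench_path.write_text(json.dumps(bench, indent=1, default=_json_default))
        artifacts["benchmark"] = bench_path
        per_tf_path = outdir / "benchmark_per_tf.tsv"
        pd.concat(per_tf_frames, ignore_index=True).to_csv(per_tf_path, sep="\t", index=False)
        artifacts["benchmark_per_tf"] = per_tf_path

        stage = "manifest"
        resolved_path = outdir / "config.json"
        resolved = {k: v for k, v in config.to_dict().items() if k != "output_dir"}
        resolved_path.write_text(json.dumps(resolved, indent=1))
        artifacts["config"] = resolved_path
        manifest = {
            "config_fingerprint": config.fingerprint(),
            "artifacts": {
                name: {"path": str(path.relative_to(outdir)), "sha256": _sha256(path)}
                for name, path in sorted(artifacts.items())
            },
        }
        manifest_path = outdir / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=1))
        return manifest
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
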