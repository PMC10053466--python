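"""Synthetic paired transcriptome/translatome atlases with known regulation.

The generator emulates the study design that motivates inter-omics network
inference: transcription factors (TFs) act through their *protein* output,
for which the translatome (ribosome-bound mRNA) is the measurable proxy.
Concretely:

1. TF mRNA abundance per tissue is lognormal with gene baselines,
   tissue-category effects and tissue noise (FPKM scale).
2. TF translatome = TF mRNA x TE(gene, tissue), where log-TE is Normal(0,
   te_sigma) per gene x tissue and the realized TE is clipped to [0.25, 4].
3. A target's transcript abundance is a softplus of a linear combination of
   its regulators' *translatome* levels (signed effect sizes drawn with the
   truth network) plus Gaussian noise, rescaled to an FPKM-like range.
4. A target's translatome is its own mRNA times its own TE.
5. Two measured replicates (and a bulked sample averaging three hidden
   replicates) add independent multiplicative lognormal noise; detection
   dropout zeroes entries at a given rate.

Because target transcription tracks TF translation, networks inferred from
TF translatome profiles (Tm, TT) should recover the truth better than
networks using TF mRNA (mm) whenever translational efficiency decouples the
two layers (te_sigma > 0) — the property the downstream benchmark measures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import softplus, substream_seed
from .atlas import ExpressionMatrix
from .benchmark import GoldStandard

__all__ = [
    "SyntheticTruth",
    "SimulatedAtlas",
    "generate_truth_network",
    "simulate_atlas",
    "make_gold_standard",
    "DEFAULT_CATEGORIES",
]

# Tissue-category vocabulary of a developmental atlas.
DEFAULT_CATEGORIES = (
    "root",
    "inflorescence",
    "stem",
    "seedling",
    "kernel",
    "tassel",
    "SAM",
    "ear",
    "leaf",
)


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth regulatory network: signed TF -> target effects."""

    regulators: tuple[str, ...]
    targets: tuple[str, ...]
    edges: tuple[tuple[str, str, float], ...]  # (tf, target, signed effect)
    seed: int

    def __post_init__(self) -> None:
        regs = set(self.regulators)
        tgts = set(self.targets)
        for tf, target, _ in self.edges:
            if tf not in regs:
                raise ValueError(f"edge TF {tf!r} not among regulators")
            if target not in tgts:
                raise ValueError(f"edge target {target!r} not among targets")
            if tf == target:
                raise ValueError("self-edges are not allowed in the truth network")

    @property
    def pairs(self) -> frozenset[tuple[str, str]]:
        return frozenset((tf, t) for tf, t, _ in self.edges)

    def targets_of(self, tf: str) -> list[str]:
        return sorted(t for f, t, _ in self.edges if f == tf)

    def out_degrees(self) -> dict[str, int]:
        deg = {tf: 0 for tf in self.regulators}
        for tf, _, _ in self.edges:
            deg[tf] += 1
        return deg

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(list(self.edges), columns=["tf", "target", "effect"]).to_csv(
            path, sep="\t", index=False
        )


def generate_truth_network(
    n_tf: int, n_target: int, mean_out_degree: float, seed: int
) -> SyntheticTruth:
    """Sample a ground-truth network with heavy-tailed TF out-degrees.

    Out-degree mass is allotted from a Pareto draw, so a few hub TFs carry
    many targets while most TFs have few — the degree structure typical of
    transcriptional networks. The total edge count is approximately
    ``n_tf * mean_out_degree``.
    """
    if n_tf < 2:
        raise ValueError("n_tf must be at least 2")
    if n_target < n_tf:
        raise ValueError("n_target must be at least n_tf")
    if mean_out_degree <= 0:
        raise ValueError("mean_out_degree must be positive")
    rng = np.random.default_rng(substream_seed(seed, "truth"))
    regulators = tuple(f"TF{i:04d}" for i in range(n_tf))
    targets = tuple(f"G{i:05d}" for i in range(n_target))
    share = 1.0 + rng.pareto(1.5, size=n_tf)
    degrees = np.rint(share / share.sum() * n_tf * mean_out_degree)
    degrees = np.clip(degrees, 1, n_target).astype(int)
    edges: list[tuple[str, str, float]] = []
    for i, tf in enumerate(regulators):
        chosen = rng.choice(n_target, size=degrees[i], replace=False)
        magnitudes = rng.uniform(0.5, 1.5, size=degrees[i])
        signs = np.where(rng.random(degrees[i]) < 0.7, 1.0, -1.0)  # mostly activators
        for j, m, s in zip(sorted(chosen), magnitudes, signs):
            edges.append((tf, targets[j], float(m * s)))
    return SyntheticTruth(regulators=regulators, targets=targets, edges=tuple(edges), seed=seed)


@dataclass
class SimulatedAtlas:
    """Simulated paired atlas: six measured matrices plus ground truth.

    ``matrices`` holds the six measured layers (``rna_rep1``, ``rna_rep2``,
    ``ribo_rep1``, ``ribo_rep2``, ``rna_bulked``, ``ribo_bulked``) and the
    convenience ``rna_mean`` / ``ribo_mean`` (mean of the two replicates).
    ``te_profile`` is the realized gene x tissue translational efficiency.
    """

    matrices: dict[str, ExpressionMatrix]
    metadata: pd.DataFrame
    te_profile: pd.DataFrame
    truth: SyntheticTruth
    params: dict = field(default_factory=dict)

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written: dict[str, Path] = {}
        for name, matrix in sorted(self.matrices.items()):
            path = outdir / f"{name}.tsv"
            matrix.to_tsv(path)
            written[name] = path
        meta_path = outdir / "metadata.tsv"
        meta = self.metadata.copy()
        meta.index.name = "sample_id"
        meta.to_csv(meta_path, sep="\t")
        written["metadata"] = meta_path
        te_path = outdir / "te_profile.tsv"
        te = self.te_profile.copy()
        te.index.name = "gene"
        te.to_csv(te_path, sep="\t")
        written["te_profile"] = te_path
        truth_path = outdir / "truth_edges.tsv"
        self.truth.to_tsv(truth_path)
        written["truth_edges"] = truth_path
        return written


def _tissue_labels(n_tissues: int, categories: tuple[str, ...]) -> tuple[list[str], list[str]]:
    labels, cats = [], []
    counts: dict[str, int] = {}
    for i in range(n_tissues):
        cat = categories[i % len(categories)]
        counts[cat] = counts.get(cat, 0) + 1
        labels.append(f"{cat}_{counts[cat]}")
        cats.append(cat)
    return labels, cats


def simulate_atlas(
    truth: SyntheticTruth,
    n_tissues: int = 12,
    categories: tuple[str, ...] = DEFAULT_CATEGORIES,
    te_sigma: float = 1.0,
    noise_sd: float = 0.25,
    detection_dropout: float = 0.02,
    te_bounds: tuple[float, float] = (0.25, 4.0),
    seed: int = 0,
) -> SimulatedAtlas:
    """Simulate the paired transcriptome/translatome atlas for a truth network.

    Parameters
    ----------
    te_sigma
        Standard deviation of log translational efficiency per gene x tissue;
        0 collapses the two omics layers (TE identically 1 after clipping).
    noise_sd
        Standard deviation of the Gaussian noise on the target drive and of
        the log-scale replicate noise.
    detection_dropout
        Probability that any measured (gene, sample) entry is zeroed,
        mimicking detection failure.
    te_bounds
        Clipping range for realized TE; the default matches the bulk of
        translational-efficiency values seen in real paired atlases.
    """
    if te_sigma < 0:
        raise ValueError("te_sigma must be nonnegative")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    if not 0 <= detection_dropout < 1:
        raise ValueError("detection_dropout must be in [0, 1)")
    if n_tissues < 1:
        raise ValueError("n_tissues must be positive")
    if not categories:
        raise ValueError("categories must be nonempty")

    tissues, cats = _tissue_labels(n_tissues, tuple(categories))
    cat_index = {c: i for i, c in enumerate(dict.fromkeys(cats))}
    cat_idx = np.array([cat_index[c] for c in cats])

    genes = list(truth.regulators) + list(truth.targets)
    n_reg, n_tgt = len(truth.regulators), len(truth.targets)
    G, T = len(genes), n_tissues

    rng_base = np.random.default_rng(substream_seed(seed, "baseline"))
    rng_te = np.random.default_rng(substream_seed(seed, "te"))
    rng_noise = np.random.default_rng(substream_seed(seed, "target_noise"))
    rng_scale = np.random.default_rng(substream_seed(seed, "target_scale"))
    rng_rep = np.random.default_rng(substream_seed(seed, "replicates"))
    rng_drop = np.random.default_rng(substream_seed(seed, "dropout"))

    # (1) lognormal FPKM-scale baselines with tissue-category structure
    mu = rng_base.normal(np.log(20.0), 1.0, size=G)
    cat_effect = rng_base.normal(0.0, 0.8, size=(G, len(cat_index)))
    tissue_noise = rng_base.normal(0.0, 0.3, size=(G, T))
    log_base = mu[:, None] + cat_effect[:, cat_idx] + tissue_noise

    # (2) translational efficiency per gene x tissue, clipped to a realistic range
    te = np.exp(rng_te.normal(0.0, te_sigma, size=(G, T))) if te_sigma > 0 else np.ones((G, T))
    te = np.clip(te, te_bounds[0], te_bounds[1])

    rna_tf = np.exp(log_base[:n_reg])
    ribo_tf = rna_tf * te[:n_reg]

    # (3) target transcription driven by regulator translatome levels
    log_ribo_tf = np.log1p(ribo_tf)
    z_mean = log_ribo_tf.mean(axis=1, keepdims=True)
    z_sd = log_ribo_tf.std(axis=1, keepdims=True)
    z = np.where(z_sd > 0, (log_ribo_tf - z_mean) / np.where(z_sd > 0, z_sd, 1.0), 0.0)

    reg_pos = {tf: i for i, tf in enumerate(truth.regulators)}
    tgt_pos = {t: i for i, t in enumerate(truth.targets)}
    beta = np.zeros((n_tgt, n_reg))
    for tf, target, effect in truth.edges:
        beta[tgt_pos[target], reg_pos[tf]] = effect
    in_degree = np.maximum((beta != 0).sum(axis=1), 1)
    drive = (beta @ z) / np.sqrt(in_degree)[:, None]
    if noise_sd > 0:
        drive = drive + rng_noise.normal(0.0, noise_sd, size=drive.shape)
    raw = softplus(drive)
    base_tgt = np.exp(rng_scale.normal(np.log(20.0), 1.0, size=n_tgt))
    rna_tgt = raw * (base_tgt / raw.mean(axis=1))[:, None]
    ribo_tgt = rna_tgt * te[n_reg:]

    latent = {
        "rna": np.vstack([rna_tf, rna_tgt]),
        "ribo": np.vstack([ribo_tf, ribo_tgt]),
    }

    def noisy(arr: np.ndarray) -> np.ndarray:
        if noise_sd == 0:
            return arr.copy()
        return arr * np.exp(rng_rep.normal(0.0, noise_sd, size=arr.shape))

    # (5) measured replicates and a bulked sample (mean of 3 hidden replicates)
    measured: dict[str, np.ndarray] = {}
    for layer in ("rna", "ribo"):
        measured[f"{layer}_rep1"] = noisy(latent[layer])
        measured[f"{layer}_rep2"] = noisy(latent[layer])
        measured[f"{layer}_bulked"] = np.mean(
            [noisy(latent[layer]) for _ in range(3)], axis=0
        )

    # (6) detection dropout, independent per measured matrix
    for name in ("rna_rep1", "rna_rep2", "rna_bulked", "ribo_rep1", "ribo_rep2", "ribo_bulked"):
        if detection_dropout > 0:
            keep = rng_drop.random(size=measured[name].shape) >= detection_dropout
            measured[name] = measured[name] * keep

    metadata = pd.DataFrame({"tissue_category": cats}, index=pd.Index(tissues, name="sample_id"))

    def as_matrix(name: str, arr: np.ndarray) -> ExpressionMatrix:
        layer, source = name.split("_")
        return ExpressionMatrix(
            values=pd.DataFrame(arr, index=genes, columns=tissues),
            omics="transcriptome" if layer == "rna" else "translatome",
            source=source,
            metadata=metadata,
        )

    matrices = {name: as_matrix(name, arr) for name, arr in measured.items()}
    for layer in ("rna", "ribo"):
        mean_vals = (measured[f"{layer}_rep1"] + measured[f"{layer}_rep2"]) / 2.0
        matrices[f"{layer}_mean"] = ExpressionMatrix(
            values=pd.DataFrame(mean_vals, index=genes, columns=tissues),
            omics="transcriptome" if layer == "rna" else "translatome",
            source="mean",
            metadata=metadata,
        )

    te_profile = pd.DataFrame(te, index=genes, columns=tissues)
    params = {
        "n_tissues": n_tissues,
        "categories": list(dict.fromkeys(cats)),
        "te_sigma": te_sigma,
        "noise_sd": noise_sd,
        "detection_dropout": detection_dropout,
        "te_bounds": list(te_bounds),
        "seed": seed,
    }
    return SimulatedAtlas(
        matrices=matrices, metadata=metadata, te_profile=te_profile, truth=truth, params=params
    )


def make_gold_standard(
    truth: SyntheticTruth,
    observed_fraction: float = 1.0,
    spurious_fraction: float = 0.0,
    seed: int = 0,
) -> GoldStandard:
    """Degrade the truth network into a ChIP-seq-like gold standard.

    Per TF with ``d`` true targets, ``round(observed_fraction * d)`` of them
    are kept (binding assays miss targets) and ``round(spurious_fraction *
    kept)`` non-targets are added (binding without regulation). With
    ``observed_fraction=1`` and ``spurious_fraction=0`` the gold standard
    equals the truth edge set.
    """
    if not 0 < observed_fraction <= 1:
        raise ValueError("observed_fraction must be in (0, 1]")
    if spurious_fraction < 0:
        raise ValueError("spurious_fraction must be nonnegative")
    if not truth.edges:
        raise ValueError("truth network has no edges")
    rng = np.random.default_rng(substream_seed(seed, "gold"))
    all_targets = set(truth.targets)
    mapping: dict[str, frozenset[str]] = {}
    for tf in truth.regulators:
        true_targets = truth.targets_of(tf)
        if not true_targets:
            continue
        n_obs = round(observed_fraction * len(true_targets))
        observed = rng.choice(true_targets, size=n_obs, replace=False) if n_obs else []
        n_spur = round(spurious_fraction * n_obs)
        pool = sorted(all_targets - set(true_targets) - {tf})
        spurious = (
            rng.choice(pool, size=min(n_spur, len(pool)), replace=False) if n_spur else []
        )
        mapping[tf] = frozenset(observed) | frozenset(spurious)
    return GoldStandard(
        targets_by_tf=mapping,
        tf_universe=truth.regulators,
        target_universe=truth.targets,
    )
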