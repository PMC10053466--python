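"""Expression-atlas containers and quality control for paired omics layers.

The atlas holds gene x sample FPKM abundances for two omics layers — the
transcriptome (RNA-seq) and the translatome (Ribo-seq, ribosome-protected
fragments) — sampled across tissues of a developmental atlas. This module
loads and validates those matrices and implements the standard atlas-level
analyses: the gene filter used before network inference, regulator (TF)
selection, translational efficiency (TE = ribo / rna), tissue-specifically
expressed genes (SEGs), and Pearson correlation reports within and across
layers.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

OMICS_LAYERS = ("transcriptome", "translatome")
DATA_SOURCES = ("mean", "bulked", "rep1", "rep2")

__all__ = [
    "ExpressionMatrix",
    "TEMatrix",
    "SegReport",
    "harmonize",
    "filter_grn_genes",
    "select_regulators",
    "compute_te",
    "detect_segs",
    "correlation_report",
    "read_metadata",
]


@dataclass
class ExpressionMatrix:
    """A gene x sample FPKM matrix with omics-layer and data-source labels.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with sample ids as columns. Entries must
        be finite and nonnegative (FPKM scale).
    omics
        ``"transcriptome"`` or ``"translatome"``.
    source
        ``"mean"``, ``"bulked"``, ``"rep1"`` or ``"rep2"``.
    metadata
        Optional per-sample table indexed by sample id with at least a
        ``tissue_category`` column.
    """

    values: pd.DataFrame
    omics: str
    source: str
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.omics not in OMICS_LAYERS:
            raise ValueError(f"omics must be one of {OMICS_LAYERS}, got {self.omics!r}")
        if self.source not in DATA_SOURCES:
            raise ValueError(f"source must be one of {DATA_SOURCES}, got {self.source!r}")
        vals = self.values
        if not isinstance(vals, pd.DataFrame):
            raise TypeError("values must be a pandas DataFrame (genes x samples)")
        if vals.index.has_duplicates:
            raise ValueError("duplicate gene ids in expression matrix")
        if vals.columns.has_duplicates:
            raise ValueError("duplicate sample ids in expression matrix")
        arr = vals.to_numpy(dtype=float, copy=False)
        if not np.isfinite(arr).all():
            raise ValueError("expression values must be finite")
        if (arr < 0).any():
            raise ValueError("expression values must be nonnegative (FPKM)")
        if self.metadata is not None:
            missing = vals.columns.difference(self.metadata.index)
            if len(missing):
                raise ValueError(f"samples missing from metadata: {list(missing)[:5]}")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def categories(self) -> pd.Series:
        """Tissue category per sample (requires metadata)."""
        if self.metadata is None:
            raise ValueError("no metadata attached to this matrix")
        return self.metadata.loc[self.samples, "tissue_category"]

    def to_tsv(self, path: str | Path) -> None:
        """Write as gene-by-sample TSV, first column ``gene``."""
        out = self.values.copy()
        out.index.name = "gene"
        out.to_csv(path, sep="\t")

    @classmethod
    def read_tsv(
        cls,
        path: str | Path,
        omics: str,
        source: str,
        metadata: pd.DataFrame | None = None,
    ) -> "ExpressionMatrix":
        vals = pd.read_csv(path, sep="\t", index_col=0)
        vals.index = vals.index.astype(str).rename(None)
        return cls(values=vals, omics=omics, source=source, metadata=metadata)


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read a sample metadata TSV (columns: sample_id, tissue_category[, source])."""
    meta = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in meta.columns or "tissue_category" not in meta.columns:
        raise ValueError("metadata must have sample_id and tissue_category columns")
    if meta["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in metadata")
    return meta.set_index("sample_id")


def harmonize(a: ExpressionMatrix, b: ExpressionMatrix) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Restrict a pair of matrices to their shared gene universe.

    Paired layers must already cover the same samples; gene sets are reduced
    to the intersection (in ``a``'s order) and dropped ids are logged.
    """
    if set(a.samples) != set(b.samples):
        raise ValueError("paired matrices must share the same sample set")
    shared = a.genes.intersection(b.genes)
    shared = a.genes[a.genes.isin(shared)]  # preserve a's order
    for m in (a, b):
        dropped = m.genes.difference(shared)
        if len(dropped):
            logger.info("harmonize: dropping %d genes from %s/%s", len(dropped), m.omics, m.source)
    a2 = ExpressionMatrix(a.values.loc[shared], a.omics, a.source, a.metadata)
    b2 = ExpressionMatrix(b.values.loc[shared, a.samples], b.omics, b.source, b.metadata)
    return a2, b2


def _detected(values: np.ndarray, detect_min: float) -> np.ndarray:
    # Detection means strictly positive FPKM and at least detect_min;
    # with the default detect_min=0 this is simply FPKM > 0.
    return (values >= detect_min) & (values > 0)


def filter_grn_genes(
    matrix: ExpressionMatrix, fpkm_min: float = 1.0, min_nonzero: int = 3
) -> list[str]:
    """Genes eligible for network inference.

    Keeps genes whose maximum FPKM across samples is at least ``fpkm_min``
    and that are non-zero in at least ``min_nonzero`` samples. Returns gene
    ids in matrix order.
    """
    vals = matrix.values.to_numpy(dtype=float)
    if matrix.values.shape[1] < min_nonzero:
        warnings.warn(
            f"matrix has {matrix.values.shape[1]} samples < min_nonzero={min_nonzero}; "
            "no gene can pass the non-zero filter",
            stacklevel=2,
        )
    keep = (vals.max(axis=1) >= fpkm_min) & ((vals > 0).sum(axis=1) >= min_nonzero)
    return list(matrix.genes[keep])


def select_regulators(
    tf_ids: list[str],
    rna: ExpressionMatrix,
    ribo: ExpressionMatrix,
    fpkm_min: float = 1.0,
    min_nonzero: int = 3,
) -> list[str]:
    """TFs detectable at both the transcriptome and translatome levels.

    A TF qualifies as a regulator only if it passes :func:`filter_grn_genes`
    in *both* paired matrices.
    """
    if not len(tf_ids):
        raise ValueError("tf_ids is empty")
    rna2, ribo2 = harmonize(rna, ribo)
    present = [t for t in tf_ids if t in rna2.genes]
    if not present:
        warnings.warn("none of the supplied TF ids are present in the matrices", stacklevel=2)
        return []
    ok_rna = set(filter_grn_genes(rna2, fpkm_min, min_nonzero))
    ok_ribo = set(filter_grn_genes(ribo2, fpkm_min, min_nonzero))
    return [t for t in present if t in ok_rna and t in ok_ribo]


@dataclass
class TEMatrix:
    """Translational efficiency (ribo FPKM / rna FPKM) per gene x sample.

    Entries where the transcript denominator falls below the detection
    threshold are masked (NaN in ``values``, True in ``mask``).
    """

    values: pd.DataFrame
    mask: pd.DataFrame
    detect_min: float

    def unmasked(self) -> pd.DataFrame:
        return self.values.where(~self.mask)

    def to_tsv(self, path: str | Path) -> None:
        out = self.values.copy()
        out.index.name = "gene"
        out.to_csv(path, sep="\t")


def compute_te(
    ribo: ExpressionMatrix, rna: ExpressionMatrix, detect_min: float = 0.0
) -> TEMatrix:
    """TE(g, s) = ribo(g, s) / rna(g, s) where the transcript is detected.

    Entries with rna below ``detect_min`` (or exactly zero) are masked rather
    than propagated as infinities.
    """
    if list(ribo.samples) != list(rna.samples):
        if set(ribo.samples) != set(rna.samples):
            raise ValueError("ribo and rna matrices must share the same sample set")
        ribo = ExpressionMatrix(ribo.values[rna.samples], ribo.omics, ribo.source, ribo.metadata)
    ribo2, rna2 = harmonize(ribo, rna)
    r = rna2.values.to_numpy(dtype=float)
    ok = _detected(r, detect_min)
    with np.errstate(divide="ignore", invalid="ignore"):
        te = np.where(ok, ribo2.values.to_numpy(dtype=float) / np.where(ok, r, 1.0), np.nan)
    values = pd.DataFrame(te, index=rna2.genes, columns=rna2.samples)
    mask = pd.DataFrame(~ok, index=rna2.genes, columns=rna2.samples)
    return TEMatrix(values=values, mask=mask, detect_min=detect_min)


@dataclass
class SegReport:
    """Tissue-specifically expressed genes (SEGs) per category.

    A gene is *specifically transcribed* (or translated) in a category when
    it is detected in at least one sample of that category and in no sample
    of any other category, within the given layer. The SEG set of a category
    is the union over the two layers; ``both`` is their intersection.
    """

    transcribed: dict[str, frozenset[str]]
    translated: dict[str, frozenset[str]]
    n_samples: dict[str, int]
    detect_min: float = 0.0

    def categories(self) -> list[str]:
        return sorted(self.n_samples)

    def segs(self, category: str) -> frozenset[str]:
        return self.transcribed[category] | self.translated[category]

    def both(self, category: str) -> frozenset[str]:
        return self.transcribed[category] & self.translated[category]

    def mean_seg(self, category: str) -> float:
        return len(self.segs(category)) / self.n_samples[category]

    def summary(self) -> pd.DataFrame:
        rows = []
        for c in self.categories():
            rows.append(
                {
                    "category": c,
                    "n_samples": self.n_samples[c],
                    "specifically_transcribed": len(self.transcribed[c]),
                    "specifically_translated": len(self.translated[c]),
                    "both": len(self.both(c)),
                    "seg": len(self.segs(c)),
                    "mean_seg": self.mean_seg(c),
                }
            )
        return pd.DataFrame(rows)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "detect_min": self.detect_min,
            "categories": {
                c: {
                    "n_samples": self.n_samples[c],
                    "specifically_transcribed": sorted(self.transcribed[c]),
                    "specifically_translated": sorted(self.translated[c]),
                }
                for c in self.categories()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _specific_by_category(
    matrix: ExpressionMatrix, categories: pd.Series, detect_min: float
) -> dict[str, frozenset[str]]:
    det = pd.DataFrame(
        _detected(matrix.values.to_numpy(dtype=float), detect_min),
        index=matrix.genes,
        columns=matrix.samples,
    )
    by_cat = det.T.groupby(categories.loc[matrix.samples]).any().T  # gene x category
    n_cats_detected = by_cat.sum(axis=1)
    out: dict[str, frozenset[str]] = {}
    for cat in by_cat.columns:
        specific = by_cat.index[(by_cat[cat]) & (n_cats_detected == 1)]
        out[str(cat)] = frozenset(specific)
    return out


def detect_segs(
    rna: ExpressionMatrix,
    ribo: ExpressionMatrix,
    detect_min: float = 0.0,
    metadata: pd.DataFrame | None = None,
) -> SegReport:
    """Identify specifically transcribed / translated genes per tissue category.

    ``metadata`` (or the matrices' attached metadata) assigns each sample to
    a tissue category; SEG counts are normalized by the number of samples per
    category to give the mean-SEG statistic.
    """
    meta = metadata if metadata is not None else rna.metadata
    if meta is None:
        raise ValueError("sample metadata with tissue_category is required")
    missing = rna.samples.difference(meta.index)
    if len(missing):
        raise ValueError(f"samples without a tissue category: {list(missing)[:5]}")
    categories = meta.loc[rna.samples, "tissue_category"]
    if categories.nunique() < 2:
        warnings.warn(
            "only one tissue category present: every detected gene is trivially specific",
            stacklevel=2,
        )
    transcribed = _specific_by_category(rna, categories, detect_min)
    translated = _specific_by_category(ribo, categories, detect_min)
    all_cats = sorted(set(transcribed) | set(translated))
    empty: frozenset[str] = frozenset()
    n_samples = categories.value_counts().to_dict()
    return SegReport(
        transcribed={c: transcribed.get(c, empty) for c in all_cats},
        translated={c: translated.get(c, empty) for c in all_cats},
        n_samples={str(c): int(n_samples.get(c, 0)) for c in all_cats},
        detect_min=detect_min,
    )


def _pearson_rows(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Pearson r between two equally shaped arrays.

    Returns (r, defined) where ``defined`` is False for rows with fewer than
    3 columns or zero variance in either profile.
    """
    n = a.shape[1]
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    sa = np.sqrt((ac**2).sum(axis=1))
    sb = np.sqrt((bc**2).sum(axis=1))
    defined = (sa > 0) & (sb > 0) & (n >= 3)
    denom = np.where(defined, sa * sb, 1.0)
    r = np.where(defined, (ac * bc).sum(axis=1) / denom, np.nan)
    return r, defined


def correlation_report(
    a: ExpressionMatrix, b: ExpressionMatrix, axis: str = "per_gene"
) -> pd.DataFrame:
    """Pearson correlations between two matrices.

    axis="per_gene"
        One r per shared gene, across shared samples (e.g. cross-omics
        agreement of a gene's tissue profile).
    axis="per_sample_pair"
        One r per shared sample, across shared genes (e.g. replicate
        agreement of a tissue's expression profile).

    Profiles with zero variance or fewer than 3 observations are reported
    with ``r = NaN`` and a ``reason``, never propagated as errors.
    """
    if axis not in ("per_gene", "per_sample_pair"):
        raise ValueError("axis must be 'per_gene' or 'per_sample_pair'")
    genes = a.genes.intersection(b.genes)
    samples = a.samples.intersection(b.samples)
    if axis == "per_gene":
        if len(samples) == 0:
            raise ValueError("per_gene correlations need shared samples")
        av = a.values.loc[genes, samples].to_numpy(dtype=float)
        bv = b.values.loc[genes, samples].to_numpy(dtype=float)
        ids = genes
        n_obs = len(samples)
    else:
        if len(genes) == 0:
            raise ValueError("per_sample_pair correlations need shared genes")
        av = a.values.loc[genes, samples].to_numpy(dtype=float).T
        bv = b.values.loc[genes, samples].to_numpy(dtype=float).T
        ids = samples
        n_obs = len(genes)
    r, defined = _pearson_rows(av, bv)
    reason = np.where(defined, "", "fewer than 3 observations" if n_obs < 3 else "zero variance")
    return pd.DataFrame({"id": list(ids), "r": r, "n": n_obs, "reason": reason})
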