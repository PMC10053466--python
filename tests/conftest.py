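from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import mogrn
from mogrn.atlas import ExpressionMatrix
from mogrn.inference import EdgeList

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_matrix(
    data: dict[str, list[float]],
    samples: list[str] | None = None,
    omics: str = "transcriptome",
    source: str = "mean",
    categories: list[str] | None = None,
) -> ExpressionMatrix:
    """Build a small ExpressionMatrix from a gene -> profile mapping."""
    n = len(next(iter(data.values())))
    samples = samples or [f"s{i}" for i in range(n)]
    meta = None
    if categories is not None:
        meta = pd.DataFrame({"tissue_category": categories},
                            index=pd.Index(samples, name="sample_id"))
    values = pd.DataFrame({s: [data[g][i] for g in data] for i, s in enumerate(samples)},
                          index=list(data))
    return ExpressionMatrix(values=values, omics=omics, source=source, metadata=meta)


def make_edges(pairs_weights: list[tuple[str, str, float]], **kw) -> EdgeList:
    df = pd.DataFrame(pairs_weights, columns=["regulator", "target", "weight"])
    return EdgeList(df, **kw)


@pytest.fixture(scope="session")
def small_truth():
    return mogrn.generate_truth_network(10, 60, 4.0, seed=11)


@pytest.fixture(scope="session")
def small_atlas(small_truth):
    return mogrn.simulate_atlas(small_truth, n_tissues=12, te_sigma=1.0,
                                noise_sd=0.25, detection_dropout=0.02, seed=11)
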