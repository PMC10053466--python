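"""Small shared helpers: seed substreams and numerics."""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream_seed", "softplus"]


def substream_seed(seed: int, label: str) -> int:
    """Derive a deterministic child seed for a named stage.

    Stages (simulation, inference, benchmarking) draw from independent
    substreams so one stage can be re-seeded without perturbing the others.
    The result is kept below 2**31 so it is valid wherever a 32-bit seed is
    expected.
    """
    return (int(seed) * 1_000_003 + zlib.crc32(label.encode("utf-8"))) % (2**31 - 1)


def softplus(x):
    """Numerically stable log(1 + exp(x))."""
    return np.logaddexp(0.0, np.asarray(x, dtype=float))
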