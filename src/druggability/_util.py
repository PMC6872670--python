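"""Shared numeric helpers: percentiles, seeded substreams, logging setup."""

from __future__ import annotations

import logging
import math
import zlib

import numpy as np

log = logging.getLogger("druggability")


def nearest_rank_percentile(values, q: float) -> float:
    """Nearest-rank q-percentile: the value at 1-based index ceil(q*n) of the
    sorted sample.

    Deterministic and always a member of the sample, which keeps integer
    cutoffs (drug counts, node degrees) integral.  q must lie in (0, 1].
    """
    if not 0.0 < q <= 1.0:
        raise ValueError(f"percentile fraction must be in (0, 1], got {q}")
    arr = np.sort(np.asarray(values))
    if arr.size == 0:
        raise ValueError("cannot take a percentile of an empty sample")
    idx = max(1, math.ceil(q * arr.size))
    return arr[idx - 1].item()


def iqr(values) -> float:
    """Interquartile range P75 - P25 under the nearest-rank convention."""
    return nearest_rank_percentile(values, 0.75) - nearest_rank_percentile(values, 0.25)


def substream(seed: int, name: str) -> np.random.Generator:
    """Named child RNG so every pipeline stage draws from its own stream.

    All randomness in the package flows from one top-level seed through these
    substreams; re-running a stage with the same (seed, name) pair reproduces
    its draws regardless of what other stages consumed.
    """
    return np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(name.encode())]))


def substream_seed(seed: int, name: str) -> int:
    """A derived integer seed (< 2**31) for APIs that want a plain int."""
    return (zlib.crc32(name.encode()) ^ (int(seed) * 2654435761)) % (2**31)
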