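"""Seed plumbing: one root seed, named per-stage substreams.

Every stochastic stage draws from ``substream(seed, "stage-name")`` so stages
are individually reproducible and insensitive to each other's draw counts.
"""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, name: str) -> np.random.Generator:
    """Deterministic generator for a named stage derived from the root seed."""
    tag = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, tag]))


def as_rng(rng_or_seed) -> np.random.Generator:
    """Coerce an int seed or Generator to a Generator."""
    if isinstance(rng_or_seed, np.random.Generator):
        return rng_or_seed
    return np.random.default_rng(rng_or_seed)
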