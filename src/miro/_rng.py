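"""Seeded random-stream management.

All stochastic code in the package draws from ``numpy.random.Generator``
instances obtained here. A single root seed is combined with a stream
name so that independent stages (simulation, augmentation, weight
initialization, training shuffles) consume independent, reproducible
streams.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "as_rng"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a generator for the named stream derived from ``seed``.

    The same ``(seed, name)`` pair always yields an identical stream;
    different names yield statistically independent streams.
    """
    tag = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, tag]))


def as_rng(seed_or_rng) -> np.random.Generator:
    """Coerce an int seed, ``None`` or a Generator into a Generator."""
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)
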