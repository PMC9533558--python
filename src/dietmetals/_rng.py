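"""Deterministic named substreams derived from one root seed.

Every source of randomness in the package draws from a generator obtained
through :func:`substream`, so a single integer seed reproduces a whole run
(cohort generation, Monte-Carlo oracle, bootstrap) bit for bit.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "child_seed"]


def child_seed(seed: int, name: str) -> int:
    """A stable 32-bit child seed for stream ``name`` under root ``seed``."""
    return zlib.crc32(f"{int(seed)}:{name}".encode()) & 0x7FFFFFFF


def substream(seed: int, name: str) -> np.random.Generator:
    """Generator for the named substream of a root seed.

    Identical (seed, name) pairs always return an identically-seeded
    generator; distinct names give statistically independent streams.
    """
    return np.random.default_rng(np.random.SeedSequence([int(seed), child_seed(seed, name)]))
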