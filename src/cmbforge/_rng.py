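"""Seed management.

All randomness in the package flows from a single master seed through named
substreams, so that every stage of a pipeline run is independently
reproducible and insensitive to the order in which other stages consume
random numbers.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "spawn_seed"]


def spawn_seed(master_seed: int, name: str) -> int:
    """Derive a child seed < 2**31 from a master seed and a stream name."""
    tag = zlib.crc32(name.encode("utf-8"))
    ss = np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, tag])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def substream(master_seed: int, name: str) -> np.random.Generator:
    """A :class:`numpy.random.Generator` for the named substream."""
    return np.random.default_rng(spawn_seed(master_seed, name))
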