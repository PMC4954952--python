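"""Seed plumbing: every stage draws from a named substream of one seed.

Substreams are derived by combining the user seed with CRC32 hashes of the
stage names, so changing one stage's stream never perturbs another's.
"""

from __future__ import annotations

import zlib

import numpy as np


def substream_entropy(seed: int, *names) -> list[int]:
    words = [int(seed) & 0x7FFFFFFF]
    for name in names:
        if isinstance(name, (int, np.integer)):
            words.append(int(name) & 0x7FFFFFFF)
        else:
            words.append(zlib.crc32(str(name).encode()) & 0x7FFFFFFF)
    return words


def substream(seed: int, *names) -> np.random.Generator:
    """Generator for the substream identified by ``names`` under ``seed``."""
    return np.random.default_rng(substream_entropy(seed, *names))


def derived_seed(seed: int, *names) -> int:
    """A stable integer seed (< 2**31) for the named substream."""
    out = int(seed) & 0x7FFFFFFF
    for word in substream_entropy(seed, *names)[1:]:
        out = (out * 1000003 + word) & 0x7FFFFFFF
    return out


def ensure_rng(rng_or_seed) -> np.random.Generator:
    if isinstance(rng_or_seed, np.random.Generator):
        return rng_or_seed
    return np.random.default_rng(rng_or_seed)
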