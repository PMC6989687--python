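"""Named random substreams.

All randomness in the package flows from one top-level integer seed. Each
consumer asks for a named substream, so adding a new stream (or reordering
calls) never perturbs the draws of an existing one.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a generator for the substream ``name`` under ``seed``.

    The stream key is a CRC32 of the name combined with the seed through a
    :class:`numpy.random.SeedSequence`, so distinct names give statistically
    independent streams and identical (seed, name) pairs give bit-identical
    draws.
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))
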