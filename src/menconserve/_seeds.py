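"""Deterministic seed derivation for all stochastic stages.

Every randomized operation in the package accepts an integer seed. Stages
that need several independent streams derive child seeds from a master seed
through :class:`numpy.random.SeedSequence` with a stage-specific spawn key,
so a single run-level seed reproduces the whole analysis bit-for-bit.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_seed", "rng_for"]


def _key_to_int(key: object) -> int:
    """Map an arbitrary hashable label (str, int, tuple) to a stable uint32."""
    if isinstance(key, (int, np.integer)):
        return int(key) & 0xFFFFFFFF
    return zlib.crc32(repr(key).encode("utf-8")) & 0xFFFFFFFF


def child_seed(master: int, *keys: object) -> np.random.SeedSequence:
    """Derive a reproducible child SeedSequence from a master seed and labels."""
    return np.random.SeedSequence(
        entropy=int(master) & 0xFFFFFFFF,
        spawn_key=tuple(_key_to_int(k) for k in keys),
    )


def rng_for(master: int, *keys: object) -> np.random.Generator:
    """A Generator seeded deterministically from (master, *keys)."""
    return np.random.default_rng(child_seed(master, *keys))
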