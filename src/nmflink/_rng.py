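"""Seed derivation helpers.

All randomness in the package flows from a single integer master seed.
Sub-streams are derived from (seed, *keys) tuples so that independent
stages (splits, replicates, methods) get independent, order-insensitive
generators.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["derive_rng", "derive_seed_sequence"]


def _as_int(key: int | str) -> int:
    if isinstance(key, str):
        return zlib.crc32(key.encode("utf-8"))
    return int(key)


def derive_seed_sequence(seed: int, *keys: int | str) -> np.random.SeedSequence:
    """Build a SeedSequence from a master seed plus arbitrary sub-keys."""
    return np.random.SeedSequence([_as_int(seed), *(_as_int(k) for k in keys)])


def derive_rng(seed: int, *keys: int | str) -> np.random.Generator:
    """A Generator seeded from (seed, *keys); same inputs, same stream."""
    return np.random.default_rng(derive_seed_sequence(seed, *keys))
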