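"""Deterministic seed derivation.

All randomness in the package flows through :class:`numpy.random.Generator`
streams derived from a single integer seed, so that every experiment —
including per-richness points of a feasibility curve and per-replicate
community draws — is reproducible and extensible without global state.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["spawn_rng", "as_rng"]


def _key_to_int(key: object) -> int:
    if isinstance(key, (int, np.integer)):
        if key < 0:
            raise ValueError("seed keys must be non-negative integers")
        return int(key)
    if isinstance(key, str):
        return zlib.crc32(key.encode("utf-8"))
    raise TypeError(f"unsupported seed key type: {type(key)!r}")


def spawn_rng(base_seed: int, *keys: object) -> np.random.Generator:
    """Create an independent generator from a base seed plus context keys.

    Keys may be non-negative integers (e.g. species richness, replicate
    index) or short strings naming the consumer (e.g. ``"structural"``).
    Identical (seed, keys) always yields an identical stream; distinct key
    tuples yield statistically independent streams.
    """
    entropy = [_key_to_int(base_seed)] + [_key_to_int(k) for k in keys]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def as_rng(seed_or_rng) -> np.random.Generator:
    """Coerce an int seed, Generator, or None into a Generator."""
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)
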