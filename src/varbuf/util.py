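"""Shared helpers: deterministic random streams and small numeric utilities.

All randomness in the package flows from a single integer seed. Named
sub-streams are derived with :func:`child_seed` so every stage (simulation,
model fitting, tie-breaking, ...) can be regenerated independently without
consuming from a shared global stream.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_seed", "rng", "geometric_mean"]


def _key_to_int(key) -> int:
    if isinstance(key, (int, np.integer)):
        return int(key) & 0x7FFFFFFF
    # stable across processes/runs (unlike hash())
    return zlib.crc32(str(key).encode("utf8")) & 0x7FFFFFFF


def child_seed(seed: int, *keys) -> int:
    """Derive a deterministic sub-seed (< 2**31) from ``seed`` and a key path."""
    ss = np.random.SeedSequence(int(seed), spawn_key=tuple(_key_to_int(k) for k in keys))
    return int(ss.generate_state(1, dtype=np.uint32)[0]) & 0x7FFFFFFF


def rng(seed: int, *keys) -> np.random.Generator:
    """A Generator on the sub-stream identified by ``keys``."""
    if keys:
        seed = child_seed(seed, *keys)
    return np.random.default_rng(seed)


def geometric_mean(x: np.ndarray, axis=None) -> np.ndarray:
    """Geometric mean of strictly positive values."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("geometric mean requires strictly positive values")
    return np.exp(np.mean(np.log(x), axis=axis))
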