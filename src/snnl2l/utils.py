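"""Seeding discipline and small shared helpers."""
from __future__ import annotations

import zlib

import numpy as np

__all__ = ["seed_stream", "child_seed", "as_array"]


def child_seed(master_seed: int, name: str) -> int:
    """Derive a named sub-seed (< 2**31) from a master seed.

    Every stochastic component (init / data / noise / ...) consumes its own
    named stream so that changing one consumer does not perturb the others.
    """
    tag = zlib.crc32(name.encode("utf-8"))
    return int(np.random.SeedSequence([int(master_seed), tag]).generate_state(1)[0] % (2**31))


def seed_stream(master_seed: int, name: str) -> np.random.Generator:
    """Independent Generator for the named stream of a master seed."""
    return np.random.default_rng(child_seed(master_seed, name))


def as_array(x, n: int) -> np.ndarray:
    """Broadcast a scalar or length-n sequence to a float64 vector of length n."""
    arr = np.asarray(x, dtype=np.float64)
    if arr.ndim == 0:
        return np.full(n, float(arr))
    if arr.shape != (n,):
        raise ValueError(f"expected scalar or shape ({n},), got {arr.shape}")
    return arr.copy()
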