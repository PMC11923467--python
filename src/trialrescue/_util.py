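"""Small shared numerics: integer apportionment and seed derivation."""
from __future__ import annotations

import zlib

import numpy as np


def largest_remainder(weights, total: int) -> np.ndarray:
    """Apportion ``total`` units across cells proportionally to ``weights``.

    Uses the largest-remainder (Hamilton) rule: each cell receives the floor of
    its exact share, and the leftover units go to the cells with the largest
    fractional remainders (ties broken by cell order, so the result is
    deterministic). The returned integer counts always sum to ``total``.
    """
    w = np.asarray(weights, dtype=float)
    if total < 0:
        raise ValueError("total must be >= 0")
    if w.size == 0:
        if total:
            raise ValueError("cannot apportion into zero cells")
        return np.zeros(0, dtype=int)
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be non-negative with positive sum")
    exact = w / w.sum() * total
    counts = np.floor(exact).astype(int)
    short = total - counts.sum()
    if short:
        # stable ordering: remainder descending, then original index
        order = np.lexsort((np.arange(w.size), -(exact - counts)))
        counts[order[:short]] += 1
    return counts


def child_seed(seed: int, *key) -> int:
    """Derive a stable 31-bit child seed from a master seed and a tag tuple."""
    tag = zlib.crc32(repr(key).encode("utf-8"))
    return (int(seed) ^ tag) & 0x7FFFFFFF


def spawn_rng(seed: int, *key) -> np.random.Generator:
    """A Generator seeded deterministically from (seed, key...).

    Distinct keys give independent streams; identical keys replay exactly.
    """
    tag = zlib.crc32(repr(key).encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, tag]))
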