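"""Deterministic seed-stream plumbing.

A master seed spawns named child streams through ``numpy.random.SeedSequence``
so that every stage / subject / replicate draws from an independent,
individually reproducible generator.  Names are hashed into the entropy pool,
making streams stable under reordering of calls.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["child_seed", "stream"]


def child_seed(master_seed: int, *names) -> np.random.SeedSequence:
    """SeedSequence for a named child stream of ``master_seed``."""
    digest = hashlib.sha256("/".join(str(n) for n in names).encode()).digest()
    salt = [int.from_bytes(digest[i : i + 4], "little") for i in range(0, 16, 4)]
    return np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, *salt])


def stream(master_seed: int, *names) -> np.random.Generator:
    """Generator for a named child stream of ``master_seed``."""
    return np.random.default_rng(child_seed(master_seed, *names))
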