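"""Deterministic seed fan-out.

A single global seed is split into independent per-stage seeds by hashing
the stage label (CRC-32) together with the global seed through numpy's
``SeedSequence``.  Stages are therefore reproducible in isolation: the
same (seed, label) pair always yields the same stream.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_seed", "rng_for"]


def child_seed(seed: int, label: str) -> int:
    """Derive a stable 31-bit child seed for a named stage."""
    tag = zlib.crc32(label.encode("utf-8"))
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, tag])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def rng_for(seed: int, label: str) -> np.random.Generator:
    return np.random.default_rng(child_seed(seed, label))
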