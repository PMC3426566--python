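"""Deterministic per-stage random streams.

Every consumer of randomness in the package derives its generator from a
master seed plus a stable component name, so re-running any stage in
isolation reproduces the result it had inside a full pipeline run.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["derive_seed", "derive_rng"]


def derive_seed(master_seed: int, name: str) -> int:
    """Return a child seed (< 2**31) for a named component."""
    tag = zlib.crc32(name.encode("utf-8"))
    ss = np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, tag])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def derive_rng(master_seed: int, name: str) -> np.random.Generator:
    """Generator seeded from ``derive_seed(master_seed, name)``."""
    return np.random.default_rng(derive_seed(master_seed, name))
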