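"""Hierarchical random-number streams.

All randomness in the package flows from one user-supplied integer seed.
Each module/operation draws from a named substream so that, e.g., the
truth-set simulation is reproducible independently of how many reads the
read simulator consumed.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, label: str) -> np.random.Generator:
    """Return a Generator deterministically keyed by (seed, label)."""
    if not (0 <= int(seed) < 2**31):
        raise ValueError(f"seed must be in [0, 2^31): got {seed}")
    key = zlib.crc32(label.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))
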