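"""Seed-substream derivation.

One top-level integer seed expands into named, independent substreams via
``SeedSequence([seed, crc32(label)])``.  The derivation is documented and
stable, so partial re-runs of a study (e.g. only the tolerance stage)
reproduce exactly the draws of the full run.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "derive_seed"]


def derive_seed(seed: int, *labels: str) -> int:
    """A 31-bit child seed for a named substream of ``seed``."""
    h = 0
    for lab in labels:
        h = zlib.crc32(str(lab).encode(), h)
    return int(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, h & 0x7FFFFFFF]).generate_state(1)[0] & 0x7FFFFFFF)


def substream(seed: int, *labels: str) -> np.random.Generator:
    """Independent generator for the substream named by ``labels``."""
    return np.random.default_rng(derive_seed(seed, *labels))
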