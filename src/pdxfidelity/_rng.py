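"""Seed-substream plumbing.

All stochastic components derive their generators from a single master
seed through named substreams, so each artifact (cohort, cell-line panel,
gene sets, ...) can be regenerated independently and reproducibly.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the named substream of ``seed``.

    The substream key is a CRC32 of the name, so the mapping is stable
    across processes and Python versions (unlike ``hash``).
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, key]))
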