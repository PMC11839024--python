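"""Seeded random substreams.

One integer seed feeds a named substream per generator, so adding a new
generator never perturbs the draws of existing ones.
"""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the (seed, name) substream.

    The stream key is derived from a CRC32 of the name, so it is stable
    across sessions and platforms.
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence((int(seed), key)))
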