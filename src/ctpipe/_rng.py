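"""Named, reproducible random substreams.

Every stochastic stage of the pipeline draws from its own substream derived
from a single master seed, so that re-running one stage (or reordering
stages) never perturbs the randomness of another.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the named substream of ``seed``.

    The stream key is a CRC32 of ``name``, which is stable across platforms
    and Python versions, so identical (seed, name) pairs always yield
    bit-identical streams.
    """
    key = zlib.crc32(name.encode("utf-8"))
    ss = np.random.SeedSequence(entropy=int(seed) % (2**31), spawn_key=(key,))
    return np.random.default_rng(ss)
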