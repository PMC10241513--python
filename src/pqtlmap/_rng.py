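"""Named, reproducible random substreams.

Every stochastic operation in the package draws from a substream derived from a
single integer seed and a short stream name, so that e.g. the genotype panel of
a run is reproducible independently of how many abundance features were drawn
afterwards.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the named substream of ``seed``.

    The stream key is a CRC32 of the name, so the mapping is stable across
    sessions and platforms. Distinct names yield independent streams.
    """
    key = zlib.crc32(name.encode("utf-8"))
    ss = np.random.SeedSequence(entropy=int(seed) & 0x7FFFFFFF, spawn_key=(key,))
    return np.random.default_rng(ss)
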