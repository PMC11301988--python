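"""Named substreams from one global seed.

Every source of randomness in the package draws from a generator obtained
with :func:`substream`, so changing e.g. the episode sampler's consumption
pattern never perturbs the weight initialization, and per-kinase draws do
not depend on iteration order.
"""

from __future__ import annotations

import zlib

import numpy as np


def _name_key(name: str) -> int:
    return zlib.crc32(name.encode("utf-8"))


def substream(seed: int, *names: str) -> np.random.Generator:
    """Independent, reproducible generator for (seed, name path)."""
    keys = [int(seed)] + [_name_key(n) for n in names]
    return np.random.default_rng(np.random.SeedSequence(keys))


def substream_seed(seed: int, *names: str) -> int:
    """A derived 31-bit integer seed, for APIs that want a plain int."""
    return int(substream(seed, *names).integers(0, 2**31 - 1))
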