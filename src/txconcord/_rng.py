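"""Named random substreams derived from one global seed.

Every stochastic operation in the package draws from a substream keyed by a
stable name, so any stage can be re-run in isolation and reproduce its draws.
"""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the named substream of ``seed``.

    The stream key is a CRC32 of the name, so it is stable across Python
    processes (unlike ``hash``).
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, key]))
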