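"""Seeded random-number substreams.

All stochastic stages of the pipeline draw from named substreams derived from a
single root seed, so that e.g. adding a unit to a simulation never perturbs the
spike trains of the units that were already there.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def _key_to_int(key: int | str) -> int:
    if isinstance(key, (int, np.integer)) and int(key) >= 0:
        return int(key)
    # strings (and negative sentinels) hash stably across sessions, unlike hash()
    return zlib.crc32(str(key).encode("utf-8"))


def substream(seed: int, *keys: int | str) -> np.random.Generator:
    """Return a Generator for the substream named by ``keys`` under ``seed``.

    The same ``(seed, *keys)`` always yields the same stream; distinct key
    tuples yield statistically independent streams.
    """
    ss = np.random.SeedSequence(int(seed), spawn_key=tuple(_key_to_int(k) for k in keys))
    return np.random.default_rng(ss)
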