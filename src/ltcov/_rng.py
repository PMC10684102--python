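"""Counter-based seed splitting.

All randomness in the package flows from one integer seed. Independent
streams for sub-tasks are derived with :func:`child_rng`, which hashes a
tuple of string keys into a ``numpy.random.SeedSequence`` spawn key, so a
module can be rerun in isolation and still reproduce exactly what the full
pipeline would have produced.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_rng"]


def _key_to_int(key: str | int) -> int:
    if isinstance(key, (int, np.integer)):
        return int(key) & 0xFFFFFFFF
    return zlib.crc32(key.encode("utf-8")) & 0xFFFFFFFF


def child_rng(seed: int, *keys: str | int) -> np.random.Generator:
    """Return a Generator for the stream identified by ``keys`` under ``seed``."""
    ss = np.random.SeedSequence(int(seed), spawn_key=tuple(_key_to_int(k) for k in keys))
    return np.random.default_rng(ss)
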