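"""Named, reproducible random streams.

Every source of randomness in the pipeline draws from a stream derived from
one master seed plus a tuple of string/integer keys (module, replicate,
step, ...), so any single bootstrap replicate or projection step can be
re-run in isolation and the whole run is bit-reproducible.
"""

from __future__ import annotations

import zlib

import numpy as np


def _key_word(key) -> int:
    if isinstance(key, (int, np.integer)):
        return int(key) & 0xFFFFFFFF
    return zlib.crc32(str(key).encode("utf-8"))


def stream(master_seed: int, *keys) -> np.random.Generator:
    """A :class:`numpy.random.Generator` for the named sub-stream."""
    words = [int(master_seed) & 0x7FFFFFFF] + [_key_word(k) for k in keys]
    return np.random.default_rng(np.random.SeedSequence(words))


def stable_uniform(seed: int, *keys) -> float:
    """Deterministic uniform in [0, 1) keyed by (seed, keys).

    Used where a per-individual decision must be idempotent (e.g. the
    follow-up wave assignment), independent of row order or table subsetting.
    """
    h = zlib.crc32(("|".join(str(k) for k in (seed, *keys))).encode("utf-8"))
    return h / 2**32
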