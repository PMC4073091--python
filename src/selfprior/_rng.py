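"""Deterministic random-stream derivation.

One root seed governs a whole simulated session.  Streams for individual
participants/blocks are derived by hashing stable string keys into the
``spawn_key`` of a :class:`numpy.random.SeedSequence`, so the data generated
for one participant never depend on how many other participants exist or on
the order in which they are simulated.
"""

from __future__ import annotations

import zlib

import numpy as np


def _key32(token: object) -> int:
    return zlib.crc32(str(token).encode("utf-8")) & 0xFFFFFFFF


def derive_rng(seed: int, *context: object) -> np.random.Generator:
    """Return a Generator for ``context`` derived from the root ``seed``.

    The same (seed, context) pair always yields the same stream, on any
    platform, independently of any other stream derived from the same seed.
    """
    spawn_key = tuple(_key32(c) for c in context)
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=spawn_key))


def as_rng(seed_or_rng: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)
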