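"""Seeded substream management.

A single root seed spawns named, mutually independent random streams
(recruitment, mortality, field, survey, ...) so that changing the number of
draws consumed by one component never perturbs another.  String keys are
hashed stably (crc32) into the entropy pool of a ``numpy`` ``SeedSequence``.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "as_rng"]


def _key_to_int(key: int | str) -> int:
    if isinstance(key, (int, np.integer)):
        if key < 0:
            raise ValueError(f"substream keys must be non-negative, got {key}")
        return int(key)
    return zlib.crc32(str(key).encode("utf-8"))


def substream(seed: int, *keys: int | str) -> np.random.Generator:
    """Return an independent Generator for (seed, *keys).

    The same (seed, keys) tuple always yields the same stream; distinct key
    tuples yield statistically independent streams.
    """
    entropy = [int(seed) & 0x7FFFFFFF] + [_key_to_int(k) for k in keys]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def as_rng(seed: "int | np.random.Generator | None", *keys: int | str) -> np.random.Generator:
    """Coerce an int seed (spawning the keyed substream) or pass a Generator through."""
    if isinstance(seed, np.random.Generator):
        return seed
    if seed is None:
        seed = 0
    return substream(int(seed), *keys)
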