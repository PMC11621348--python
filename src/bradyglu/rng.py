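"""Deterministic random-stream derivation.

A single root seed is expanded into independent substreams keyed by stage
name and unit (patient index, bootstrap iteration, ...) via a counter-based
``SeedSequence`` scheme: the substream for ("simulate", patient 7) does not
change when more patients are added, so cohorts grow reproducibly.
"""

from __future__ import annotations

import zlib

import numpy as np


def _key_to_int(key) -> int:
    if isinstance(key, (int, np.integer)):
        return int(key) & 0x7FFFFFFF
    return zlib.crc32(str(key).encode("utf-8")) & 0x7FFFFFFF


def derive_seed_sequence(seed: int, *keys) -> np.random.SeedSequence:
    return np.random.SeedSequence(
        entropy=int(seed) & 0x7FFFFFFF,
        spawn_key=tuple(_key_to_int(k) for k in keys),
    )


def derive_rng(seed: int, *keys) -> np.random.Generator:
    """Generator for the substream identified by (seed, *keys)."""
    return np.random.Generator(np.random.PCG64(derive_seed_sequence(seed, *keys)))
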