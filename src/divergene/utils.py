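"""Deterministic seeding and logging helpers shared across the pipeline."""

from __future__ import annotations

import hashlib
import logging

import numpy as np

logger = logging.getLogger("divergene")


def seed_sequence(seed: int, *purpose: str) -> np.random.SeedSequence:
    """A named random stream derived from one root seed.

    Each (seed, purpose) pair maps to an independent stream, so pipeline
    stages can be regenerated in isolation without replaying earlier draws.
    """
    key = []
    for token in purpose:
        digest = hashlib.sha256(token.encode("utf-8")).digest()
        key.extend(int.from_bytes(digest[i : i + 4], "little") for i in range(0, 16, 4))
    return np.random.SeedSequence(entropy=int(seed), spawn_key=tuple(key))


def seeded_rng(seed: int, *purpose: str) -> np.random.Generator:
    return np.random.default_rng(seed_sequence(seed, *purpose))


def derived_int_seed(seed: int, *purpose: str) -> int:
    """A 31-bit integer seed for libraries that take plain ints."""
    return int(seed_sequence(seed, *purpose).generate_state(1, np.uint32)[0] % (2**31))
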