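"""Deterministic random-number substreams.

One master seed governs a whole scenario.  Every stochastic stage draws from a
substream derived from ``(master_seed, purpose-tag, *ids)`` so that, e.g.,
adding a protected area never perturbs the draws of an unrelated one.
"""

from __future__ import annotations

from zlib import crc32

import numpy as np


def _tag_to_int(tag) -> int:
    if isinstance(tag, (int, np.integer)):
        return int(tag) & 0xFFFFFFFF
    return crc32(str(tag).encode("utf-8"))


def seed_sequence(master_seed: int, *tags) -> np.random.SeedSequence:
    entropy = [int(master_seed) & 0xFFFFFFFF] + [_tag_to_int(t) for t in tags]
    return np.random.SeedSequence(entropy)


def substream(master_seed: int, *tags) -> np.random.Generator:
    """Generator for the substream identified by ``(master_seed, *tags)``."""
    return np.random.default_rng(seed_sequence(master_seed, *tags))


def substream_seed(master_seed: int, *tags) -> int:
    """A 31-bit integer seed derived from the substream (for APIs taking ints)."""
    return int(seed_sequence(master_seed, *tags).generate_state(1)[0]) & 0x7FFFFFFF
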