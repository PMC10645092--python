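"""Deterministic fan-out of a single master seed to independent streams.

Every stochastic stage (per-watershed null chain, permutation test,
simulation) draws its generator from the master seed plus stable string
tags, so any stage can be re-run in isolation — or watersheds processed
in parallel — with bit-identical results.
"""

from __future__ import annotations

import zlib

import numpy as np


def _tag_to_int(tag: str | int) -> int:
    if isinstance(tag, int):
        return tag
    return zlib.crc32(tag.encode("utf-8"))


def rng_for(master_seed: int, *tags: str | int) -> np.random.Generator:
    """Generator for the stream identified by ``(master_seed, *tags)``.

    Tags are strings (hashed with CRC-32, stable across runs and
    platforms) or plain integers.
    """
    entropy = [int(master_seed)] + [_tag_to_int(t) for t in tags]
    return np.random.default_rng(np.random.SeedSequence(entropy))
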