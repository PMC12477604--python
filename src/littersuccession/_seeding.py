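"""Deterministic splitting of one global seed into per-stage substreams.

A single integer seed reproduces the whole pipeline: every stage draws from
its own named substream, so adding or reordering stages never perturbs the
randomness seen by the others.
"""
from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, label: str) -> np.random.Generator:
    """Return an independent generator for ``label`` derived from ``seed``."""
    key = zlib.crc32(label.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(key,)))


def child_seed(seed: int, label: str) -> int:
    """A plain integer seed (< 2**31) for APIs that take one."""
    return int(substream(seed, label).integers(2**31))
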