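"""Seed fan-out.

A single global seed is expanded into named, statistically independent
substreams so that changing the parameters of one simulation component
never perturbs the draws of another.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Return an independent generator for component ``name`` under ``seed``.

    The component name is hashed (CRC32, stable across runs and platforms)
    into the spawn key of a :class:`numpy.random.SeedSequence`, so each
    (seed, name) pair maps to a fixed, independent stream.
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))
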