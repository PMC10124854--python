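"""Seeded random-number substreams.

All stochastic stages of the pipeline draw from named substreams derived
from one root seed, so that adding a stage never perturbs the draws of
another and every artifact can record the (seed, stream) pair it used.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["rng_for"]


def rng_for(seed: int, *names: str) -> np.random.Generator:
    """Return a Generator for the substream identified by ``names``.

    The stream key is a CRC32 hash of the joined names, mixed with the root
    seed through numpy's SeedSequence, so distinct names give independent
    streams and identical (seed, names) pairs give identical streams.
    """
    if seed < 0:
        raise ValueError("seed must be non-negative")
    key = zlib.crc32("/".join(names).encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))
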