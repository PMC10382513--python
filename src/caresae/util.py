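"""Seed management: named, reproducible substreams from a single run seed."""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, *labels) -> np.random.Generator:
    """Return a Generator for a named stage, derived from the run seed.

    Every source of randomness in the pipeline draws from one of these, so a
    single config seed reproduces the whole run while stages stay independent
    (changing the number of draws in one stage does not perturb another).
    """
    key = tuple(zlib.crc32(str(lab).encode("utf8")) for lab in labels)
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=key))
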