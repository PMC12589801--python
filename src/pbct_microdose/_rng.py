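"""Seed handling: every stochastic entry point accepts an int seed, a
``numpy.random.Generator``, or a ``SeedSequence``."""
from __future__ import annotations

import numpy as np


def as_generator(seed=None) -> np.random.Generator:
    """Coerce ``seed`` into a Generator (a Generator passes through unchanged)."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def spawn_seeds(master_seed: int, n: int) -> list[np.random.SeedSequence]:
    """Derive ``n`` statistically independent child seed sequences."""
    return np.random.SeedSequence(master_seed).spawn(n)
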