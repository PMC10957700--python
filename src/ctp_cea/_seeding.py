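"""Domain-separated random streams.

Different pipeline stages (cohort synthesis, missed-LVO selection, event
simulation, PSA replicates) must produce independent streams even when the
user passes the same integer seed to each, so every stage derives its
generator from a ``SeedSequence`` with a stage-specific spawn key. Passing
an existing ``numpy.random.Generator`` bypasses this (the caller then owns
stream management, as the engine does within one run).
"""

from __future__ import annotations

import numpy as np

COHORT = 1
ARMS = 2
SIMULATION = 3
BASELINE = 4
PSA = 5
COHORT_IO = 6


def rng_for(seed: int | np.random.Generator | None, domain: int, *sub: int) -> np.random.Generator:
    """Generator for ``seed`` within a stage domain (plus optional sub-keys,
    e.g. a replicate index)."""
    if isinstance(seed, np.random.Generator):
        return seed
    if seed is None:
        seed = np.random.SeedSequence().entropy % (2**31)
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(domain, *sub)))
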