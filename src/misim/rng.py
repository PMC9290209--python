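"""Deterministic seeding.

A single master seed spawns independent streams through
``numpy.random.SeedSequence`` keyed by small integer tags, so any piece of
the simulation (the population draw, the outcome draw, a single replicate)
is reproducible in isolation from ``(master_seed, tags...)`` alone.
"""

from __future__ import annotations

import numpy as np

# stream tags
POPULATION = 1
OUTCOME = 2
MISSINGNESS = 3
REPLICATE = 4


def child_rng(master_seed: int, *path: int) -> np.random.Generator:
    """Generator for the stream identified by ``(master_seed, *path)``."""
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), *map(int, path)]))
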