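"""Seed-derivation helpers.

All randomness in the package flows through :class:`numpy.random.Generator`
objects built from :class:`numpy.random.SeedSequence`. A master seed plus a
tuple of small non-negative integers (well indices, cell index, stage id)
deterministically identifies every stream, so any single well or cell can be
re-simulated in isolation.
"""

from __future__ import annotations

import numpy as np

# Stage identifiers for per-cell streams inside the simulated experiment.
STAGE_FOOTPRINT = 0
STAGE_RECEPTORS = 1
STAGE_DISRUPTION = 2
STAGE_LABELING = 3
STAGE_RENDER_AIE = 4
STAGE_RENDER_CONV = 5

SeedLike = "int | np.random.SeedSequence | np.random.Generator"


def as_generator(seed) -> np.random.Generator:
    """Coerce an int, SeedSequence or Generator into a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    if isinstance(seed, np.random.SeedSequence):
        return np.random.default_rng(seed)
    if isinstance(seed, (int, np.integer)):
        if seed < 0:
            raise ValueError("seed must be non-negative")
        return np.random.default_rng(int(seed))
    raise TypeError(f"cannot build a Generator from {type(seed).__name__}")


def derive_seed(master_seed: int, *key: int) -> np.random.SeedSequence:
    """Derive a child SeedSequence from a master seed and an integer key path."""
    return np.random.SeedSequence(int(master_seed), spawn_key=tuple(int(k) for k in key))
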