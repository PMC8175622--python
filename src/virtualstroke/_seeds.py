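"""Deterministic sub-seed derivation.

Every stochastic stage draws from a Generator derived from
``SeedSequence([master_seed, *path])`` where ``path`` is a fixed tuple of
small integers identifying the stage (and, where relevant, the patient or
replicate index).  This makes any patient or replicate regenerable in
isolation from the master seed alone.
"""

from __future__ import annotations

import numpy as np

# stage codes used in seed paths (stable across versions)
CLINICAL = 1
GEOMETRY = 2
HEMODYNAMICS = 3
DWI = 4
PERFUSION = 5
FATE = 6
SAMPLING = 7
FOREST = 8
REPLICATE = 9
PHANTOM = 10


def seed_sequence(master_seed: int, *path: int) -> np.random.SeedSequence:
    return np.random.SeedSequence([int(master_seed), *[int(p) for p in path]])


def rng_for(master_seed: int, *path: int) -> np.random.Generator:
    """Generator for a named stage; pure function of (master_seed, path)."""
    return np.random.default_rng(seed_sequence(master_seed, *path))


def int_seed(master_seed: int, *path: int) -> int:
    """A 31-bit integer seed (e.g. for scikit-learn ``random_state``)."""
    return int(seed_sequence(master_seed, *path).generate_state(1)[0] % (2**31))
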