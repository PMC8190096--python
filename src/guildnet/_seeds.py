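"""Deterministic per-stage seed derivation.

One master seed drives the whole pipeline; each stage draws from a child
``numpy.random.SeedSequence`` obtained with a fixed integer offset, so that
changing e.g. the bootstrap seed never perturbs the simulation stream.
"""

from __future__ import annotations

import numpy as np

STAGE_OFFSETS = {
    "guild_db": 11,
    "counts": 23,
    "rarefy": 37,
    "sparcc_boot": 53,
    "permtest": 71,
    "permanova": 89,
}


def stage_seed_sequence(master_seed: int, stage: str) -> np.random.SeedSequence:
    """Child seed sequence for a named pipeline stage."""
    return np.random.SeedSequence((int(master_seed), STAGE_OFFSETS[stage]))


def stage_rng(master_seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(stage_seed_sequence(master_seed, stage))
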