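"""Seed-substream management.

One global integer seed expands into named, independent substreams (features /
survival / clinical / images) so each simulation stage can be regenerated on
its own without perturbing the others.
"""

from __future__ import annotations

import numpy as np

STAGES = ("features", "survival", "clinical", "images")


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Return a Generator for a named substream of ``seed``.

    Substreams are derived with :class:`numpy.random.SeedSequence` spawn keys,
    so they are mutually independent and reproducible bit-for-bit.
    """
    if stage not in STAGES:
        raise ValueError(f"unknown rng stage {stage!r}; expected one of {STAGES}")
    key = STAGES.index(stage)
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(key,)))
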