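"""Small shared numeric helpers."""

from __future__ import annotations

import math

import numpy as np


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero.

    Python's built-in ``round`` uses banker's rounding; printed clinical
    percentages (36% from 5/14, 50% from 7/14) follow the conventional
    half-away rule instead.
    """
    if not math.isfinite(x):
        raise ValueError(f"cannot round non-finite value {x!r}")
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def as_rng(seed) -> np.random.Generator:
    """Accept an int, a SeedSequence, or an existing Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)
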