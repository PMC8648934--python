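"""Small shared numerics: rounding, quartiles, child-seed derivation."""

from __future__ import annotations

import math

import numpy as np


def round_half_up(x: float) -> int:
    """Round to the nearest integer, ties away from zero toward +inf.

    Used for converting configured fractions (extinct, naturalized) into
    exact species counts so that documented example counts hold exactly.
    """
    return int(math.floor(x + 0.5))


def quartiles(values) -> tuple[float, float]:
    """(Q1, Q3) with linear interpolation between order statistics."""
    v = np.asarray(values, dtype=float)
    return float(np.quantile(v, 0.25)), float(np.quantile(v, 0.75))


def iqr_upper_fence(values, k: float = 1.5) -> float:
    """Tukey upper fence Q3 + k*IQR of a sample."""
    q1, q3 = quartiles(values)
    return q3 + k * (q3 - q1)


def child_seed(master_seed: int, stage: int) -> int:
    """Deterministic per-stage seed from a master seed.

    Counter-based (SeedSequence spawn keys) so adding a stage never
    perturbs the streams of earlier stages. Result fits in 31 bits, which
    keeps it usable for both numpy and stdlib ``random``.
    """
    ss = np.random.SeedSequence(master_seed, spawn_key=(stage,))
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def child_rng(master_seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(child_seed(master_seed, stage))
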