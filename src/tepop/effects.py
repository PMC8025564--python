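"""Sampling per-insertion fitness effects and applying them to host fitness.

Every TE insertion draws one of four effect classes — lethal, mildly
deleterious, neutral, mildly beneficial — from an
:class:`~tepop.parameters.InsertionEffectDistribution`.  The class maps to a
multiplicative fitness update: lethal → 0, deleterious → ``1 - s_d``,
neutral → 1, beneficial → ``1 + s_b``.  Fitness combines multiplicatively
across insertions (and host mutations), so lethal is absorbing and the order
of application never matters.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np

from .parameters import InsertionEffectDistribution

__all__ = ["EffectClass", "EffectDraw", "draw_effect", "draw_effect_counts", "apply_effect"]


class EffectClass(IntEnum):
    """The four per-insertion fitness effect categories."""

    LETHAL = 0
    DELETERIOUS = 1
    NEUTRAL = 2
    BENEFICIAL = 3


@dataclass(frozen=True)
class EffectDraw:
    """One sampled insertion effect and its fitness multiplier."""

    effect_class: EffectClass
    fitness_multiplier: float


def class_multiplier(
    effect_class: EffectClass, dist: InsertionEffectDistribution
) -> float:
    """Fitness multiplier of an effect class under ``dist``'s magnitudes."""
    if effect_class is EffectClass.LETHAL:
        return 0.0
    if effect_class is EffectClass.DELETERIOUS:
        return 1.0 - dist.s_deleterious
    if effect_class is EffectClass.NEUTRAL:
        return 1.0
    return 1.0 + dist.s_beneficial


def draw_effect(
    dist: InsertionEffectDistribution, rng: np.random.Generator
) -> EffectDraw:
    """Sample one insertion effect.

    Consumes exactly one uniform variate from ``rng``, so a seeded stream
    replays the same draw sequence.
    """
    u = rng.random()
    cumulative = 0.0
    for effect_class, p in zip(EffectClass, dist.probabilities):
        cumulative += p
        if u < cumulative:
            break
    else:  # u landed in the top rounding sliver; assign the last class
        effect_class = EffectClass.BENEFICIAL
    return EffectDraw(effect_class, class_multiplier(effect_class, dist))


def draw_effect_counts(
    dist: InsertionEffectDistribution, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Class counts for ``n`` independent insertion effects.

    A single multinomial draw, distributionally identical to ``n`` calls of
    :func:`draw_effect`; this is the batched form the simulation core uses.
    Returns a length-4 array in :class:`EffectClass` order.
    """
    if n < 0:
        raise ValueError(f"n={n} must be >= 0")
    return rng.multinomial(n, dist.probabilities)


def apply_effect(current_fitness: float, draw: EffectDraw) -> float:
    """Multiply a host fitness by one effect draw.

    Lethal returns exactly 0 regardless of the current value; fitness must
    be non-negative.
    """
    if current_fitness < 0:
        raise ValueError(f"fitness must be >= 0, got {current_fitness}")
    if draw.effect_class is EffectClass.LETHAL:
        return 0.0
    return current_fitness * draw.fitness_multiplier
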