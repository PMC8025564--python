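"""Parameter axes, scenario codes, and the insertion-effect distribution.

The simulation is controlled by eight two-level (High/Low) parameter axes:
four transposon properties — progeny count, excision rate, death rate,
insertion bias — and four host properties — corrected mutation rate,
non-coding DNA fraction, mutation effect size, carrying capacity.  A
scenario is written as a nine-character code such as ``"LLLH-LLHH"``: the
four letters before the hyphen set the TE axes and the four after set the
host axes, in the fixed order above.

The published experiment re-examines six such scenarios in which TEs were
originally reported to accumulate, comparing runs with and without a
beneficial insertion-effect class.  Per-insertion fitness effects are
categorical: lethal (probability 0.20), mildly deleterious (0.30), neutral,
and mildly beneficial; the beneficial probability is the swept variable
(0–20 %) and the neutral class absorbs whatever the beneficial class gives
up, so neutral ranges from 0.30 (at 20 % beneficial) to 0.50 (at 0 %).

High/Low letters are symbolic; the numeric values behind them are a
configurable *level map*.  :data:`DEFAULT_LEVEL_MAP` holds this package's
calibration (see ``docs/methods.md`` for the rationale behind each value).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "TE_AXES",
    "HOST_AXES",
    "AXES",
    "PROPORTIONAL",
    "ParameterScenario",
    "InsertionEffectDistribution",
    "SimulationParams",
    "parse_scenario_code",
    "published_scenarios",
    "make_effect_distribution",
    "resolve_levels",
    "DEFAULT_LEVEL_MAP",
    "GLOBAL_DEFAULTS",
    "PUBLISHED_SCENARIO_CODES",
]

#: TE-property axes, in scenario-code order (letters 1-4).
TE_AXES: tuple[str, ...] = (
    "te_progeny",
    "te_excision_rate",
    "te_death_rate",
    "insertion_bias",
)

#: Host-property axes, in scenario-code order (letters 6-9, after the hyphen).
HOST_AXES: tuple[str, ...] = (
    "corrected_mutation_rate",
    "non_coding_dna",
    "mutation_effect",
    "carrying_capacity",
)

AXES: tuple[str, ...] = TE_AXES + HOST_AXES

#: Sentinel level-map value for an unbiased insertion target choice: the
#: probability of hitting a non-coding locus equals the current non-coding
#: (including dead-TE) fraction of the genome.
PROPORTIONAL = None


@dataclass(frozen=True)
class ParameterScenario:
    """One High/Low assignment of the eight parameter axes."""

    te_progeny: str
    te_excision_rate: str
    te_death_rate: str
    insertion_bias: str
    corrected_mutation_rate: str
    non_coding_dna: str
    mutation_effect: str
    carrying_capacity: str

    def __post_init__(self) -> None:
        for axis in AXES:
            level = getattr(self, axis)
            if level not in ("H", "L"):
                raise ValueError(
                    f"level for axis {axis!r} must be 'H' or 'L', got {level!r}"
                )

    @property
    def code(self) -> str:
        """The nine-character ``"XXXX-XXXX"`` form of this scenario."""
        te = "".join(getattr(self, axis) for axis in TE_AXES)
        host = "".join(getattr(self, axis) for axis in HOST_AXES)
        return f"{te}-{host}"

    def levels(self) -> dict[str, str]:
        """Axis → level letter, in canonical axis order."""
        return {axis: getattr(self, axis) for axis in AXES}

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.code


def parse_scenario_code(code: str) -> ParameterScenario:
    """Parse a scenario code like ``"LLLH-LLHH"`` (or ``"LLLH - LLHH"``).

    Whitespace around and inside the code is ignored, so codes copied
    verbatim from the published table parse unchanged.

    Raises
    ------
    ValueError
        If the normalized code is not four letters, a hyphen, and four
        letters, or contains a letter outside ``{H, L}``.  The message
        names the offending character.
    """
    normalized = "".join(code.split())
    if len(normalized) != 9 or normalized[4] != "-":
        raise ValueError(
            f"scenario code {code!r} must normalize to 4 letters, '-', 4 letters "
            f"(got {normalized!r})"
        )
    letters = normalized[:4] + normalized[5:]
    for position, letter in enumerate(letters):
        if letter not in ("H", "L"):
            raise ValueError(
                f"scenario code {code!r}: letter {letter!r} at axis "
                f"{AXES[position]!r} is not 'H' or 'L'"
            )
    return ParameterScenario(**dict(zip(AXES, letters)))


#: The six scenarios of the published table, in table order.
PUBLISHED_SCENARIO_CODES: tuple[str, ...] = (
    "HLLL-LHLH",
    "LLHH-LHHH",
    "LLLH-LHHL",
    "LLLH-LLHH",
    "LLLL-LHHH",
    "LLLL-LLHL",
)


def published_scenarios() -> list[ParameterScenario]:
    """The six published scenarios in which TEs were originally reported to
    accumulate in the majority of runs, in table order."""
    return [parse_scenario_code(c) for c in PUBLISHED_SCENARIO_CODES]


@dataclass(frozen=True)
class InsertionEffectDistribution:
    """Categorical distribution of per-insertion fitness effects.

    ``s_deleterious`` and ``s_beneficial`` are the selection-coefficient
    magnitudes of the mildly deleterious and mildly beneficial classes; a
    deleterious insertion multiplies host fitness by ``1 - s_deleterious``
    and a beneficial one by ``1 + s_beneficial``.  Lethal insertions set
    fitness to zero and neutral insertions leave it unchanged.
    """

    p_lethal: float
    p_deleterious: float
    p_neutral: float
    p_beneficial: float
    s_deleterious: float = 0.01
    s_beneficial: float = 0.30

    def __post_init__(self) -> None:
        probs = (self.p_lethal, self.p_deleterious, self.p_neutral, self.p_beneficial)
        for name, p in zip(("lethal", "deleterious", "neutral", "beneficial"), probs):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"p_{name}={p} outside [0, 1]")
        total = math.fsum(probs)
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"class probabilities sum to {total!r}, not 1")
        if not 0.0 < 1.0 - self.s_deleterious < 1.0:
            raise ValueError(f"s_deleterious={self.s_deleterious} outside (0, 1)")
        if self.s_beneficial <= 0.0:
            raise ValueError(f"s_beneficial={self.s_beneficial} must be > 0")

    @property
    def probabilities(self) -> np.ndarray:
        """Class probabilities as a length-4 array in
        (lethal, deleterious, neutral, beneficial) order."""
        return np.array(
            [self.p_lethal, self.p_deleterious, self.p_neutral, self.p_beneficial]
        )


def make_effect_distribution(
    beneficial_pct: float,
    *,
    s_deleterious: float = 0.01,
    s_beneficial: float = 0.30,
) -> InsertionEffectDistribution:
    """Build the insertion-effect distribution for a beneficial frequency.

    The lethal (20 %) and mildly deleterious (30 %) classes are fixed; the
    beneficial class takes ``beneficial_pct`` percent and the neutral class
    absorbs the remainder, ``50 % - beneficial_pct``.  ``beneficial_pct``
    must therefore lie in [0, 20].
    """
    if not 0.0 <= beneficial_pct <= 20.0:
        raise ValueError(
            f"beneficial_pct={beneficial_pct} outside [0, 20]: the fixed "
            "lethal/deleterious split leaves only the 50% neutral+beneficial "
            "mass to reallocate"
        )
    p_beneficial = beneficial_pct / 100.0
    return InsertionEffectDistribution(
        p_lethal=0.20,
        p_deleterious=0.30,
        p_neutral=0.50 - p_beneficial,
        p_beneficial=p_beneficial,
        s_deleterious=s_deleterious,
        s_beneficial=s_beneficial,
    )


@dataclass(frozen=True)
class SimulationParams:
    """Fully resolved numeric parameters for one simulation run.

    The first eight fields are the numeric values behind the High/Low axes;
    the rest are global model constants not on any axis.
    ``insertion_bias`` is the probability that a new insertion targets a
    non-coding locus (dead TEs count as non-coding); ``None`` means
    unbiased, i.e. proportional to the genome's current non-coding fraction.
    """

    progeny: int
    excision_rate: float
    death_rate: float
    insertion_bias: float | None
    mutation_rate: float
    non_coding_fraction: float
    mutation_effect: float
    carrying_capacity: int
    genome_length: int = 1000
    initial_te_per_host: int = 5
    transposition_rate: float = 0.05
    effect_distribution: InsertionEffectDistribution = field(
        default_factory=lambda: make_effect_distribution(20.0)
    )
    max_generations: int = 1500

    def __post_init__(self) -> None:
        if self.progeny < 1:
            raise ValueError(f"progeny={self.progeny} must be >= 1")
        if self.carrying_capacity < 1:
            raise ValueError(f"carrying_capacity={self.carrying_capacity} must be >= 1")
        if self.genome_length < 1:
            raise ValueError(f"genome_length={self.genome_length} must be >= 1")
        if self.initial_te_per_host < 0:
            raise ValueError("initial_te_per_host must be >= 0")
        if self.max_generations < 1:
            raise ValueError("max_generations must be >= 1")
        for name in (
            "excision_rate",
            "death_rate",
            "mutation_rate",
            "non_coding_fraction",
            "transposition_rate",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name}={value} outside [0, 1]")
        if self.insertion_bias is not None and not 0.0 <= self.insertion_bias <= 1.0:
            raise ValueError(f"insertion_bias={self.insertion_bias} outside [0, 1]")
        if not 0.0 <= self.mutation_effect < 1.0:
            raise ValueError(f"mutation_effect={self.mutation_effect} outside [0, 1)")


# Calibrated numeric values behind the High/Low levels: axis -> (low, high).
# The excision/death rates are set so that the per-copy mechanical loss rate
# exceeds the per-copy transposition gain (transposition_rate * progeny) even
# at the high progeny level; TE persistence then requires lineage-level
# positive selection through the beneficial insertion class, which is the
# contrast the experiment is about.  See docs/methods.md.
DEFAULT_LEVEL_MAP: dict[str, tuple] = {
    "te_progeny": (1, 2),
    "te_excision_rate": (0.08, 0.16),
    "te_death_rate": (0.04, 0.08),
    "insertion_bias": (PROPORTIONAL, 0.9),
    "corrected_mutation_rate": (1e-4, 1e-3),
    "non_coding_dna": (0.3, 0.7),
    "mutation_effect": (0.01, 0.1),
    "carrying_capacity": (100, 500),
}

# Global model constants not on any High/Low axis.
GLOBAL_DEFAULTS: dict[str, float | int] = {
    "genome_length": 1000,
    "initial_te_per_host": 5,
    "transposition_rate": 0.05,
    "s_deleterious": 0.01,
    "s_beneficial": 0.30,
    "max_generations": 1500,
}


def resolve_levels(
    scenario: ParameterScenario,
    level_map: Mapping[str, Sequence] | None = None,
    *,
    defaults: Mapping[str, float | int] | None = None,
    effect_distribution: InsertionEffectDistribution | None = None,
    beneficial_pct: float | None = None,
) -> SimulationParams:
    """Resolve a High/Low scenario into numeric :class:`SimulationParams`.

    Parameters
    ----------
    scenario
        The eight-axis High/Low assignment.
    level_map
        Axis → ``(low_value, high_value)``.  Defaults to
        :data:`DEFAULT_LEVEL_MAP`.  Every axis must be present.
    defaults
        Overrides for :data:`GLOBAL_DEFAULTS` (genome length, initial TE
        count, transposition rate, effect magnitudes, generation cutoff).
    effect_distribution, beneficial_pct
        Either an explicit effect distribution, or a beneficial percentage
        from which one is built with the default-calibration magnitudes.
        Mutually exclusive; if neither is given the original 20 %
        configuration is used.
    """
    if level_map is None:
        level_map = DEFAULT_LEVEL_MAP
    merged = dict(GLOBAL_DEFAULTS)
    if defaults:
        unknown = set(defaults) - set(GLOBAL_DEFAULTS)
        if unknown:
            raise ValueError(f"unknown global default(s): {sorted(unknown)}")
        merged.update(defaults)

    resolved: dict[str, object] = {}
    for axis in AXES:
        if axis not in level_map:
            raise ValueError(f"level map is missing axis {axis!r}")
        low, high = level_map[axis]
        resolved[axis] = high if getattr(scenario, axis) == "H" else low

    if effect_distribution is not None and beneficial_pct is not None:
        raise ValueError("give either effect_distribution or beneficial_pct, not both")
    if effect_distribution is None:
        pct = 20.0 if beneficial_pct is None else beneficial_pct
        effect_distribution = make_effect_distribution(
            pct,
            s_deleterious=float(merged["s_deleterious"]),
            s_beneficial=float(merged["s_beneficial"]),
        )

    return SimulationParams(
        progeny=int(resolved["te_progeny"]),
        excision_rate=float(resolved["te_excision_rate"]),
        death_rate=float(resolved["te_death_rate"]),
        insertion_bias=(
            None
            if resolved["insertion_bias"] is None
            else float(resolved["insertion_bias"])
        ),
        mutation_rate=float(resolved["corrected_mutation_rate"]),
        non_coding_fraction=float(resolved["non_coding_dna"]),
        mutation_effect=float(resolved["mutation_effect"]),
        carrying_capacity=int(resolved["carrying_capacity"]),
        genome_length=int(merged["genome_length"]),
        initial_te_per_host=int(merged["initial_te_per_host"]),
        transposition_rate=float(merged["transposition_rate"]),
        effect_distribution=effect_distribution,
        max_generations=int(merged["max_generations"]),
    )
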