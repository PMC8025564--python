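"""tepop: forward-time agent-based simulation of transposable-element
population dynamics in asexual hosts.

The package models a clonal host population whose genomes carry mobile
elements. TE insertions draw categorical fitness effects (lethal, mildly
deleterious, neutral, mildly beneficial); transposition, excision, element
death, and host mutation act each generation, followed by
fitness-proportional reproduction under a carrying capacity.  The central
experiment contrasts TE fate with and without the beneficial insertion
class across published High/Low parameter scenarios, and sweeps the
beneficial insertion frequency from 0 to 20 %.
"""

__version__ = "0.1.0"

from .parameters import (  # noqa: F401
    InsertionEffectDistribution,
    ParameterScenario,
    SimulationParams,
    make_effect_distribution,
    parse_scenario_code,
    published_scenarios,
    resolve_levels,
)
from .effects import EffectClass, EffectDraw, apply_effect, draw_effect  # noqa: F401
from .sim_core import (  # noqa: F401
    Genome,
    GenerationRecord,
    Host,
    LocusClass,
    Population,
    init_population,
    step_generation,
)
from .experiment import (  # noqa: F401
    Outcome,
    OutcomeKind,
    ResultSet,
    Trajectory,
    classify,
    run_design,
    run_replicate,
)
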