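"""The published experimental design: scenarios × beneficial-frequency sweep
× replicates, with early stopping on TE extinction.

Two designs are supported directly:

* six published scenarios × beneficial frequency {0 %, 20 %} × 3 replicates
  (the with/without-beneficial-effects contrast), and
* one scenario (``LLLH-LLHH``) × {0, 1, 5, 10, 15, 20} % × 3 replicates
  (the beneficial-frequency sweep),

but any factorial combination of scenario codes, percentages and replicate
counts runs the same way.  Each run iterates the per-generation cycle until
the active-TE count hits zero (extinction, recorded) or the generation
cutoff (default 1,500) is reached; a run that still carries at least one
active TE at the cutoff is classified as ACCUMULATED.

Per-cell seeds are derived from the base seed by hashing
``"{base_seed}|{scenario}|{beneficial_pct}|{replicate}"`` with SHA-256 and
taking the first four bytes (below 2^31), so adding cells to a design never
perturbs the seeds of existing ones.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .parameters import (
    DEFAULT_LEVEL_MAP,
    GLOBAL_DEFAULTS,
    ParameterScenario,
    SimulationParams,
    parse_scenario_code,
    resolve_levels,
)
from .sim_core import GenerationRecord, init_population, step_generation

__all__ = [
    "Trajectory",
    "OutcomeKind",
    "Outcome",
    "ResultSet",
    "derive_seed",
    "run_replicate",
    "run_design",
    "classify",
]

#: Columns of the per-run trajectory CSV, in order.
TRAJECTORY_COLUMNS = (
    "generation",
    "total_active_te",
    "mean_te_per_host",
    "population_size",
    "mean_fitness",
    "insertions",
    "excisions",
    "te_deaths",
    "te_inactivations",
    "te_repro_delta",
    "host_deaths",
)


@dataclass
class Trajectory:
    """One run's per-generation records plus its design-cell identity."""

    scenario_code: str
    beneficial_pct: float
    replicate: int
    seed: int
    records: list[GenerationRecord]
    extinction_generation: int | None

    @property
    def final_active_te(self) -> int:
        return self.records[-1].total_active_te

    @property
    def generations_survived(self) -> int:
        """Number of generations with at least one active TE."""
        if self.extinction_generation is not None:
            return self.extinction_generation
        return self.records[-1].generation

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            [getattr(rec, col) for col in TRAJECTORY_COLUMNS]
            for rec in self.records
        ]
        return pd.DataFrame(rows, columns=list(TRAJECTORY_COLUMNS))


class OutcomeKind(str, Enum):
    ACCUMULATED = "accumulated"
    EXTINCT = "extinct"


@dataclass(frozen=True)
class Outcome:
    kind: OutcomeKind
    extinction_generation: int | None = None


def classify(trajectory: Trajectory) -> Outcome:
    """ACCUMULATED if active TEs remain at the cutoff, else EXTINCT with the
    first zero-TE generation."""
    if trajectory.extinction_generation is not None:
        return Outcome(OutcomeKind.EXTINCT, trajectory.extinction_generation)
    return Outcome(OutcomeKind.ACCUMULATED)


def derive_seed(
    base_seed: int, scenario_code: str, beneficial_pct: float, replicate: int
) -> int:
    """Deterministic per-cell seed (< 2^31), stable under design growth."""
    key = f"{base_seed}|{scenario_code}|{beneficial_pct:g}|{replicate}"
    digest = hashlib.sha256(key.encode()).digest()
    return int.from_bytes(digest[:4], "big") & 0x7FFFFFFF


def run_replicate(
    params: SimulationParams,
    seed: int,
    *,
    scenario_code: str = "",
    beneficial_pct: float | None = None,
    replicate: int = 0,
) -> Trajectory:
    """Run one replicate to extinction or the generation cutoff.

    Deterministic given ``params`` and ``seed``.  The trajectory starts
    with a generation-0 record of the founding state.
    """
    rng = np.random.default_rng(seed)
    pop = init_population(params, rng)
    records = [
        GenerationRecord(
            generation=0,
            total_active_te=pop.total_active_te(),
            mean_te_per_host=pop.mean_te_per_host(),
            population_size=pop.size,
            mean_fitness=pop.mean_fitness(),
        )
    ]
    while (
        records[-1].total_active_te > 0
        and pop.size > 0
        and pop.generation < params.max_generations
    ):
        records.append(step_generation(pop))
    extinction = (
        records[-1].generation if records[-1].total_active_te == 0 else None
    )
    if beneficial_pct is None:
        beneficial_pct = params.effect_distribution.p_beneficial * 100.0
    return Trajectory(
        scenario_code=scenario_code,
        beneficial_pct=float(beneficial_pct),
        replicate=replicate,
        seed=seed,
        records=records,
        extinction_generation=extinction,
    )


@dataclass
class ResultSet:
    """Trajectories keyed by (scenario code, beneficial %, replicate), plus
    the configuration snapshot needed to replay every run exactly."""

    trajectories: dict[tuple[str, float, int], Trajectory]
    config: dict

    def __len__(self) -> int:
        return len(self.trajectories)

    def __iter__(self):
        return iter(self.trajectories.values())

    def get(
        self, scenario_code: str, beneficial_pct: float, replicate: int
    ) -> Trajectory:
        return self.trajectories[(scenario_code, float(beneficial_pct), replicate)]

    # -- persistence -----------------------------------------------------
    @staticmethod
    def run_filename(scenario_code: str, beneficial_pct: float, replicate: int) -> str:
        return f"{scenario_code}_b{beneficial_pct:g}_r{replicate}.csv"

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for (code, pct, rep), traj in sorted(self.trajectories.items()):
            outcome = classify(traj)
            rows.append(
                {
                    "scenario": code,
                    "beneficial_pct": pct,
                    "replicate": rep,
                    "outcome": outcome.kind.value,
                    "extinction_generation": outcome.extinction_generation,
                    "final_active_te": traj.final_active_te,
                    "seed": traj.seed,
                }
            )
        return pd.DataFrame(rows)

    def write(self, outdir: str | Path) -> Path:
        """Write one trajectory CSV per run, a design summary CSV, and the
        JSON config snapshot; returns the output directory."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for (code, pct, rep), traj in self.trajectories.items():
            traj.to_dataframe().to_csv(
                outdir / self.run_filename(code, pct, rep), index=False
            )
        self.summary_frame().to_csv(outdir / "summary.csv", index=False)
        with open(outdir / "config.json", "w") as fh:
            json.dump(self.config, fh, indent=2)
        return outdir


def _level_map_jsonable(level_map: Mapping[str, Sequence]) -> dict:
    return {axis: list(values) for axis, values in level_map.items()}


def run_design(
    scenarios: Sequence[ParameterScenario | str],
    beneficial_pcts: Sequence[float],
    n_replicates: int,
    base_seed: int,
    *,
    level_map: Mapping[str, Sequence] | None = None,
    defaults: Mapping[str, float | int] | None = None,
) -> ResultSet:
    """Run the full factorial design: every scenario × beneficial % ×
    replicate, each with its own derived seed."""
    if not scenarios or not list(beneficial_pcts):
        raise ValueError("scenarios and beneficial_pcts must be non-empty")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    resolved_scenarios = [
        s if isinstance(s, ParameterScenario) else parse_scenario_code(s)
        for s in scenarios
    ]
    lm = DEFAULT_LEVEL_MAP if level_map is None else dict(level_map)
    merged_defaults = dict(GLOBAL_DEFAULTS)
    if defaults:
        merged_defaults.update(defaults)

    trajectories: dict[tuple[str, float, int], Trajectory] = {}
    seeds: dict[str, int] = {}
    for scenario in resolved_scenarios:
        for pct in beneficial_pcts:
            params = resolve_levels(
                scenario, lm, defaults=defaults, beneficial_pct=float(pct)
            )
            for rep in range(1, n_replicates + 1):
                seed = derive_seed(base_seed, scenario.code, float(pct), rep)
                traj = run_replicate(
                    params,
                    seed,
                    scenario_code=scenario.code,
                    beneficial_pct=float(pct),
                    replicate=rep,
                )
                trajectories[(scenario.code, float(pct), rep)] = traj
                seeds[f"{scenario.code}|{pct:g}|{rep}"] = seed
    config = {
        "version": __version__,
        "level_map": _level_map_jsonable(lm),
        "defaults": merged_defaults,
        "design": {
            "scenarios": [s.code for s in resolved_scenarios],
            "beneficial_pcts": [float(p) for p in beneficial_pcts],
            "n_replicates": n_replicates,
            "max_generations": int(merged_defaults["max_generations"]),
        },
        "base_seed": base_seed,
        "seeds": seeds,
    }
    return ResultSet(trajectories=trajectories, config=config)
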