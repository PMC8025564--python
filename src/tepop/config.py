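"""Run configuration: TOML loading, validation, snapshots, and exact replay.

A run configuration bundles the numeric level map behind the High/Low
parameter axes, the global model constants, and the experimental design
(scenario codes, beneficial percentages, replicate count, generation
cutoff, base seed).  Configurations are loaded from sectioned TOML files,
validated fail-fast (unknown keys and out-of-range values are rejected
rather than defaulted), and written alongside results as a JSON snapshot
that suffices to replay every trajectory bit-identically.
"""

from __future__ import annotations

import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from . import __version__
from .parameters import (
    AXES,
    DEFAULT_LEVEL_MAP,
    GLOBAL_DEFAULTS,
    PUBLISHED_SCENARIO_CODES,
    parse_scenario_code,
    resolve_levels,
)

__all__ = ["RunConfig", "load_config", "snapshot_config", "load_snapshot", "replay_snapshot"]

_DESIGN_KEYS = {
    "scenarios",
    "beneficial_pcts",
    "replicates",
    "max_generations",
    "base_seed",
}
_SECTIONS = {"levels", "defaults", "design", "output"}


@dataclass
class RunConfig:
    """A fully validated run configuration with documented defaults."""

    level_map: dict[str, tuple] = field(
        default_factory=lambda: dict(DEFAULT_LEVEL_MAP)
    )
    defaults: dict[str, float | int] = field(
        default_factory=lambda: dict(GLOBAL_DEFAULTS)
    )
    scenarios: list[str] = field(
        default_factory=lambda: list(PUBLISHED_SCENARIO_CODES)
    )
    beneficial_pcts: list[float] = field(default_factory=lambda: [0.0, 20.0])
    replicates: int = 3
    base_seed: int = 1
    outdir: str = "results"

    def __post_init__(self) -> None:
        for code in self.scenarios:
            parse_scenario_code(code)  # raises on malformed codes
        for pct in self.beneficial_pcts:
            if not 0.0 <= pct <= 20.0:
                raise ValueError(
                    f"beneficial percentage {pct} outside [0, 20]: the fixed "
                    "lethal/deleterious split bounds the beneficial class"
                )
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        missing = set(AXES) - set(self.level_map)
        if missing:
            raise ValueError(f"level map missing axes: {sorted(missing)}")
        unknown = set(self.defaults) - set(GLOBAL_DEFAULTS)
        if unknown:
            raise ValueError(f"unknown global default(s): {sorted(unknown)}")
        # resolving every scenario exercises the numeric range checks
        for code in self.scenarios:
            for pct in self.beneficial_pcts or [20.0]:
                resolve_levels(
                    parse_scenario_code(code),
                    self.level_map,
                    defaults=self.defaults,
                    beneficial_pct=pct,
                )

    @property
    def max_generations(self) -> int:
        return int(self.defaults["max_generations"])


def _parse_level_value(axis: str, value):
    if isinstance(value, str):
        if value == "proportional" and axis == "insertion_bias":
            return None
        raise ValueError(
            f"level value {value!r} for axis {axis!r} is not numeric "
            "(only insertion_bias accepts 'proportional')"
        )
    return value


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a TOML run configuration.

    Recognized sections: ``[levels]`` (axis tables with ``low``/``high``),
    ``[defaults]`` (global model constants), ``[design]`` (scenarios,
    beneficial_pcts, replicates, max_generations, base_seed), ``[output]``
    (``directory``).  An empty file yields all documented defaults; unknown
    sections or keys are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    with open(path, "rb") as fh:
        try:
            raw = tomllib.load(fh)
        except tomllib.TOMLDecodeError as err:
            raise ValueError(f"config file {path} does not parse: {err}") from err

    unknown_sections = set(raw) - _SECTIONS
    if unknown_sections:
        raise ValueError(f"unknown config section(s): {sorted(unknown_sections)}")

    level_map = dict(DEFAULT_LEVEL_MAP)
    for axis, entry in raw.get("levels", {}).items():
        if axis not in AXES:
            raise ValueError(f"unknown level-map axis: {axis!r}")
        if not isinstance(entry, dict) or set(entry) != {"low", "high"}:
            raise ValueError(
                f"level entry for {axis!r} must be a table with exactly "
                "'low' and 'high' keys"
            )
        level_map[axis] = (
            _parse_level_value(axis, entry["low"]),
            _parse_level_value(axis, entry["high"]),
        )

    defaults = dict(GLOBAL_DEFAULTS)
    for key, value in raw.get("defaults", {}).items():
        if key not in GLOBAL_DEFAULTS:
            raise ValueError(f"unknown default key: {key!r}")
        defaults[key] = value

    design = raw.get("design", {})
    unknown_keys = set(design) - _DESIGN_KEYS
    if unknown_keys:
        raise ValueError(f"unknown design key(s): {sorted(unknown_keys)}")
    if "max_generations" in design:
        defaults["max_generations"] = int(design["max_generations"])

    output = raw.get("output", {})
    if set(output) - {"directory"}:
        raise ValueError(
            f"unknown output key(s): {sorted(set(output) - {'directory'})}"
        )

    return RunConfig(
        level_map=level_map,
        defaults=defaults,
        scenarios=list(design.get("scenarios", PUBLISHED_SCENARIO_CODES)),
        beneficial_pcts=[float(p) for p in design.get("beneficial_pcts", [0.0, 20.0])],
        replicates=int(design.get("replicates", 3)),
        base_seed=int(design.get("base_seed", 1)),
        outdir=str(output.get("directory", "results")),
    )


def snapshot_config(config: RunConfig, resultset_dir: str | Path) -> Path:
    """Write a JSON snapshot sufficient for exact replay.

    Includes the artifact version, the full level map and global defaults,
    the design, and every per-cell derived seed along with the resolved
    numeric parameters per (scenario, beneficial %) cell.
    """
    from .experiment import derive_seed  # local import to avoid a cycle

    resultset_dir = Path(resultset_dir)
    resultset_dir.mkdir(parents=True, exist_ok=True)
    cells = {}
    for code in config.scenarios:
        scenario = parse_scenario_code(code)
        for pct in config.beneficial_pcts:
            params = resolve_levels(
                scenario, config.level_map, defaults=config.defaults,
                beneficial_pct=pct,
            )
            dist = params.effect_distribution
            cells[f"{code}|{pct:g}"] = {
                "resolved_params": {
                    "progeny": params.progeny,
                    "excision_rate": params.excision_rate,
                    "death_rate": params.death_rate,
                    "insertion_bias": params.insertion_bias,
                    "mutation_rate": params.mutation_rate,
                    "non_coding_fraction": params.non_coding_fraction,
                    "mutation_effect": params.mutation_effect,
                    "carrying_capacity": params.carrying_capacity,
                    "genome_length": params.genome_length,
                    "initial_te_per_host": params.initial_te_per_host,
                    "transposition_rate": params.transposition_rate,
                    "max_generations": params.max_generations,
                    "effect_probabilities": list(dist.probabilities),
                    "s_deleterious": dist.s_deleterious,
                    "s_beneficial": dist.s_beneficial,
                },
                "seeds": {
                    str(rep): derive_seed(config.base_seed, code, pct, rep)
                    for rep in range(1, config.replicates + 1)
                },
            }
    snapshot = {
        "version": __version__,
        "level_map": {axis: list(v) for axis, v in config.level_map.items()},
        "defaults": config.defaults,
        "design": {
            "scenarios": config.scenarios,
            "beneficial_pcts": config.beneficial_pcts,
            "replicates": config.replicates,
            "max_generations": config.max_generations,
        },
        "base_seed": config.base_seed,
        "cells": cells,
    }
    path = resultset_dir / "snapshot.json"
    with open(path, "w") as fh:
        json.dump(snapshot, fh, indent=2)
    return path


def load_snapshot(path: str | Path) -> dict:
    """Load a snapshot, refusing to proceed if replay data is missing."""
    with open(path) as fh:
        snapshot = json.load(fh)
    required = {"version", "level_map", "defaults", "design", "base_seed", "cells"}
    missing = required - set(snapshot)
    if missing:
        raise ValueError(f"snapshot {path} is missing {sorted(missing)}: refusing replay")
    for key, cell in snapshot["cells"].items():
        if "seeds" not in cell or not cell["seeds"]:
            raise ValueError(
                f"snapshot {path} cell {key!r} has no seeds: refusing replay"
            )
    return snapshot


def replay_snapshot(path: str | Path):
    """Re-run every trajectory recorded in a snapshot, exactly.

    Returns a :class:`~tepop.experiment.ResultSet` identical to the one the
    snapshot was written from.
    """
    from .experiment import run_design  # local import to avoid a cycle

    snapshot = load_snapshot(path)
    level_map = {
        axis: tuple(values) for axis, values in snapshot["level_map"].items()
    }
    design = snapshot["design"]
    defaults = dict(snapshot["defaults"])
    defaults["max_generations"] = design["max_generations"]
    return run_design(
        design["scenarios"],
        design["beneficial_pcts"],
        design["replicates"],
        snapshot["base_seed"],
        level_map=level_map,
        defaults=defaults,
    )
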