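"""Aggregation and plotting of simulation result sets.

Produces the experiment's summary quantities — accumulation/extinction
counts and extinction-generation order statistics per design cell — and the
two figure layouts: TE copy-number trajectories panelled by scenario (the
with/without-beneficial contrast) or by beneficial frequency (the sweep).
The plotted series are the raw per-generation records; nothing is smoothed
or resampled.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy import stats

from .effects import EffectClass, draw_effect_counts
from .experiment import OutcomeKind, ResultSet, classify
from .parameters import InsertionEffectDistribution

__all__ = ["summarize", "recount_from_dir", "plot_trajectories", "calibration_check"]


def summarize(resultset: ResultSet) -> pd.DataFrame:
    """Per-cell summary: run counts, outcomes, extinction order statistics.

    One row per (scenario, beneficial_pct) with ``n_runs``,
    ``n_accumulated``, ``n_extinct``, min/median/max extinction generation,
    and the replicate labels of accumulating runs (e.g. ``"r3"``), which is
    how single persistent runs are identified.
    """
    if len(resultset) == 0:
        raise ValueError("empty ResultSet")
    cells: dict[tuple[str, float], list] = {}
    for (code, pct, rep), traj in sorted(resultset.trajectories.items()):
        cells.setdefault((code, pct), []).append((rep, classify(traj)))
    rows = []
    for (code, pct), outcomes in sorted(cells.items()):
        ext_gens = [
            o.extinction_generation
            for _, o in outcomes
            if o.kind is OutcomeKind.EXTINCT
        ]
        accumulated = [rep for rep, o in outcomes if o.kind is OutcomeKind.ACCUMULATED]
        rows.append(
            {
                "scenario": code,
                "beneficial_pct": pct,
                "n_runs": len(outcomes),
                "n_accumulated": len(accumulated),
                "n_extinct": len(ext_gens),
                "min_extinction": min(ext_gens) if ext_gens else np.nan,
                "median_extinction": float(np.median(ext_gens)) if ext_gens else np.nan,
                "max_extinction": max(ext_gens) if ext_gens else np.nan,
                "accumulated_runs": ";".join(f"r{r}" for r in accumulated),
            }
        )
    return pd.DataFrame(rows)


def recount_from_dir(results_dir: str | Path) -> pd.DataFrame:
    """Independent per-cell recount from trajectory CSVs on disk.

    Reads every per-run CSV written by :meth:`ResultSet.write` (ignoring the
    summary file), re-derives each run's outcome from its final active-TE
    count, and aggregates exactly like :func:`summarize`.  Used to verify
    round-trip integrity of the written results.
    """
    results_dir = Path(results_dir)
    cells: dict[tuple[str, float], list] = {}
    for path in sorted(results_dir.glob("*_b*_r*.csv")):
        stem = path.stem
        code, rest = stem.split("_b", 1)
        pct_str, rep_str = rest.rsplit("_r", 1)
        frame = pd.read_csv(path)
        final = frame.iloc[-1]
        extinct = final["total_active_te"] == 0
        cells.setdefault((code, float(pct_str)), []).append(
            (int(rep_str), extinct, int(final["generation"]) if extinct else None)
        )
    if not cells:
        raise ValueError(f"no trajectory CSVs found under {results_dir}")
    rows = []
    for (code, pct), runs in sorted(cells.items()):
        ext_gens = [g for _, extinct, g in runs if extinct]
        accumulated = [rep for rep, extinct, _ in runs if not extinct]
        rows.append(
            {
                "scenario": code,
                "beneficial_pct": pct,
                "n_runs": len(runs),
                "n_accumulated": len(accumulated),
                "n_extinct": len(ext_gens),
                "min_extinction": min(ext_gens) if ext_gens else np.nan,
                "median_extinction": float(np.median(ext_gens)) if ext_gens else np.nan,
                "max_extinction": max(ext_gens) if ext_gens else np.nan,
                "accumulated_runs": ";".join(f"r{r}" for r in sorted(accumulated)),
            }
        )
    return pd.DataFrame(rows)


def _panel_series(resultset: ResultSet, grouping: str):
    """Group trajectories into panels; within a panel, one line per run."""
    panels: dict[object, list] = {}
    for (code, pct, rep), traj in sorted(resultset.trajectories.items()):
        if grouping == "scenario":
            key, label = code, f"{pct:g}% r{rep}"
        elif grouping == "beneficial_pct":
            key, label = pct, f"{code} r{rep}"
        else:
            raise ValueError(
                f"grouping must be 'scenario' or 'beneficial_pct', got {grouping!r}"
            )
        panels.setdefault(key, []).append((label, traj))
    return panels


def plot_trajectories(
    resultset: ResultSet,
    grouping: str = "scenario",
    outdir: str | Path = ".",
    *,
    stem: str = "trajectories",
    quantity: str = "total_active_te",
    formats: Sequence[str] = ("svg", "png"),
) -> list[Path]:
    """Multi-panel line plots of TE abundance versus generation.

    ``grouping="scenario"`` gives one panel per scenario with replicate
    lines for each beneficial frequency; ``grouping="beneficial_pct"`` gives
    one panel per swept frequency.  ``quantity`` selects the y statistic:
    total active copies (default) or ``"mean_te_per_host"``.  Writes one
    file per requested format and returns their paths; an empty selection
    is a warned no-op.
    """
    panels = _panel_series(resultset, grouping)
    if not panels:
        warnings.warn("no trajectories selected; nothing plotted")
        return []
    n = len(panels)
    ncols = min(3, n)
    nrows = -(-n // ncols)
    fig, axes = plt.subplots(
        nrows, ncols, figsize=(4.2 * ncols, 3.2 * nrows), squeeze=False, sharex=True
    )
    flat = axes.ravel()
    for ax, (key, series) in zip(flat, sorted(panels.items(), key=lambda kv: str(kv[0]))):
        for label, traj in series:
            gens = [r.generation for r in traj.records]
            ys = [getattr(r, quantity) for r in traj.records]
            ax.plot(gens, ys, lw=1.0, label=label)
        title = key if grouping == "scenario" else f"beneficial {key:g}%"
        ax.set_title(title, fontsize=10)
        ax.set_xlabel("generation")
        ax.set_ylabel(quantity.replace("_", " "))
        if len(series) <= 8:
            ax.legend(fontsize=6, frameon=False)
    for ax in flat[n:]:
        ax.set_visible(False)
    fig.tight_layout()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for fmt in formats:
        path = outdir / f"{stem}_{grouping}.{fmt}"
        fig.savefig(path)
        paths.append(path)
    plt.close(fig)
    return paths


def calibration_check(
    dist: InsertionEffectDistribution,
    n_draws: int,
    seed: int,
    *,
    confidence: float = 0.95,
) -> pd.DataFrame:
    """Empirical effect-class frequencies with exact binomial intervals.

    Draws ``n_draws`` insertion effects and returns one row per class with
    its expected probability, observed count and frequency, and the
    Clopper–Pearson interval at the given confidence level.
    """
    if n_draws < 1:
        raise ValueError(f"n_draws={n_draws} must be >= 1")
    rng = np.random.default_rng(seed)
    counts = draw_effect_counts(dist, n_draws, rng)
    expected = dist.probabilities
    rows = []
    for cls, k, p in zip(EffectClass, counts, expected):
        interval = stats.binomtest(int(k), n_draws).proportion_ci(
            confidence_level=confidence, method="exact"
        )
        rows.append(
            {
                "effect_class": cls.name,
                "expected_p": float(p),
                "count": int(k),
                "frequency": k / n_draws,
                "ci_low": interval.low,
                "ci_high": interval.high,
            }
        )
    return pd.DataFrame(rows)
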