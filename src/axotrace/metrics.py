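"""Per-movie transport statistics from segmented tracks."""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .tracking import (ANTEROGRADE, RETROGRADE, MOTILE, STATIONARY,
                       Pause, Run)

DIRECTIONS = (ANTEROGRADE, RETROGRADE)


def flux(runs: Sequence[Run], axon_length_um: float, duration_min: float) -> Dict[str, float]:
    """Sum of run displacements per direction, divided by (l x t).

    Units: um travelled per um of axon per minute.
    """
    if axon_length_um <= 0:
        raise ValueError("axon length must be positive")
    if duration_min <= 0:
        raise ValueError("duration must be positive")
    out = {}
    for direction in DIRECTIONS:
        total = sum(r.displacement_um for r in runs if r.direction == direction)
        out[direction] = total / (axon_length_um * duration_min)
    return out


def _mean_sd(values: List[float]):
    if not values:
        return math.nan, math.nan
    arr = np.asarray(values, dtype=float)
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return float(arr.mean()), sd


def velocity_stats(runs: Sequence[Run]) -> Dict[str, dict]:
    """Per-direction mean +/- SD of run speed (displacement / moving time)."""
    out = {}
    for direction in DIRECTIONS:
        speeds = [r.mean_speed_um_s for r in runs if r.direction == direction]
        mean, sd = _mean_sd(speeds)
        out[direction] = {"mean": mean, "sd": sd, "n": len(speeds)}
    return out


def run_length_stats(runs: Sequence[Run]) -> Dict[str, dict]:
    out = {}
    for direction in DIRECTIONS:
        lengths = [r.displacement_um for r in runs if r.direction == direction]
        mean, sd = _mean_sd(lengths)
        out[direction] = {"mean": mean, "sd": sd, "n": len(lengths)}
    return out


def pause_stats(pauses: Sequence[Pause]) -> Dict[str, dict]:
    """Per-direction mean +/- SD pause duration (direction of preceding run)."""
    out = {}
    for direction in DIRECTIONS:
        durs = [p.duration_s for p in pauses if p.direction == direction]
        mean, sd = _mean_sd(durs)
        out[direction] = {"mean": mean, "sd": sd, "n": len(durs)}
    return out


def density(runs: Sequence[Run], n_stationary: int, length_um: float) -> float:
    """(directed runs + stationary objects) per um of kymograph."""
    if length_um <= 0:
        raise ValueError("kymograph length must be positive")
    if n_stationary < 0:
        raise ValueError("n_stationary must be >= 0")
    return (len(runs) + n_stationary) / length_um


def percent_stationary(classifications: Sequence[str],
                       weights: Optional[Sequence[float]] = None) -> float:
    """100 x stationary / (stationary + motile); unclassified excluded.

    ``weights`` (defaults to 1 per track) let callers weight each track by
    the fraction of the movie it spans, so that fragments of one vesicle
    sum to a single counted object instead of inflating the census.
    """
    if weights is None:
        weights = [1.0] * len(classifications)
    if len(weights) != len(classifications):
        raise ValueError("weights must align with classifications")
    w_stat = sum(w for c, w in zip(classifications, weights) if c == STATIONARY)
    w_mot = sum(w for c, w in zip(classifications, weights) if c == MOTILE)
    if w_stat + w_mot == 0:
        raise ValueError("no classified tracks")
    return 100.0 * w_stat / (w_stat + w_mot)


@dataclass
class TransportSummary:
    """All per-movie transport parameters, mirroring the per-video tables."""

    anterograde_flux: float
    retrograde_flux: float
    anterograde_velocity: float
    anterograde_velocity_sd: float
    retrograde_velocity: float
    retrograde_velocity_sd: float
    anterograde_run_length: float
    anterograde_run_length_sd: float
    retrograde_run_length: float
    retrograde_run_length_sd: float
    anterograde_pause_duration: float
    retrograde_pause_duration: float
    anterograde_n_runs: int
    retrograde_n_runs: int
    percent_stationary: float
    density_per_um: float
    directionality: float            # fraction anterograde of directed runs
    axon_length_um: float
    duration_min: float

    def to_dict(self) -> dict:
        return asdict(self)


def summarize(runs: Sequence[Run], pauses: Sequence[Pause],
              classifications: Sequence[str], axon_length_um: float,
              duration_s: float,
              class_weights: Optional[Sequence[float]] = None) -> TransportSummary:
    """Assemble one movie's TransportSummary from segmented events."""
    duration_min = duration_s / 60.0
    fl = flux(runs, axon_length_um, duration_min)
    vel = velocity_stats(runs)
    rl = run_length_stats(runs)
    ps = pause_stats(pauses)
    n_stationary = sum(1 for c in classifications if c == STATIONARY)
    n_a = vel[ANTEROGRADE]["n"]
    n_r = vel[RETROGRADE]["n"]
    try:
        pct = percent_stationary(classifications, class_weights)
    except ValueError:
        pct = math.nan
    return TransportSummary(
        anterograde_flux=fl[ANTEROGRADE],
        retrograde_flux=fl[RETROGRADE],
        anterograde_velocity=vel[ANTEROGRADE]["mean"],
        anterograde_velocity_sd=vel[ANTEROGRADE]["sd"],
        retrograde_velocity=vel[RETROGRADE]["mean"],
        retrograde_velocity_sd=vel[RETROGRADE]["sd"],
        anterograde_run_length=rl[ANTEROGRADE]["mean"],
        anterograde_run_length_sd=rl[ANTEROGRADE]["sd"],
        retrograde_run_length=rl[RETROGRADE]["mean"],
        retrograde_run_length_sd=rl[RETROGRADE]["sd"],
        anterograde_pause_duration=ps[ANTEROGRADE]["mean"],
        retrograde_pause_duration=ps[RETROGRADE]["mean"],
        anterograde_n_runs=n_a,
        retrograde_n_runs=n_r,
        percent_stationary=pct,
        density_per_um=density(runs, n_stationary, axon_length_um),
        directionality=n_a / (n_a + n_r) if (n_a + n_r) else math.nan,
        axon_length_um=axon_length_um,
        duration_min=duration_min,
    )


def aggregate(summaries: Sequence[TransportSummary]) -> pd.DataFrame:
    """Mean +/- SEM of each summary field across movies (per-axon units)."""
    if not summaries:
        raise ValueError("no summaries to aggregate")
    df = pd.DataFrame([s.to_dict() for s in summaries])
    rows = []
    for col in df.columns:
        vals = df[col].dropna().to_numpy(dtype=float)
        n = len(vals)
        mean = float(vals.mean()) if n else math.nan
        sem = float(vals.std(ddof=1) / math.sqrt(n)) if n > 1 else math.nan
        rows.append({"parameter": col, "mean": mean, "sem": sem, "n": n})
    return pd.DataFrame(rows)
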