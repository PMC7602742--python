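"""Non-compartmental analysis and model-verification statistics.

Exposure metrics use the linear trapezoidal rule with no extrapolation
(predicted/observed comparisons are made over the same time interval), a
log-linear terminal fit for half-life, first-attainment Tmax, and t-based
95% confidence intervals of observed replicate means.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "NCAResult",
    "auc_trapezoid",
    "cmax_tmax",
    "terminal_half_life",
    "nca",
    "fold_error",
    "relative_error_percent",
    "observed_ci95",
    "relative_tumor_growth",
]


@dataclass
class NCAResult:
    auc_0_t: float  # ng·h/mL
    cmax: float  # ng/mL
    tmax: float  # h
    t_half: float | None  # h; None when no terminal fit was requested
    terminal_points_used: int


def _check_profile(times, concentrations):
    t = np.asarray(times, dtype=float)
    c = np.asarray(concentrations, dtype=float)
    if t.ndim != 1 or t.shape != c.shape:
        raise ValueError("times and concentrations must be equal-length 1-D arrays")
    if len(t) < 2:
        raise ValueError("need at least 2 points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if np.any(c < 0):
        raise ValueError("concentrations must be >= 0")
    return t, c


def auc_trapezoid(times, concentrations) -> float:
    """Linear trapezoidal AUC over the given points, no extrapolation."""
    t, c = _check_profile(times, concentrations)
    return float(np.trapezoid(c, t))


def cmax_tmax(times, concentrations) -> tuple[float, float]:
    """Maximum concentration and the first time it is attained."""
    t = np.asarray(times, dtype=float)
    c = np.asarray(concentrations, dtype=float)
    if len(t) == 0 or len(t) != len(c):
        raise ValueError("times and concentrations must be non-empty and aligned")
    i = int(np.argmax(c))  # argmax returns the first maximizer
    return float(c[i]), float(t[i])


def terminal_half_life(times, concentrations, n_terminal: int = 3) -> float:
    """ln2 / |slope| of the log-linear fit over the last ``n_terminal`` points."""
    if n_terminal < 3:
        raise ValueError("n_terminal must be >= 3")
    t, c = _check_profile(times, concentrations)
    if n_terminal > len(t):
        raise ValueError("n_terminal exceeds the number of points")
    _, tmax = cmax_tmax(t, c)
    tt, cc = t[-n_terminal:], c[-n_terminal:]
    if tt[0] < tmax:
        raise ValueError("terminal window must start after Tmax")
    if np.any(cc <= 0):
        raise ValueError("terminal window contains non-positive concentrations")
    slope, _ = np.polyfit(tt, np.log(cc), 1)
    if slope >= 0:
        raise ValueError("terminal slope is non-negative; no elimination phase")
    return float(np.log(2.0) / abs(slope))


def nca(times, concentrations, n_terminal: int | None = 3) -> NCAResult:
    """Bundle AUC (trapezoid), Cmax/Tmax and optional terminal half-life."""
    auc = auc_trapezoid(times, concentrations)
    cmax, tmax = cmax_tmax(times, concentrations)
    t_half = None
    used = 0
    if n_terminal is not None:
        t_half = terminal_half_life(times, concentrations, n_terminal)
        used = n_terminal
    return NCAResult(auc_0_t=auc, cmax=cmax, tmax=tmax, t_half=t_half,
                     terminal_points_used=used)


def fold_error(predicted: float, observed: float) -> float:
    """Predicted / observed ratio of a PK metric."""
    if observed <= 0:
        raise ValueError("observed must be > 0")
    return predicted / observed


def relative_error_percent(predicted, observed_mean):
    """100 * (pred - obs_mean) / obs_mean, per time point."""
    pred = np.asarray(predicted, dtype=float)
    obs = np.asarray(observed_mean, dtype=float)
    if pred.shape != obs.shape:
        raise ValueError("predicted and observed series must be aligned")
    if np.any(obs <= 0):
        raise ValueError("observed means must be > 0 at every point")
    return 100.0 * (pred - obs) / obs


def observed_ci95(replicates) -> tuple[float, float, float]:
    """Mean and t-based 95% CI of replicate observations at one time point.

    A single replicate yields ``(mean, nan, nan)`` so callers can flag it.
    """
    x = np.asarray(replicates, dtype=float)
    if x.ndim != 1 or len(x) < 1:
        raise ValueError("replicates must be a non-empty 1-D array")
    m = float(np.mean(x))
    if len(x) < 2:
        return m, float("nan"), float("nan")
    se = float(np.std(x, ddof=1) / np.sqrt(len(x)))
    tcrit = float(stats.t.ppf(0.975, df=len(x) - 1))
    return m, m - tcrit * se, m + tcrit * se


def relative_tumor_growth(volumes: pd.DataFrame, vehicle_group: str) -> pd.DataFrame:
    """Within-subject day-1-normalized growth, relative to the vehicle mean.

    ``volumes`` needs columns ``subject_id``, ``group``, ``time`` (day) and
    ``value``; the earliest time per subject is the day-1 baseline.
    """
    required = {"subject_id", "group", "time", "value"}
    missing = required - set(volumes.columns)
    if missing:
        raise ValueError(f"missing column(s): {sorted(missing)}")
    df = volumes.copy()
    baseline = df.sort_values("time").groupby("subject_id")["value"].first()
    if (baseline <= 0).any():
        raise ValueError("day-1 baseline values must be > 0")
    df["ratio"] = df["value"] / df["subject_id"].map(baseline)
    vehicle = df[df["group"] == vehicle_group]
    if vehicle.empty:
        raise ValueError(f"vehicle group {vehicle_group!r} not found")
    veh_mean = vehicle.groupby("time")["ratio"].mean()
    missing_t = sorted(set(df["time"]) - set(veh_mean.index))
    if missing_t:
        raise ValueError(f"vehicle data missing at time(s) {missing_t}")
    df["relative_growth"] = df["ratio"] / df["time"].map(veh_mean)
    return df[["subject_id", "group", "time", "relative_growth"]]
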