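"""Parameter estimation and local sensitivity analysis.

The objective is weighted least squares with each dataset weighted by the
reciprocal of its squared maximum observation, minimized by Nelder-Mead with
a termination rule based on the relative improvement of the objective
function value between simplex iterations (default: stop below 1%).
Sensitivity is local: central finite differences at a fractional
perturbation, reported as normalized coefficients
(Δmetric/metric)/(Δparam/param).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

__all__ = [
    "FreeParameter",
    "Dataset",
    "FitSpec",
    "EstimationResult",
    "wls_objective",
    "fit",
    "local_sensitivity",
]


@dataclass
class FreeParameter:
    name: str
    initial: float
    lower: float = -np.inf
    upper: float = np.inf
    transform: str = "linear"  # or "log"

    def __post_init__(self) -> None:
        if not self.lower <= self.initial <= self.upper:
            raise ValueError(
                f"initial value of {self.name!r} is outside [{self.lower}, {self.upper}]"
            )
        if self.transform not in ("linear", "log"):
            raise ValueError(f"unknown transform {self.transform!r}")
        if self.transform == "log" and (self.initial <= 0 or self.lower < 0):
            raise ValueError("log transform requires positive initial and bounds")

    def to_internal(self, value: float) -> float:
        return np.log(value) if self.transform == "log" else value

    def to_external(self, internal: float) -> float:
        return float(np.exp(internal)) if self.transform == "log" else float(internal)


@dataclass
class Dataset:
    """One observed output: name, sampling times and values (model units)."""

    output: str
    times: np.ndarray
    values: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.size == 0:
            raise ValueError("dataset times and values must be non-empty and aligned")


@dataclass
class FitSpec:
    free_parameters: Sequence[FreeParameter]
    datasets: Sequence[Dataset]
    objective: str = "wls_recip_max_sq"
    termination_rtol: float = 0.01
    max_iter: int = 1000

    def __post_init__(self) -> None:
        if not self.free_parameters:
            raise ValueError("at least one free parameter is required")
        if not self.datasets:
            raise ValueError("at least one dataset is required")
        if self.objective != "wls_recip_max_sq":
            raise ValueError(f"unknown objective {self.objective!r}")


@dataclass
class EstimationResult:
    estimates: dict[str, float]
    ofv: float
    n_evaluations: int
    converged: bool
    trace: list[float] = field(default_factory=list)


def wls_objective(
    predicted: Mapping[str, np.ndarray], datasets: Sequence[Dataset]
) -> float:
    """Sum over datasets of squared residuals / max(obs)^2.

    Scaling a dataset's observations and predictions by a common factor
    leaves its contribution unchanged, so outputs in different units
    contribute comparably.
    """
    if not datasets:
        raise ValueError("at least one dataset is required")
    total = 0.0
    for ds in datasets:
        if ds.output not in predicted:
            raise ValueError(f"prediction missing for output {ds.output!r}")
        pred = np.asarray(predicted[ds.output], dtype=float)
        if pred.shape != ds.values.shape:
            raise ValueError(f"prediction for {ds.output!r} is misaligned")
        wmax = float(np.max(np.abs(ds.values)))
        if wmax == 0:
            raise ValueError(f"dataset {ds.output!r} has all-zero observations")
        total += float(np.sum((ds.values - pred) ** 2)) / wmax**2
    return total


def fit(
    spec: FitSpec,
    predict: Callable[[dict[str, float]], Mapping[str, np.ndarray]],
) -> EstimationResult:
    """Nelder-Mead minimization of the WLS objective.

    ``predict`` maps a parameter dict to predictions evaluated at each
    dataset's times.  Out-of-bounds proposals receive an infinite objective,
    so estimates respect the bounds.  Iteration stops when the best objective
    improves by less than ``termination_rtol`` relative over one simplex
    update (or at ``max_iter``).
    """
    params = list(spec.free_parameters)
    x0 = np.array([p.to_internal(p.initial) for p in params])
    n_eval = 0
    trace: list[float] = []

    def objective(x: np.ndarray) -> float:
        nonlocal n_eval
        n_eval += 1
        values = {}
        for p, xi in zip(params, x):
            v = p.to_external(xi)
            if not p.lower <= v <= p.upper:
                return np.inf
            values[p.name] = v
        pred = predict(values)
        val = wls_objective(pred, spec.datasets)
        if not np.isfinite(val):
            return np.inf
        return val

    f0 = objective(x0)
    if not np.isfinite(f0):
        raise ValueError("objective is non-finite at the initial point")

    converged = [False]
    # compare against the best OFV a few simplex updates back, so single
    # non-improving iterations (contractions/shrinks) do not stop the search
    window = 10

    def callback(xk: np.ndarray) -> None:
        cur = objective(xk)
        trace.append(cur)
        if len(trace) < window:
            return
        prev = trace[-window]
        if prev <= 0 or (prev - cur) / prev < spec.termination_rtol:
            converged[0] = True
            raise StopIteration

    res = minimize(
        objective, x0, method="Nelder-Mead",
        callback=callback if spec.termination_rtol > 0 else None,
        options={"maxiter": spec.max_iter, "xatol": 1e-12, "fatol": 1e-14},
    )
    x_best, f_best = res.x, float(res.fun)
    if f0 <= f_best:  # the initial point may remain the best (e.g. perfect fit)
        x_best, f_best = x0, f0
    estimates = {p.name: p.to_external(xi) for p, xi in zip(params, x_best)}
    return EstimationResult(
        estimates=estimates, ofv=f_best, n_evaluations=n_eval,
        converged=bool(converged[0] or res.success), trace=trace,
    )


def local_sensitivity(
    evaluate: Callable[[dict[str, float]], Mapping[str, float]],
    base_parameters: Mapping[str, float],
    parameters: Sequence[str] | None = None,
    perturbation: float = 0.2,
    metrics: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Normalized local sensitivity coefficients by central differences.

    ``evaluate`` maps a full parameter dict to metric values (e.g. plasma
    AUC_0-t and Cmax).  Each listed parameter is perturbed by ±``perturbation``
    (fraction of its base value); a failed evaluation flags the row instead of
    aborting the table.
    """
    if not 0 < perturbation <= 0.5:
        raise ValueError("perturbation must lie in (0, 0.5]")
    names = list(parameters) if parameters is not None else list(base_parameters)
    base = dict(base_parameters)
    base_metrics = dict(evaluate(base))
    wanted = list(metrics) if metrics is not None else list(base_metrics)
    rows = []
    for name in names:
        if name not in base:
            raise ValueError(f"unknown parameter {name!r}")
        try:
            up = dict(base)
            up[name] = base[name] * (1 + perturbation)
            down = dict(base)
            down[name] = base[name] * (1 - perturbation)
            m_up = evaluate(up)
            m_down = evaluate(down)
            for metric in wanted:
                coeff = (m_up[metric] - m_down[metric]) / (
                    2.0 * perturbation * base_metrics[metric]
                )
                rows.append({
                    "parameter": name, "perturbation": perturbation,
                    "metric": metric, "coefficient": float(coeff), "ok": True,
                })
        except Exception as exc:  # noqa: BLE001 - row-level failure policy
            for metric in wanted:
                rows.append({
                    "parameter": name, "perturbation": perturbation,
                    "metric": metric, "coefficient": float("nan"), "ok": False,
                    "error": str(exc),
                })
    return pd.DataFrame(rows)
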