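"""Synthetic observed datasets with the structure of the two mouse studies.

Two designs are emulated: (a) the destructive-sampling tissue-distribution
study (groups of mice sacrificed per time point, so each record is an
independent pseudo-animal with no within-animal correlation), and (b) the
longitudinal xenograft tumor-growth study (weekly whole-body imaging of the
same subjects, with a shared multiplicative baseline jitter on the initial
tumor burden).  Residuals are proportional lognormal by default, which keeps
concentrations and volumes positive and gives replicates an empirical CV
equal to the design CV.  The noise-free model truth is stored alongside every
record for parameter-recovery tests.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pbpk import PBPKModel, DoseRegimen, simulate
from .regimen import RegimenSpec, expand_regimen
from .tgi import TGIParams, simulate_tgi

__all__ = ["PKStudyDesign", "TGIStudyDesign", "generate_pk_dataset",
           "generate_tgi_dataset"]

RESIDUAL_MODELS = ("proportional_lognormal", "additive", "combined")


def _noise_factors(rng: np.random.Generator, model: str, cv: float, truth: np.ndarray):
    """Return noisy observations around ``truth`` under the residual model."""
    if cv == 0:
        return truth.copy()
    if model == "proportional_lognormal":
        if cv > 1:
            warnings.warn("cv > 1 with a lognormal residual model is unusual",
                          RuntimeWarning, stacklevel=3)
        sigma = np.sqrt(np.log1p(cv**2))
        return truth * np.exp(sigma * rng.standard_normal(truth.shape))
    if model == "additive":
        # cv is interpreted as an absolute SD in the value units
        return np.clip(truth + cv * rng.standard_normal(truth.shape), 0.0, None)
    if model == "combined":
        sigma = np.sqrt(np.log1p(cv**2))
        prop = truth * np.exp(sigma * rng.standard_normal(truth.shape))
        return np.clip(prop + cv * rng.standard_normal(truth.shape), 0.0, None)
    raise ValueError(f"unknown residual model {model!r}")


@dataclass
class PKStudyDesign:
    """Destructive-sampling PK study: n mice sacrificed per time point."""

    timepoints: tuple[float, ...] = (0.5, 1.0, 3.0, 6.0, 9.0, 12.0, 24.0)
    n_per_timepoint: int = 5
    outputs: tuple[str, ...] = ("plasma",)
    residual_model: str = "proportional_lognormal"
    cv: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        t = tuple(float(x) for x in self.timepoints)
        if any(x <= 0 for x in t) or any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("timepoints must be positive and increasing")
        self.timepoints = t
        if self.n_per_timepoint < 1:
            raise ValueError("n_per_timepoint must be >= 1")
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        if self.residual_model not in RESIDUAL_MODELS:
            raise ValueError(f"unknown residual model {self.residual_model!r}")


@dataclass
class TGIStudyDesign:
    """Longitudinal tumor-growth study: weekly imaging of fixed subjects."""

    groups: tuple[tuple[str, float], ...] = (
        ("vehicle", 0.0), ("1mgkg", 1.0), ("5mgkg", 5.0), ("10mgkg", 10.0),
    )  # (label, dose mg/kg); 0 marks the vehicle group
    schedule: str = "three_weekly"
    duration: float = 65.0  # days
    n_per_group: int = 10
    observation_interval: float = 7.0  # days
    residual_model: str = "proportional_lognormal"
    cv: float = 0.15
    baseline_cv: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if not any(dose == 0 for _, dose in self.groups):
            raise ValueError("a vehicle group (dose 0) must be present")
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if self.residual_model not in RESIDUAL_MODELS:
            raise ValueError(f"unknown residual model {self.residual_model!r}")

    @property
    def observation_days(self) -> np.ndarray:
        """Imaging days since treatment start (day 1 = start = 0 here)."""
        return np.arange(0.0, self.duration, self.observation_interval)


def generate_pk_dataset(
    design: PKStudyDesign, model: PBPKModel, regimen: DoseRegimen
) -> pd.DataFrame:
    """Simulate the model and draw noisy destructive-sampling observations.

    Returns a tidy frame with one row per (output, time, pseudo-animal) and a
    ``truth`` column carrying the noise-free model prediction.
    """
    rng = np.random.default_rng(design.seed)
    t_grid = np.concatenate([[0.0], np.asarray(design.timepoints)])
    result = simulate(model, regimen, t_grid=t_grid)
    rows = []
    for output in design.outputs:
        if output not in result.concentrations:
            raise ValueError(f"model does not produce output {output!r}")
        truth = result.concentrations[output][1:]  # drop the t=0 anchor
        reps = np.repeat(truth, design.n_per_timepoint)
        noisy = _noise_factors(rng, design.residual_model, design.cv, reps)
        for j, (t, tr) in enumerate(zip(np.repeat(design.timepoints,
                                                  design.n_per_timepoint),
                                        reps)):
            rows.append({
                "study": "pk", "subject_id": f"{output}_t{t:g}_m{j % design.n_per_timepoint + 1}",
                "group": "10mgkg", "output": output, "time": t, "time_unit": "h",
                "value": noisy[j], "value_unit": "ng/mL", "truth": tr,
            })
    return pd.DataFrame(rows)


def generate_tgi_dataset(
    design: TGIStudyDesign,
    tgi_params: TGIParams,
    pbpk_model: PBPKModel | None = None,
    body_weight: float = 20.0,
) -> pd.DataFrame:
    """Per-subject weekly tumor volumes around the TGI model truth.

    Treated groups need ``pbpk_model`` to provide the plasma driver; the
    vehicle group uses the unperturbed model.  Subject baselines get a shared
    multiplicative jitter (CV ``baseline_cv``) applied to the initial tumor
    mass, and observations carry the residual model on top.
    """
    rng = np.random.default_rng(design.seed)
    obs_days = design.observation_days
    rows = []
    for label, dose in design.groups:
        if dose == 0:
            profile = None
        else:
            if pbpk_model is None:
                raise ValueError("pbpk_model is required for treated groups")
            reg = expand_regimen(RegimenSpec(
                dose_mg_per_kg=dose, schedule=design.schedule,
                duration=design.duration, body_weight=body_weight,
            ))
            t_h = np.arange(0.0, design.duration * 24.0 + 0.05, 0.05)
            sim = simulate(pbpk_model, reg, t_grid=t_h, rtol=1e-6, atol=1e-8)
            profile = (t_h, sim.concentrations["plasma"])
        group_truth = simulate_tgi(tgi_params, plasma_profile=profile,
                                   duration=design.duration, t_eval=obs_days)
        base_volume = group_truth.volume  # mL, at the group-level baseline w0
        for subject in range(design.n_per_group):
            jitter = 1.0
            if design.baseline_cv > 0:
                sigma_b = np.sqrt(np.log1p(design.baseline_cv**2))
                jitter = float(np.exp(sigma_b * rng.standard_normal()))
            truth = base_volume * jitter  # growth is near-scale-invariant early on
            noisy = _noise_factors(rng, design.residual_model, design.cv, truth)
            for day, tr, ob in zip(obs_days, truth, noisy):
                rows.append({
                    "study": "tgi", "subject_id": f"{label}_s{subject + 1:02d}",
                    "group": label, "output": "tumor_volume", "time": day,
                    "time_unit": "day", "value": ob, "value_unit": "mL",
                    "truth": tr,
                })
    return pd.DataFrame(rows)
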