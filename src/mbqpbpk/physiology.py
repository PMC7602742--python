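"""Mouse system physiology for the whole-body PBPK model.

Tissue volumes scale linearly with body weight and blood flows with cardiac
output, so a single pinned reference animal (20 g mouse) generates the
parameter set for any body weight.  Defaults live in a versioned JSON asset
(``data/physiology_mouse.json``); every entry can be overridden through
:func:`build_mouse_physiology`, after which non-overridden flows are
renormalized so that the systemic flows still sum to cardiac output.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

__all__ = [
    "PhysiologyParams",
    "build_mouse_physiology",
    "whole_liver_unbound_clint",
    "SYSTEMIC_TISSUES",
]

#: Systemic (non-blood, non-lung) tissues of the full-body model.  Spleen and
#: gut drain into the liver portal inflow; everything else drains to venous
#: blood directly.
SYSTEMIC_TISSUES = (
    "heart",
    "kidney",
    "liver",
    "spleen",
    "gut",
    "muscle",
    "adipose",
    "skin",
    "bone",
    "brain",
    "rest_of_body",
)

_FLOW_KEYS = (
    "heart",
    "kidney",
    "liver_arterial",
    "gut",
    "spleen",
    "muscle",
    "adipose",
    "skin",
    "bone",
    "brain",
    "rest_of_body",
)


def _load_defaults() -> dict:
    with resources.files("mbqpbpk.data").joinpath("physiology_mouse.json").open() as fh:
        return json.load(fh)


@dataclass
class PhysiologyParams:
    """Complete mouse system parameter set consumed by the PBPK ODE system.

    Volumes in mL, flows in mL/min, masses in g.  ``tissue_flows`` carries the
    hepatic-arterial flow under ``liver_arterial`` and the derived portal
    inflow (spleen + gut outflow) under ``liver_portal``; ``lung`` flow equals
    cardiac output.
    """

    body_weight: float
    cardiac_output: float
    tissue_volumes: dict[str, float]
    tissue_flows: dict[str, float]
    gfr: float
    liver_weight: float
    hepatocellularity: float
    tissue_density: dict[str, float]
    hematocrit: float

    def density(self, tissue: str) -> float:
        return self.tissue_density.get(tissue, self.tissue_density.get("default", 1.0))

    @property
    def blood_volume(self) -> float:
        return self.tissue_volumes["arterial_blood"] + self.tissue_volumes["venous_blood"]

    def systemic_flow_sum(self) -> float:
        return sum(self.tissue_flows[k] for k in _FLOW_KEYS)

    def liver_total_inflow(self) -> float:
        return (
            self.tissue_flows["liver_arterial"]
            + self.tissue_flows["spleen"]
            + self.tissue_flows["gut"]
        )

    def validate(self) -> None:
        for name, v in self.tissue_volumes.items():
            if v <= 0:
                raise ValueError(f"tissue volume {name!r} must be > 0, got {v}")
        for name, q in self.tissue_flows.items():
            if q <= 0:
                raise ValueError(f"tissue flow {name!r} must be > 0, got {q}")
        if not 0 < self.hematocrit < 1:
            raise ValueError(f"hematocrit must lie in (0, 1), got {self.hematocrit}")
        if self.body_weight <= 0 or self.cardiac_output <= 0:
            raise ValueError("body_weight and cardiac_output must be > 0")
        if self.gfr <= 0 or self.liver_weight <= 0 or self.hepatocellularity <= 0:
            raise ValueError("gfr, liver_weight and hepatocellularity must be > 0")
        rel = abs(self.systemic_flow_sum() - self.cardiac_output) / self.cardiac_output
        if rel > 1e-6:
            raise ValueError(
                f"systemic flows sum to {self.systemic_flow_sum():.6g} mL/min, "
                f"cardiac output is {self.cardiac_output:.6g} mL/min"
            )
        if abs(self.tissue_flows["lung"] - self.cardiac_output) > 1e-9 * self.cardiac_output:
            raise ValueError("lung flow must equal cardiac output")
        portal = self.tissue_flows["spleen"] + self.tissue_flows["gut"]
        if abs(self.tissue_flows["liver_portal"] - portal) > 1e-9 * max(portal, 1.0):
            raise ValueError("liver portal inflow must equal spleen + gut outflow")


_SCALAR_OVERRIDES = {
    "cardiac_output",
    "gfr",
    "hematocrit",
    "hepatocellularity",
    "liver_weight",
}
_MAP_OVERRIDES = {"tissue_volumes", "tissue_flows", "tissue_density"}


def build_mouse_physiology(
    body_weight: float = 20.0, overrides: dict | None = None
) -> PhysiologyParams:
    """Build a complete, invariant-satisfying mouse parameter set.

    Parameters
    ----------
    body_weight:
        Body weight in grams.  Fractional volumes and flows scale linearly.
    overrides:
        Optional partial parameter map.  Scalar keys: ``cardiac_output``,
        ``gfr``, ``hematocrit``, ``hepatocellularity``, ``liver_weight``.
        Nested maps: ``tissue_volumes``, ``tissue_flows``, ``tissue_density``.
        Overrides are applied last; afterwards the non-overridden systemic
        flows are rescaled so they still sum to cardiac output.
    """
    if body_weight <= 0:
        raise ValueError(f"body_weight must be > 0, got {body_weight}")
    overrides = dict(overrides or {})
    defaults = _load_defaults()

    unknown = set(overrides) - _SCALAR_OVERRIDES - _MAP_OVERRIDES
    if unknown:
        raise ValueError(f"unknown override key(s): {sorted(unknown)}")

    co = body_weight * defaults["cardiac_output_ml_min_per_g"]
    gfr = body_weight * defaults["gfr_ml_min_per_g"]
    hct = defaults["hematocrit"]
    hep = defaults["hepatocellularity_1e6_cells_per_g"]
    volumes = {
        t: f * body_weight for t, f in defaults["volume_fraction_of_bw"].items()
    }
    density = dict(defaults["tissue_density_g_per_ml"])

    if "cardiac_output" in overrides:
        co = float(overrides["cardiac_output"])
    if "gfr" in overrides:
        gfr = float(overrides["gfr"])
    if "hematocrit" in overrides:
        hct = float(overrides["hematocrit"])
    if "hepatocellularity" in overrides:
        hep = float(overrides["hepatocellularity"])
    for t, v in overrides.get("tissue_density", {}).items():
        density[t] = float(v)
    vol_over = overrides.get("tissue_volumes", {})
    unknown = set(vol_over) - set(volumes)
    if unknown:
        raise ValueError(f"unknown tissue volume override(s): {sorted(unknown)}")
    for t, v in vol_over.items():
        if float(v) <= 0:
            raise ValueError(f"tissue volume override {t!r} must be > 0, got {v}")
        volumes[t] = float(v)

    # Flows: start from cardiac-output fractions, fix any overrides, then
    # rescale the remaining flows so systemic flow conservation holds.
    flows = {k: f * co for k, f in defaults["flow_fraction_of_cardiac_output"].items()}
    flow_over = dict(overrides.get("tissue_flows", {}))
    for banned in ("lung", "liver_portal"):
        if banned in flow_over:
            raise ValueError(
                f"flow {banned!r} is derived and cannot be overridden directly"
            )
    unknown = set(flow_over) - set(_FLOW_KEYS)
    if unknown:
        raise ValueError(f"unknown tissue flow override(s): {sorted(unknown)}")
    for k, q in flow_over.items():
        if float(q) <= 0:
            raise ValueError(f"tissue flow override {k!r} must be > 0, got {q}")
        flows[k] = float(q)
    fixed = sum(flows[k] for k in flow_over)
    free_keys = [k for k in _FLOW_KEYS if k not in flow_over]
    free = sum(flows[k] for k in free_keys)
    if free_keys:
        remaining = co - fixed
        if remaining <= 0:
            raise ValueError(
                "overridden flows already meet or exceed cardiac output; "
                "cannot renormalize the remaining flows"
            )
        scale = remaining / free
        for k in free_keys:
            flows[k] *= scale
    elif abs(fixed - co) > 1e-6 * co:
        raise ValueError("all flows overridden but their sum is not cardiac output")
    flows["lung"] = co
    flows["liver_portal"] = flows["spleen"] + flows["gut"]

    volumes["plasma"] = (volumes["arterial_blood"] + volumes["venous_blood"]) * (1 - hct)
    liver_weight = volumes["liver"] * density.get("liver", 1.0)
    if "liver_weight" in overrides:
        liver_weight = float(overrides["liver_weight"])

    phys = PhysiologyParams(
        body_weight=body_weight,
        cardiac_output=co,
        tissue_volumes=volumes,
        tissue_flows=flows,
        gfr=gfr,
        liver_weight=liver_weight,
        hepatocellularity=hep,
        tissue_density=density,
        hematocrit=hct,
    )
    phys.validate()
    return phys


def whole_liver_unbound_clint(
    clint_per_million_cells: float,
    fu_inc: float,
    hepatocellularity: float,
    liver_weight: float,
) -> float:
    """Scale an in vitro hepatocyte intrinsic clearance to the whole liver.

    ``clint_per_million_cells`` is in µL/min/10^6 cells, ``hepatocellularity``
    in 10^6 cells/g liver, ``liver_weight`` in g.  Dividing by the incubation
    unbound fraction ``fu_inc`` converts the apparent in vitro clearance to an
    unbound intrinsic clearance.  Returns mL/min.
    """
    if clint_per_million_cells <= 0 or hepatocellularity <= 0 or liver_weight <= 0:
        raise ValueError("all clearance-scaling arguments must be > 0")
    if not 0 < fu_inc <= 1:
        raise ValueError(f"fu_inc must lie in (0, 1], got {fu_inc}")
    ul_per_min = (clint_per_million_cells / fu_inc) * hepatocellularity * liver_weight
    return ul_per_min / 1000.0
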