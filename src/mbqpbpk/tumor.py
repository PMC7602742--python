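"""Permeability-limited tumor disposition attached to the whole-body model.

The tumor is split into a vascular space (16% of tumor volume by default),
extracellular water and intracellular water.  Blood perfuses the vascular
space at ``q_tumor``; a capillary permeability clearance exchanges unbound
plasma with extracellular water; a passive permeability clearance ``ps``
exchanges extra- and intracellular water bidirectionally; an efflux
transporter pumps intracellular drug back out; and a tumor intrinsic
clearance eliminates drug from the intracellular space.  All clearances are
densities (mL/min per mL tumor).  Tumor water is treated as binding-free, so
unbound equals total in the EC/IC spaces.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .pbpk import PBPKModel

__all__ = ["TumorDispositionParams", "attach_tumor", "tumor_total_concentration"]


@dataclass
class TumorDispositionParams:
    """Tumor geometry, perfusion and transfer clearances."""

    tumor_volume: float = 0.5  # mL
    f_vascular: float = 0.16
    f_extracellular: float = 0.40
    f_intracellular: float = 0.44
    ps: float = 1.2  # EC<->IC passive permeability, mL/min/mL tumor
    cl_efflux: float = 7.0  # IC->EC efflux transporter, mL/min/mL tumor
    cl_tumor: float = 2.2  # IC intrinsic clearance, mL/min/mL tumor
    q_tumor: float = 0.05  # blood flow, mL/min (0.1 mL/min per mL at 0.5 mL)
    ps_capillary: float = 12.0  # vascular<->EC, mL/min/mL tumor (10x ps)

    def __post_init__(self) -> None:
        if self.tumor_volume <= 0:
            raise ValueError("tumor_volume must be > 0")
        fractions = (self.f_vascular, self.f_extracellular, self.f_intracellular)
        if any(f <= 0 for f in fractions):
            raise ValueError("tumor subspace fractions must be > 0")
        if abs(sum(fractions) - 1.0) > 1e-9:
            raise ValueError(
                f"tumor subspace fractions must sum to 1, got {sum(fractions):.6g}"
            )
        for name in ("ps", "cl_efflux", "cl_tumor", "ps_capillary"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.q_tumor < 0:
            raise ValueError("q_tumor must be >= 0")

    # -- ODE coupling -------------------------------------------------------
    def add_to_matrix(self, M: np.ndarray, idx: dict[str, int], model: PBPKModel,
                      min_to_h: float) -> None:
        """Append the three tumor states and their couplings to the system."""
        comp = model.compound
        vol = model.physiology.tissue_volumes
        v_t = self.tumor_volume
        v_vasc = self.f_vascular * v_t
        v_ec = self.f_extracellular * v_t
        v_ic = self.f_intracellular * v_t

        ven, art = idx["venous_blood"], idx["arterial_blood"]
        tv, te, ti = idx["tumor_vascular"], idx["tumor_extracellular"], idx["tumor_intracellular"]
        elim = idx["eliminated_tumor"]

        q = self.q_tumor * min_to_h
        if q > 0:
            # tumor perfusion adds to cardiac output as a small extra branch;
            # the venous -> lung -> arterial transit carries it too, so blood
            # flow is conserved at every node
            v_vb = vol["venous_blood"]
            v_ab = vol["arterial_blood"]
            v_lu = vol["lung"]
            e_lu = comp.bp_ratio / model.kpset.kp["lung"]
            lu = idx["lung"]
            M[ven, ven] -= q / v_vb
            M[lu, ven] += q / v_vb
            M[lu, lu] -= q * e_lu / v_lu
            M[art, lu] += q * e_lu / v_lu
            M[art, art] -= q / v_ab
            M[tv, art] += q / v_ab
            M[tv, tv] -= q / v_vasc
            M[ven, tv] += q / v_vasc

        # capillary exchange: unbound plasma in the vascular space vs EC water
        psc = self.ps_capillary * v_t * min_to_h
        if psc > 0:
            unbound = comp.fu_plasma / comp.bp_ratio  # blood conc -> unbound plasma
            M[tv, tv] -= psc * unbound / v_vasc
            M[te, tv] += psc * unbound / v_vasc
            M[te, te] -= psc / v_ec
            M[tv, te] += psc / v_ec

        ps = self.ps * v_t * min_to_h
        M[te, te] -= ps / v_ec
        M[ti, te] += ps / v_ec
        M[ti, ti] -= ps / v_ic
        M[te, ti] += ps / v_ic

        eff = self.cl_efflux * v_t * min_to_h
        if eff > 0:
            M[ti, ti] -= eff / v_ic
            M[te, ti] += eff / v_ic

        clt = self.cl_tumor * v_t * min_to_h
        if clt > 0:
            M[ti, ti] -= clt / v_ic
            M[elim, ti] += clt / v_ic


def attach_tumor(model: PBPKModel, params: TumorDispositionParams) -> PBPKModel:
    """Return a new model with the tumor subsystem attached.

    Attaching to a model that already carries a tumor is rejected.
    """
    if model.tumor is not None:
        raise ValueError("model already has a tumor attached")
    new = replace(model, tumor=params, _matrix=None, state_names=[])
    new._assemble()
    return new


def tumor_total_concentration(
    amounts: dict[str, np.ndarray], params: TumorDispositionParams
) -> np.ndarray:
    """Total tumor concentration (ng/mL): homogenate of all three subspaces."""
    return (
        np.asarray(amounts["tumor_vascular"])
        + np.asarray(amounts["tumor_extracellular"])
        + np.asarray(amounts["tumor_intracellular"])
    ) / params.tumor_volume
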