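"""Published MBQ-167 model parameterization and study designs.

Everything here is a reported or optimized value for MBQ-167 in the mouse:
physicochemistry and binding, the optimized tissue partition coefficients and
global Kp scalar, elimination inputs (in vitro hepatocyte CLint, observed
systemic plasma clearance, renal clearance), the tumor disposition
clearances, and the Simeoni growth/kill parameter sets for the HER2+
(MDA-MB-435) and Triple Negative (MDA-MB-231) xenograft lines.
"""
from __future__ import annotations

import numpy as np

from .compound import CompoundParams, assemble_final_kpset, predict_kp_method2
from .pbpk import (
    Clearances,
    DoseRegimen,
    PBPKModel,
    build_pbpk_model,
    calibrate_hepatic_pathway,
)
from .physiology import build_mouse_physiology, whole_liver_unbound_clint
from .tgi import TGIParams
from .tumor import TumorDispositionParams, attach_tumor

__all__ = [
    "mbq167_compound",
    "KP_OVERRIDES",
    "KP_SCALAR",
    "HEPATOCYTE_CLINT_UL_MIN_PER_1E6_CELLS",
    "OBSERVED_PLASMA_CL_ML_MIN",
    "RENAL_CL_ML_MIN",
    "PK_SAMPLING_TIMES_H",
    "OBSERVED_EXPOSURE",
    "tgi_her2",
    "tgi_tnbc",
    "tumor_disposition",
    "build_reference_model",
    "single_dose_regimen",
]

#: Optimized tissue:plasma partition coefficients (final values).
KP_OVERRIDES = {"heart": 1.0, "kidney": 13.94, "liver": 14.66, "lung": 1.9, "spleen": 2.1}
#: Global scalar applied to the mechanistically predicted Kp of the remaining tissues.
KP_SCALAR = 0.29

#: In vitro hepatocyte intrinsic clearance, µL/min/10^6 cells.
HEPATOCYTE_CLINT_UL_MIN_PER_1E6_CELLS = 79.0
#: Reported in vivo systemic plasma clearance used to calibrate fu_inc, mL/min.
OBSERVED_PLASMA_CL_ML_MIN = 2.15
#: Renal clearance (glomerular filtration only), mL/min for a 20 g mouse.
RENAL_CL_ML_MIN = 0.3

#: Destructive-sampling times of the tissue-distribution study, h.
PK_SAMPLING_TIMES_H = (0.5, 1.0, 3.0, 6.0, 9.0, 12.0, 24.0)

#: Observed exposure metrics after a single 10 mg/kg IP dose
#: (AUC_0-t in ng·h/mL over 0-12 h for plasma/tissues and 0-24 h for tumor;
#: Cmax in ng/mL).
OBSERVED_EXPOSURE = {
    "plasma": {"auc_0_t": 1417.2, "cmax": 839.9},
    "lung": {"auc_0_t": 1887.6, "cmax": 1540.9},
    "liver": {"auc_0_t": 8388.5, "cmax": 4793.7},
    "spleen": {"auc_0_t": 3983.9, "cmax": 1693.4},
    "kidney": {"auc_0_t": 34279.0, "cmax": 11160.4},
    "heart": {"auc_0_t": 949.2, "cmax": 840.8},
    "tumor": {"auc_0_t": 10286.8, "cmax": 1243.6},
}


def mbq167_compound(fu_inc: float = 0.07) -> CompoundParams:
    """MBQ-167 physicochemistry and binding."""
    return CompoundParams(
        molecular_weight=338.414,
        logp=4.944,
        compound_type="monoprotic_base",
        pka=0.27,
        fu_plasma=0.02,
        bp_ratio=1.8,
        fu_inc=fu_inc,
    )


def tgi_her2() -> TGIParams:
    """Simeoni parameters for the HER2+ xenograft (65-day study)."""
    return TGIParams(
        lambda0=0.2, lambda1=0.12, psi=0.7, w0=0.1, n_transit=3,
        k1=0.39, kmax=0.3683, ic50_um=0.0187, hill=0.5,
    )


def tgi_tnbc() -> TGIParams:
    """Simeoni parameters for the Triple Negative xenograft (108-day study)."""
    return TGIParams(
        lambda0=0.0393, lambda1=0.5457, psi=0.9985, w0=0.0384, n_transit=4,
        k1=0.0007, kmax=0.0533, ic50_um=0.0001, hill=0.5,
    )


def tumor_disposition(tumor_volume: float = 0.5) -> TumorDispositionParams:
    """Permeability-limited tumor block with the optimized clearances."""
    return TumorDispositionParams(
        tumor_volume=tumor_volume,
        f_vascular=0.16,
        f_extracellular=0.40,
        f_intracellular=0.44,
        ps=1.2,
        cl_efflux=7.0,
        cl_tumor=2.2,
        q_tumor=0.1 * tumor_volume,
        ps_capillary=12.0,
    )


def build_reference_model(
    body_weight: float = 20.0,
    with_tumor: bool = False,
    tumor_volume: float = 0.5,
) -> PBPKModel:
    """Fully parameterized MBQ-167 model with calibrated hepatic pathway.

    The incubation unbound fraction is calibrated so that the well-stirred
    hepatic plasma clearance plus the fixed renal clearance reproduces the
    reported systemic plasma clearance (the renal clearance scales with body
    weight through GFR).
    """
    phys = build_mouse_physiology(body_weight)
    renal_cl = phys.gfr
    target_cl = OBSERVED_PLASMA_CL_ML_MIN * (body_weight / 20.0)
    compound = mbq167_compound()
    fu_inc = calibrate_hepatic_pathway(
        phys, compound, HEPATOCYTE_CLINT_UL_MIN_PER_1E6_CELLS, target_cl, renal_cl
    )
    compound = mbq167_compound(fu_inc=fu_inc)
    clint_u = whole_liver_unbound_clint(
        HEPATOCYTE_CLINT_UL_MIN_PER_1E6_CELLS, fu_inc,
        phys.hepatocellularity, phys.liver_weight,
    )
    kpset = assemble_final_kpset(
        predict_kp_method2(compound), overrides=KP_OVERRIDES, scalar=KP_SCALAR
    )
    clearances = Clearances(hepatic_clint_u=clint_u, renal_cl=renal_cl)
    model = build_pbpk_model(phys, compound, kpset, clearances)
    if with_tumor:
        model = attach_tumor(model, tumor_disposition(tumor_volume))
    return model


def single_dose_regimen(
    dose_mg_per_kg: float = 10.0, body_weight: float = 20.0
) -> DoseRegimen:
    """Single IP dose with the optimized absorption kinetics (ka 3/h, lag 0.17 h)."""
    return DoseRegimen(
        dose_amount=dose_mg_per_kg * body_weight / 1000.0,
        dose_times=(0.0,),
        ka=3.0,
        lag_time=0.17,
        fa=1.0,
    )
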