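"""Compound physicochemistry and tissue partitioning.

Tissue:plasma partition coefficients (Kp) are predicted mechanistically from
tissue composition (Rodgers & Rowland "method 2"): the neutral species
partitions into tissue water, neutral lipid and neutral phospholipid, the
ionized species into intracellular water, and any residual plasma protein
binding not explained by plasma lipid partitioning is mapped to the tissue by
its protein ratio.  For MBQ-167 (monoprotic base, pKa 0.27) the ionized
fraction at physiological pH is below 1e-7, so the neutral terms dominate.

Predicted Kp values can be overridden tissue-by-tissue with optimized values
and the remainder scaled by a global Kp scalar; the steady-state volume of
distribution follows from the final set and the tissue volumes.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from importlib import resources

from .physiology import PhysiologyParams

__all__ = [
    "CompoundParams",
    "KpSet",
    "load_tissue_composition",
    "predict_kp_method2",
    "assemble_final_kpset",
    "compute_vss",
    "molar_to_mass_concentration",
]

PLASMA_PH = 7.4


@dataclass
class CompoundParams:
    """Physicochemical and binding parameters of a small molecule."""

    molecular_weight: float  # g/mol
    logp: float  # log10 octanol:water partition coefficient
    compound_type: str = "monoprotic_base"
    pka: float = 0.0
    fu_plasma: float = 1.0
    bp_ratio: float = 1.0
    fu_inc: float = 1.0  # unbound fraction in the in vitro incubation

    def __post_init__(self) -> None:
        if self.molecular_weight <= 0:
            raise ValueError("molecular_weight must be > 0")
        if not 0 < self.fu_plasma <= 1:
            raise ValueError(f"fu_plasma must lie in (0, 1], got {self.fu_plasma}")
        if self.bp_ratio <= 0:
            raise ValueError("bp_ratio must be > 0")
        if self.compound_type not in ("monoprotic_base", "neutral"):
            raise ValueError(f"unsupported compound_type {self.compound_type!r}")

    @property
    def fu_blood(self) -> float:
        """Unbound fraction referenced to whole blood (fu / B:P)."""
        return self.fu_plasma / self.bp_ratio

    def ionized_ratio(self, ph: float) -> float:
        """Henderson-Hasselbalch ionized:neutral ratio at the given pH."""
        if self.compound_type == "neutral":
            return 0.0
        return 10.0 ** (self.pka - ph)

    def ionized_fraction(self, ph: float) -> float:
        x = self.ionized_ratio(ph)
        return x / (1.0 + x)


@dataclass
class KpSet:
    """Final per-tissue partition coefficients with provenance.

    ``provenance`` marks each tissue as ``optimized`` (override taken
    verbatim) or ``predicted_scaled`` (mechanistic prediction times the
    global scalar).
    """

    kp: dict[str, float]
    scalar: float = 1.0
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for t, v in self.kp.items():
            if v <= 0:
                raise ValueError(f"Kp for {t!r} must be > 0, got {v}")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"tissue": t, "kp": v, "provenance": self.provenance.get(t, "predicted_scaled")}
            for t, v in sorted(self.kp.items())
        ]
        return pd.DataFrame(rows)


def load_tissue_composition() -> pd.DataFrame:
    """Pinned tissue composition table (fractional water, lipid, protein)."""
    with resources.files("mbqpbpk.data").joinpath("tissue_composition.csv").open() as fh:
        return pd.read_csv(fh).set_index("tissue")


def _neutral_lipid_affinity(compound: CompoundParams, tissue: str) -> float:
    """Partition coefficient of the neutral species into neutral lipid.

    Adipose neutral lipid behaves like vegetable oil rather than octanol;
    the standard regression log D_vo = 1.115 logP - 1.35 is used there.
    """
    if tissue == "adipose":
        return 10.0 ** (1.115 * compound.logp - 1.35)
    return 10.0 ** compound.logp


def predict_kp_method2(
    compound: CompoundParams, tissue_composition: pd.DataFrame | None = None
) -> dict[str, float]:
    """Predict tissue:plasma partition coefficients from tissue composition.

    Returns total tissue:total plasma Kp for every tissue row of the
    composition table (the plasma row parameterizes the residual protein
    binding term).  The residual binding term is clamped at zero when plasma
    lipid partitioning alone over-explains the measured plasma binding.
    """
    comp = tissue_composition if tissue_composition is not None else load_tissue_composition()
    if "plasma" not in comp.index:
        raise ValueError("tissue composition table must include a 'plasma' row")
    plasma = comp.loc["plasma"]

    x_p = compound.ionized_ratio(PLASMA_PH)
    p_oct = 10.0 ** compound.logp
    # Residual plasma protein association (per unit plasma protein), from the
    # measured fu after subtracting plasma neutral-lipid partitioning.
    lipid_plasma = (p_oct * plasma["f_nl"] + (0.3 * p_oct + 0.7) * plasma["f_npl"]) / (1.0 + x_p)
    ka_pr = max((1.0 / compound.fu_plasma - 1.0 - lipid_plasma), 0.0)

    kp: dict[str, float] = {}
    for tissue, row in comp.iterrows():
        if tissue == "plasma":
            continue
        x_iw = compound.ionized_ratio(row["ph_iw"])
        p_t = _neutral_lipid_affinity(compound, str(tissue))
        kpu = (
            row["f_ew"]
            + row["f_iw"] * (1.0 + x_iw) / (1.0 + x_p)
            + (p_t * row["f_nl"] + (0.3 * p_t + 0.7) * row["f_npl"]) / (1.0 + x_p)
            + ka_pr * row["protein_ratio"]
        )
        kp[str(tissue)] = kpu * compound.fu_plasma
    return kp


def assemble_final_kpset(
    predicted: dict[str, float],
    overrides: dict[str, float] | None = None,
    scalar: float = 1.0,
) -> KpSet:
    """Combine predicted and optimized Kp values into the final set.

    Overridden tissues take the optimized value verbatim; all remaining
    tissues take ``predicted × scalar``.
    """
    overrides = dict(overrides or {})
    unknown = set(overrides) - set(predicted)
    if unknown:
        raise ValueError(f"override(s) for unknown tissue(s): {sorted(unknown)}")
    for t, v in overrides.items():
        if v <= 0:
            raise ValueError(f"Kp override for {t!r} must be > 0, got {v}")
    if scalar <= 0:
        raise ValueError("Kp scalar must be > 0")
    kp: dict[str, float] = {}
    prov: dict[str, str] = {}
    for t, v in predicted.items():
        if t in overrides:
            kp[t] = float(overrides[t])
            prov[t] = "optimized"
        else:
            kp[t] = float(v) * scalar
            prov[t] = "predicted_scaled"
    return KpSet(kp=kp, scalar=scalar, provenance=prov)


def compute_vss(kpset: KpSet, phys: PhysiologyParams, compound: CompoundParams) -> float:
    """Steady-state volume of distribution, plasma-referenced, in L/kg.

    Vss = [V_plasma + V_ery * E:P + sum_t Kp_t * V_t] / BW, with the
    erythrocyte:plasma ratio derived from the blood:plasma ratio and
    hematocrit: E:P = (B/P - (1 - Hct)) / Hct.
    """
    hct = phys.hematocrit
    v_plasma = phys.tissue_volumes.get("plasma", phys.blood_volume * (1 - hct))
    v_ery = phys.blood_volume * hct
    ep = (compound.bp_ratio - (1.0 - hct)) / hct
    ep = max(ep, 0.0)
    total = v_plasma + v_ery * ep
    for tissue, volume in phys.tissue_volumes.items():
        if tissue in ("plasma", "arterial_blood", "venous_blood"):
            continue
        if tissue not in kpset.kp:
            raise ValueError(f"KpSet is missing tissue {tissue!r} required for Vss")
        total += kpset.kp[tissue] * volume
    return total / phys.body_weight  # mL/g == L/kg


def molar_to_mass_concentration(value_um: float, molecular_weight: float) -> float:
    """Convert µM to ng/mL (µM × g/mol = ng/mL)."""
    if value_um < 0:
        raise ValueError(f"concentration must be >= 0, got {value_um}")
    return value_um * molecular_weight
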