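"""Independent re-derivations used as test oracles.

Deliberately written as plain scalar arithmetic, separate from the package's
vectorized implementations.
"""
from __future__ import annotations

import math


def kp_tissue_oracle(
    logp: float,
    pka: float,
    fu_plasma: float,
    row: dict,
    plasma_row: dict,
    is_adipose: bool,
    compound_type: str = "monoprotic_base",
) -> float:
    """Tissue:plasma partition coefficient from composition, step by step."""
    ph_p = 7.4
    if compound_type == "monoprotic_base":
        x_p = 10.0 ** (pka - ph_p)
        x_iw = 10.0 ** (pka - row["ph_iw"])
    else:
        x_p = x_iw = 0.0

    if is_adipose:
        p = 10.0 ** (1.115 * logp - 1.35)
    else:
        p = 10.0 ** logp
    p_plasma = 10.0 ** logp

    lipid_plasma = (
        p_plasma * plasma_row["f_nl"] + (0.3 * p_plasma + 0.7) * plasma_row["f_npl"]
    ) / (1.0 + x_p)
    ka_pr = (1.0 / fu_plasma) - 1.0 - lipid_plasma
    if ka_pr < 0.0:
        ka_pr = 0.0

    kpu = row["f_ew"]
    kpu += row["f_iw"] * (1.0 + x_iw) / (1.0 + x_p)
    kpu += (p * row["f_nl"] + (0.3 * p + 0.7) * row["f_npl"]) / (1.0 + x_p)
    kpu += ka_pr * row["protein_ratio"]
    return kpu * fu_plasma


def one_compartment_oral(t: float, dose: float, v: float, ka: float, ke: float,
                         lag: float) -> float:
    """Closed-form first-order-absorption one-compartment concentration."""
    if t <= lag:
        return 0.0
    tt = t - lag
    return dose * ka / (v * (ka - ke)) * (math.exp(-ke * tt) - math.exp(-ka * tt))
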