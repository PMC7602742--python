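# Methods

## Whole-body PBPK model

The model is a linear, perfusion-limited whole-body system written in drug
amounts (ng) with time in hours. Compartments: an absorption depot, venous
and arterial blood, lung, and eleven systemic tissues (heart, kidney,
liver, spleen, gut, muscle, adipose, skin, bone, brain, rest-of-body), plus
cumulative eliminated-amount accumulators per route so that mass balance is
checkable at every output time (the suite asserts |residual|/dose < 1e-6).

Intraperitoneal dosing is represented exactly as the original modeling
workaround: a first-order depot (ka, default 3 h⁻¹) that empties directly
into venous blood with complete bioavailability and a 0.17 h lag,
deliberately bypassing gut and liver first pass. Dosing is event-driven:
integration restarts at every `dose_time + lag` with `fa·dose` added to the
depot, so multiple-dose profiles are exact state discontinuities rather
than stiff forcing terms. Because the system is linear, the right-hand side
is assembled once as a constant matrix and integrated with a stiff solver
(BDF, rtol 1e-8 / atol 1e-10 by default, analytic constant Jacobian).
Superposition and strict dose linearity are asserted in the suite.

Blood-side concentrations leave each tissue at C_t·(B/P)/Kp_t; plasma
concentration is venous blood / (B/P). Spleen and gut drain into the liver
portal inflow; the liver's elimination term CLint_u·fu_b·C_out,blood makes
its steady-state clearance identical to the closed-form well-stirred model.
Renal elimination is glomerular filtration of arterial plasma (CL_R ×
C_arterial,plasma). It is *debited at the kidney compartment*, which keeps
arterial and venous AUCs equal, so the simulated systemic clearance
(dose/AUC∞) equals the closed-form hepatic + renal sum exactly; debiting
the arterial pool itself would lower it by CL_R/(B/P·CO) ≈ 2%. A
venous-side variant is available through `Clearances(renal_site="venous")`.

### Physiology

The mouse system data (fractional tissue volumes and flows, cardiac output
0.4 mL/min/g, GFR 0.015 mL/min/g, hematocrit 0.45, hepatocellularity
135×10⁶ cells/g liver, liver density 1.05 g/mL) are pinned in
`data/physiology_mouse.json` from the standard rodent compilations (Brown
et al. 1997 fractions; Davies & Morris 1993 cardiac output and blood
volume). Volumes scale linearly with body weight and flows with cardiac
output. Any entry can be overridden; after overrides the non-overridden
systemic flows are renormalized so they still sum to cardiac output, and
the portal inflow is rebuilt as spleen + gut outflow. For the reference
20 g mouse the GFR gives the renal clearance 0.3 mL/min used throughout.

### Partition coefficients

Tissue:plasma Kp values are predicted with the Rodgers–Rowland
tissue-composition method: the neutral species partitions into tissue
water, neutral lipid (P_octanol:water; the vegetable-oil regression
log D = 1.115·logP − 1.35 for adipose) and neutral phospholipid
(0.3P + 0.7), ionization follows Henderson–Hasselbalch at plasma pH 7.4
and intracellular pH 7.0, and residual plasma-protein binding (what the
measured fu cannot be explained by plasma lipid) is carried to tissues by
their protein ratios, clamped at zero when plasma lipid partitioning
already over-explains fu — which is the case for MBQ-167 (logP 4.944,
fu 0.02). For a monoprotic base with pKa 0.27 the ionized fraction at
pH 7.4 is ~7×10⁻⁸, so the compound is effectively neutral. The
composition table is pinned from the published rat data (the standard
surrogate when no mouse table exists); rest-of-body uses muscle
composition, since carcass is muscle-dominated. An independently coded
scalar oracle reproduces the vectorized implementation to 1e-10 on random
compounds.

The final Kp set takes the five optimized values (heart 1, kidney 13.94,
liver 14.66, lung 1.9, spleen 2.1) verbatim and multiplies the remaining
predictions by the global scalar 0.29. Whether the scalar should also
shrink the optimized values is ambiguous; applying it only to predicted
tissues keeps the optimized values as the final ones listed and gives
Vss = 17.45 L/kg for the 20 g mouse (plasma-referenced:
[V_plasma + V_ery·E:P + Σ Kp_t·V_t]/BW with E:P = (B/P − (1 − Hct))/Hct),
about 14% below the previously reported 20.21 L/kg — the residual
difference traces to the unpublished simulator-internal composition and
physiology tables.

### Hepatic pathway calibration

The in vitro hepatocyte intrinsic clearance (79 µL/min/10⁶ cells — the
unit is read as µL, since 79 mL/min/10⁶ cells would exceed cardiac output
by orders of magnitude) is scaled by hepatocellularity and liver weight
and divided by the incubation unbound fraction fu_inc. fu_inc is then
calibrated by a bracketed root search so that well-stirred hepatic plasma
clearance plus the fixed renal clearance reproduces the observed systemic
clearance 2.15 mL/min. With this package's physiology the calibration
yields fu_inc = 0.033 (the originally reported 0.07 reflects a different
liver blood flow); the resulting clearance partition — hepatic
1.85 mL/min, renal 0.3 mL/min, hepatic share 86% — is what the model
actually uses, and the unit ambiguity above is entirely absorbed by this
calibration.

## Tumor disposition

Three sub-spaces of a fixed tumor volume (default 0.5 mL): vascular (16%),
extracellular water (40%) and intracellular water (44%). Tumor blood flow
(default 0.1 mL/min per mL tumor — tumor perfusion is not published, so
tumor PK is verified by properties, not numbers) is carried through the
venous→lung→arterial loop so blood flow is conserved at every node. A
capillary permeability clearance (default 10× PS, non-limiting) exchanges
*unbound* plasma with extracellular water; PS = 1.2 mL/min/mL exchanges
EC↔IC water; the efflux transporter (7 mL/min/mL) moves IC→EC; the tumor
intrinsic clearance (2.2 mL/min/mL) eliminates from IC. Tumor water is
binding-free (unbound = total), a documented simplification; consequently
the steady-state IC:EC ratio is PS/(PS + CL_efflux) = 0.146, asserted in
the suite, and total tumor concentrations are much lower than plasma with
a later peak — the qualitative behavior the tissue data show. Tumor PK is
not coupled to tumor growth because the PD model is driven by plasma.

## Tumor growth inhibition

The Simeoni system generalized to n transit stages:

    dx1/dt = G(w)·x1 − k(C)·x1
    dx2/dt = k(C)·x1 − k1·x2
    dxi/dt = k1·(x_{i−1} − x_i),  i = 3…n+1,   w = Σ x_i

with G(w) = λ₀/[1 + (λ₀w/λ₁)^Ψ]^(1/Ψ) acting on the proliferating pool
with total-mass feedback (damaged cells shade the proliferating ones), and
only the last stage leaving the tumor. The kill term is sigmoid Emax on
total plasma concentration with Hill coefficient 0.5 applied symmetrically
to C and IC₅₀; IC₅₀ is stored in µM and converted to ng/mL with the
molecular weight 338.414 g/mol (µM × g/mol = ng/mL), so the net-effect
ratio K_max/IC₅₀ is reported in 1/(µM·day): 19.7 for HER2+
(0.3683/0.0187) and 533 for Triple Negative (0.0533/0.0001). Parameter
sets: HER2+ λ₀ 0.2 d⁻¹, λ₁ 0.12 g/d, Ψ 0.7, w₀ 0.1 g, 3 stages,
k₁ 0.39 d⁻¹; TNBC λ₀ 0.0393, λ₁ 0.5457, Ψ 0.9985, w₀ 0.0384, 4 stages,
k₁ 0.0007. The TNBC k₁ implies damaged cells essentially never clear —
near-permanent growth arrest rather than cell loss — and is used as
reported. Tumor density 1 g/mL interconverts weight and volume.

Integration uses LSODA with a 0.05-day step cap whenever a drug profile is
present, so no 48-h dosing peak can be stepped over; the plasma driver is
a densely sampled (0.05 h) multiple-dose PBPK profile, linearly
interpolated and held at zero outside its support. The "three times a
week" schedule is encoded as days {0, 2, 4} of every 7-day cycle.

## Estimation and sensitivity

The objective is weighted least squares with each dataset weighted by
1/max(obs)², summed across datasets, minimized by Nelder–Mead (standard
reflection/expansion/contraction coefficients) with log transforms where
requested and infinite objective outside bounds. The published termination
rule — stop when the objective improves by less than 1% — is implemented
over a 10-iteration window so isolated non-improving simplex updates
(contractions/shrinks) do not end the search; `termination_rtol = 0`
disables the rule and runs to the solver's native tolerances, which the
parameter-recovery tests use. Local sensitivity is a central finite
difference at ±20% by default, reported as normalized coefficients
(Δm/m)/(Δp/p); a failed perturbed simulation flags the row rather than
aborting the table.

A caveat the test suite documents deliberately: with the 1/max² weighting,
weekly vehicle tumor data weight the late linear-phase points ~10⁴-fold
more than the early exponential-phase points, so the joint (λ₀, λ₁, Ψ) fit
is practically unidentifiable at realistic (15%) noise — full-convergence
fits reach better-than-truth objective values at 40–60% parameter error.
Fixing Ψ (common practice for this model) recovers λ₀ to ~5% and λ₁ to
~10% median. The zero-noise joint fit recovers all three to <1%.

## Synthetic data

`synthetic` emulates the two study designs: (a) destructive-sampling PK —
5 mice per time point at 0.5, 1, 3, 6, 9, 12, 24 h, each record an
independent pseudo-animal (no within-animal correlation, matching
sacrifice-based sampling); (b) longitudinal tumor growth — 4 groups
(vehicle, 1, 5, 10 mg/kg three-times-weekly), 10 subjects per group,
weekly observations over 65 or 108 days. Residuals are proportional
lognormal by default (σ² = ln(1 + cv²), so the empirical CV equals the
design CV; positivity is automatic); additive and combined models exist.
Subjects in the growth study share a multiplicative baseline jitter
(default CV 10%) applied to the whole trajectory — exact in the
exponential phase, an approximation later. The noise-free truth is stored
with every record, and all generators are deterministic given their seed.
What the generator does not emulate: fluorescence-imaging measurement
physics, inter-animal physiological variability, or dropout — so passing
recovery tests demonstrate estimator correctness under the stated error
model, not robustness to real-data pathologies.

## Numerical choices and limitations

- PBPK defaults rtol 1e-8/atol 1e-10 (BDF); long multiple-dose drivers for
  the PD model use rtol 1e-6 on a 0.05 h grid, which changes the computed
  tumor endpoints by <0.1%.
- Tmax ties resolve to first attainment; AUC is linear trapezoid with no
  extrapolation (all predicted/observed comparisons share a time window);
  observed-mean confidence intervals use Student t.
- Tiny integrator negatives (|x| < 1e-6 ng) are clamped; genuine negative
  states would surface in the mass-balance assertions.
- Problem sizes: acceptance computations use a 0.005 h grid for the 24 h
  single-dose profile and 0.05 h grids for the 65/108-day regimens —
  roughly 5k–52k output points per simulation, each completing in seconds.
- No enterohepatic recirculation, metabolite kinetics, transporter
  saturation, spatial tumor gradients, resistance dynamics, or population
  variability; "fed state" is metadata only. The tumor-concentration-driven
  PD mode exists as a flag (`drug_input="tumor_total"`) but is untested
  against reported endpoints.
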