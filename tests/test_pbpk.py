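import numpy as np
import pytest

from _oracles import one_compartment_oral
from mbqpbpk import presets
from mbqpbpk.compound import CompoundParams, KpSet
from mbqpbpk.metrics import auc_trapezoid, cmax_tmax
from mbqpbpk.pbpk import (
    Clearances,
    DoseRegimen,
    build_pbpk_model,
    calibrate_hepatic_pathway,
    hepatic_clearance_well_stirred,
    simulate,
)
from mbqpbpk.physiology import PhysiologyParams, build_mouse_physiology


class TestWellStirred:
    def test_flow_limited_ceiling(self):
        q = 1.5
        cl = hepatic_clearance_well_stirred(q, 0.01, 1e9, 1.0)
        assert cl == pytest.approx(q, rel=1e-6)

    def test_restrictive_limit(self):
        q, fu_b, clint = 100.0, 0.01, 10.0
        cl = hepatic_clearance_well_stirred(q, fu_b, clint, 1.0)
        assert cl == pytest.approx(fu_b * clint, rel=0.01)

    def test_hand_evaluation(self):
        cl = hepatic_clearance_well_stirred(1.8, 0.0111, 152.36, 1.8)
        assert cl == pytest.approx(1.57, rel=0.01)


class TestCalibrateHepaticPathway:
    def test_fixed_point(self):
        phys = build_mouse_physiology(20.0)
        comp = presets.mbq167_compound()
        from mbqpbpk.physiology import whole_liver_unbound_clint

        clint = whole_liver_unbound_clint(79.0, 0.07, phys.hepatocellularity,
                                          phys.liver_weight)
        hep = hepatic_clearance_well_stirred(
            phys.liver_total_inflow(), comp.fu_blood, clint, comp.bp_ratio
        )
        fu_inc = calibrate_hepatic_pathway(phys, comp, 79.0, hep + 0.3, 0.3)
        assert fu_inc == pytest.approx(0.07, rel=1e-6)

    def test_reported_clearance_partition(self, ref_model):
        # calibrated against the observed total 2.15 with fixed renal 0.3:
        # hepatic lands at 1.85 mL/min
        assert ref_model.hepatic_plasma_clearance() == pytest.approx(1.85, rel=1e-4)
        assert ref_model.total_plasma_clearance() == pytest.approx(2.15, rel=1e-4)

    def test_unreachable_target_rejected(self):
        phys = build_mouse_physiology(20.0)
        comp = presets.mbq167_compound()
        ceiling = phys.liver_total_inflow() * comp.bp_ratio
        with pytest.raises(ValueError, match="ceiling"):
            calibrate_hepatic_pathway(phys, comp, 79.0, ceiling + 0.3 + 1.0, 0.3)


class TestSimulate:
    def test_mass_balance_zero_clearance(self, ref_model):
        model = build_pbpk_model(
            ref_model.physiology, ref_model.compound, ref_model.kpset,
            Clearances(hepatic_clint_u=0.0, renal_cl=0.0),
        )
        reg = presets.single_dose_regimen()
        res = simulate(model, reg, t_grid=np.linspace(0, 48, 200))
        total = sum(
            res.amounts[n][-1]
            for n in model.state_names
            if not n.startswith("eliminated")
        )
        assert total == pytest.approx(res.dose_total, rel=1e-9)
        assert res.amounts["eliminated_hepatic"][-1] == 0.0

    def test_mass_balance_with_elimination(self, single_dose_sim):
        rel = np.abs(single_dose_sim.mass_balance_residual) / single_dose_sim.dose_total
        assert np.max(rel) < 1e-6

    def test_no_absorption_before_lag(self, single_dose_sim):
        t = single_dose_sim.time
        cp = single_dose_sim.concentrations["plasma"]
        assert np.all(cp[t < 0.17] == 0.0)
        _, tmax = cmax_tmax(t, cp)
        assert tmax >= 0.17

    def test_dose_linearity(self, ref_model, single_dose_sim, dense_grid):
        reg = presets.single_dose_regimen(20.0)  # doubled dose
        res = simulate(ref_model, reg, t_grid=dense_grid)
        ref = single_dose_sim.concentrations["plasma"]
        mask = ref > 1e-3
        ratio = res.concentrations["plasma"][mask] / ref[mask]
        assert np.allclose(ratio, 2.0, rtol=1e-6)

    def test_superposition_of_shifted_single_doses(self, ref_model):
        grid = np.arange(0.0, 36.0005, 0.01)
        multi = simulate(
            ref_model,
            DoseRegimen(dose_amount=0.2, dose_times=(0.0, 6.0, 12.0)),
            t_grid=grid,
        )
        single = simulate(
            ref_model, DoseRegimen(dose_amount=0.2, dose_times=(0.0,)), t_grid=grid
        )
        cp = single.concentrations["plasma"]
        summed = np.zeros_like(cp)
        for shift in (0.0, 6.0, 12.0):
            summed += np.interp(grid - shift, grid, cp, left=0.0)
        target = multi.concentrations["plasma"]
        mask = target > 1e-3
        assert np.allclose(summed[mask], target[mask], rtol=1e-4)

    def test_simulated_clearance_matches_closed_form(self, ref_model):
        # dose / AUC_0-inf from a long simulation against hepatic + renal
        grid = np.arange(0.0, 96.001, 0.01)
        res = simulate(ref_model, presets.single_dose_regimen(), t_grid=grid)
        cp = res.concentrations["plasma"]
        auc = auc_trapezoid(grid, cp)
        lam = -np.polyfit(grid[-500:], np.log(cp[-500:]), 1)[0]
        auc_inf = auc + cp[-1] / lam
        cl_sim = res.dose_total / auc_inf / 60.0  # ng/(ng·h/mL)/60 -> mL/min
        assert cl_sim == pytest.approx(ref_model.total_plasma_clearance(), rel=0.02)

    def test_missing_kp_rejected(self, ref_model):
        kp = dict(ref_model.kpset.kp)
        kp.pop("muscle")
        with pytest.raises(ValueError, match="muscle"):
            build_pbpk_model(
                ref_model.physiology, ref_model.compound, KpSet(kp=kp),
                ref_model.clearances,
            )

    def test_tissue_equilibrium_ratios_approach_kp(self, ref_model):
        # with zero clearance, tissue:plasma ratios drift to Kp at late times
        model = build_pbpk_model(
            ref_model.physiology, ref_model.compound, ref_model.kpset,
            Clearances(0.0, 0.0),
        )
        grid = np.linspace(0.0, 400.0, 400)
        res = simulate(model, presets.single_dose_regimen(), t_grid=grid)
        cp = res.concentrations["plasma"][-1]
        for tissue in ("heart", "kidney", "muscle", "adipose"):
            ratio = res.concentrations[tissue][-1] / cp
            assert ratio == pytest.approx(ref_model.kpset.kp[tissue], rel=1e-3)


class TestOneCompartmentDegenerate:
    def test_matches_closed_form(self):
        # a single fast-perfused tissue at Kp 1 collapses to one compartment
        volumes = {
            "arterial_blood": 0.5, "venous_blood": 0.5, "lung": 0.1,
            "kidney": 10.0, "plasma": 1.0,
        }
        q = 1.0e7  # effectively instantaneous equilibration
        phys = PhysiologyParams(
            body_weight=20.0, cardiac_output=q, tissue_volumes=volumes,
            tissue_flows={"kidney": q, "lung": q}, gfr=0.1, liver_weight=1.0,
            hepatocellularity=135.0, tissue_density={"default": 1.0},
            hematocrit=0.45,
        )
        comp = CompoundParams(molecular_weight=300.0, logp=0.0,
                              compound_type="neutral", fu_plasma=1.0, bp_ratio=1.0)
        clr = 0.1  # mL/min
        model = build_pbpk_model(
            phys, comp, KpSet(kp={"kidney": 1.0, "lung": 1.0}),
            Clearances(hepatic_clint_u=0.0, renal_cl=clr),
        )
        reg = DoseRegimen(dose_amount=0.2, dose_times=(0.0,), ka=3.0, lag_time=0.17)
        grid = np.linspace(0.0, 12.0, 121)
        res = simulate(model, reg, t_grid=grid, rtol=1e-10, atol=1e-12)
        v_total = sum(v for k, v in volumes.items() if k != "plasma")
        ke = clr * 60.0 / v_total  # 1/h
        expected = np.array([
            one_compartment_oral(t, 0.2e6, v_total, 3.0, ke, 0.17) for t in grid
        ])
        mask = expected > 1e-6 * expected.max()
        assert np.allclose(res.concentrations["plasma"][mask], expected[mask],
                           rtol=1e-6)


def test_regimen_validation():
    with pytest.raises(ValueError):
        DoseRegimen(dose_amount=0.0)
    with pytest.raises(ValueError):
        DoseRegimen(dose_amount=0.2, dose_times=(3.0, 1.0))
    with pytest.raises(ValueError):
        DoseRegimen(dose_amount=0.2, fa=1.5)
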