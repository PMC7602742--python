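import numpy as np
import pytest

from mbqpbpk import presets
from mbqpbpk.estimation import (
    Dataset,
    FitSpec,
    FreeParameter,
    fit,
    local_sensitivity,
    wls_objective,
)
from mbqpbpk.pbpk import DoseRegimen, simulate
from mbqpbpk.tgi import TGIParams, simulate_tgi


class TestWlsObjective:
    def test_perfect_fit_is_zero(self):
        ds = [Dataset("y", [1.0, 2.0], [10.0, 5.0])]
        assert wls_objective({"y": np.array([10.0, 5.0])}, ds) == 0.0

    def test_hand_arithmetic(self):
        ds = [Dataset("y", [1.0, 2.0], [10.0, 5.0])]
        assert wls_objective({"y": np.array([10.0, 0.0])}, ds) == pytest.approx(0.25)

    def test_invariant_under_dataset_rescaling(self):
        obs = np.array([3.0, 8.0, 2.0])
        pred = np.array([2.5, 8.5, 2.5])
        a = wls_objective({"y": pred}, [Dataset("y", [1, 2, 3], obs)])
        b = wls_objective({"y": 10 * pred}, [Dataset("y", [1, 2, 3], 10 * obs)])
        assert a == pytest.approx(b, rel=1e-12)

    def test_empty_datasets_rejected(self):
        with pytest.raises(ValueError):
            wls_objective({}, [])


class TestFit:
    def test_recovers_tgi_growth_parameters_zero_noise(self):
        truth = presets.tgi_her2()
        t = np.arange(0.0, 64.0, 7.0)
        curve = simulate_tgi(truth, None, 63.0, t_eval=t).volume

        def predict(p):
            params = TGIParams(**{**truth.__dict__, "lambda0": p["lambda0"],
                                  "lambda1": p["lambda1"], "psi": p["psi"]})
            return {"tumor": simulate_tgi(params, None, 63.0, t_eval=t).volume}

        spec = FitSpec(
            free_parameters=[
                FreeParameter("lambda0", 0.3, 0.01, 2.0, transform="log"),
                FreeParameter("lambda1", 0.3, 0.01, 5.0, transform="log"),
                FreeParameter("psi", 1.5, 0.1, 10.0, transform="log"),
            ],
            datasets=[Dataset("tumor", t, curve)],
            termination_rtol=0.0, max_iter=600,
        )
        res = fit(spec, predict)
        assert res.estimates["lambda0"] == pytest.approx(truth.lambda0, rel=0.01)
        assert res.estimates["lambda1"] == pytest.approx(truth.lambda1, rel=0.01)
        assert res.estimates["psi"] == pytest.approx(truth.psi, rel=0.01)

    def test_zero_objective_returns_initial_point(self):
        ds = [Dataset("y", [1.0], [2.0])]

        def predict(p):
            return {"y": np.array([2.0])}

        spec = FitSpec(
            free_parameters=[FreeParameter("a", 1.0, 0.0, 10.0)], datasets=ds
        )
        res = fit(spec, predict)
        assert res.estimates["a"] == 1.0
        assert res.ofv == 0.0

    def test_bounds_respected(self):
        ds = [Dataset("y", [1.0], [5.0])]

        def predict(p):
            return {"y": np.array([p["a"]])}

        spec = FitSpec(
            free_parameters=[FreeParameter("a", 1.0, 0.5, 2.0)], datasets=ds,
            termination_rtol=0.0, max_iter=200,
        )
        res = fit(spec, predict)  # optimum (5.0) lies outside the bounds
        assert 0.5 <= res.estimates["a"] <= 2.0
        assert res.estimates["a"] == pytest.approx(2.0, rel=1e-3)

    def test_nonfinite_initial_rejected(self):
        ds = [Dataset("y", [1.0], [5.0])]

        def predict(p):
            return {"y": np.array([np.nan])}

        spec = FitSpec(free_parameters=[FreeParameter("a", 1.0)], datasets=ds)
        with pytest.raises(ValueError, match="non-finite"):
            fit(spec, predict)


def _absorption_predict(ref_model, times):
    def predict(p):
        reg = DoseRegimen(dose_amount=0.2, dose_times=(0.0,), ka=p["ka"],
                          lag_time=p["lag"])
        grid = np.unique(np.concatenate([[0.0], times]))
        sim = simulate(ref_model, reg, t_grid=grid, rtol=1e-6, atol=1e-8)
        return {"plasma": np.interp(times, grid, sim.concentrations["plasma"])}

    return predict


class TestAbsorptionRecovery:
    TIMES = np.array([0.25, 0.5, 0.75, 1.0, 2.0, 3.0, 6.0, 9.0, 12.0])

    def test_zero_noise_recovery_within_one_percent(self, ref_model):
        predict = _absorption_predict(ref_model, self.TIMES)
        truth = predict({"ka": 3.0, "lag": 0.17})["plasma"]
        spec = FitSpec(
            free_parameters=[
                FreeParameter("ka", 1.5, 0.1, 30.0, transform="log"),
                FreeParameter("lag", 0.05, 0.0, 1.0),
            ],
            datasets=[Dataset("plasma", self.TIMES, truth)],
            termination_rtol=0.0, max_iter=250,
        )
        res = fit(spec, predict)
        assert res.estimates["ka"] == pytest.approx(3.0, rel=0.01)
        assert res.estimates["lag"] == pytest.approx(0.17, rel=0.01)

    def test_noisy_recovery_median_within_25_percent(self, ref_model):
        # 15% proportional noise on the mean of 5 replicates per time point
        predict = _absorption_predict(ref_model, self.TIMES)
        truth = predict({"ka": 3.0, "lag": 0.17})["plasma"]
        sigma = np.sqrt(np.log1p(0.15**2))
        errors = {"ka": [], "lag": []}
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            reps = truth[:, None] * np.exp(
                sigma * rng.standard_normal((len(truth), 5))
            )
            obs = reps.mean(axis=1)
            spec = FitSpec(
                free_parameters=[
                    FreeParameter("ka", 1.5, 0.1, 30.0, transform="log"),
                    FreeParameter("lag", 0.05, 0.0, 1.0),
                ],
                datasets=[Dataset("plasma", self.TIMES, obs)],
                termination_rtol=1e-4, max_iter=120,
            )
            res = fit(spec, predict)
            errors["ka"].append(abs(res.estimates["ka"] - 3.0) / 3.0)
            errors["lag"].append(abs(res.estimates["lag"] - 0.17) / 0.17)
        assert np.median(errors["ka"]) < 0.25
        assert np.median(errors["lag"]) < 0.25


class TestLocalSensitivity:
    def test_proportional_parameter_has_unit_coefficient(self):
        def evaluate(p):
            return {"auc": p["fa"] * 100.0, "cmax": p["fa"] * 10.0}

        table = local_sensitivity(evaluate, {"fa": 1.0}, perturbation=0.2)
        assert np.allclose(table["coefficient"], 1.0)

    def test_decoupled_parameter_has_zero_coefficient(self):
        def evaluate(p):
            return {"auc": 100.0 + 0.0 * p["ps"]}

        table = local_sensitivity(evaluate, {"ps": 1.2}, perturbation=0.2)
        assert table["coefficient"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_failure_flags_row_not_fatal(self):
        def evaluate(p):
            if p.get("bad", 0) != 0.5:
                raise RuntimeError("boom")
            return {"auc": 1.0}

        table = local_sensitivity(evaluate, {"bad": 0.5}, perturbation=0.2)
        assert not table["ok"].iloc[0]
        assert np.isnan(table["coefficient"].iloc[0])

    def test_invalid_perturbation_rejected(self):
        with pytest.raises(ValueError):
            local_sensitivity(lambda p: {"m": 1.0}, {"a": 1.0}, perturbation=0.9)


class TestPBPKSensitivity:
    def test_renal_clearance_lowers_plasma_auc(self):
        from mbqpbpk.workflows import pbpk_local_sensitivity

        table = pbpk_local_sensitivity(parameters=("renal_cl", "fa", "ps"),
                                       perturbation=0.2, t_end=12.0)
        by_param = table.set_index(["parameter", "metric"])["coefficient"]
        assert by_param[("renal_cl", "auc_0_t")] < 0
        # linear model: fractional AUC change tracks fractional fa change
        assert by_param[("fa", "auc_0_t")] == pytest.approx(1.0, rel=1e-3)
        # tumor permeability has no visible effect on plasma at this tumor burden
        assert abs(by_param[("ps", "auc_0_t")]) < 1e-3
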