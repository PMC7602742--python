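import numpy as np
import pytest

from mbqpbpk import presets
from mbqpbpk.pbpk import simulate
from mbqpbpk.regimen import RegimenSpec, expand_regimen


@pytest.fixture(scope="session")
def ref_model():
    """Calibrated MBQ-167 whole-body model for a 20 g mouse."""
    return presets.build_reference_model()


@pytest.fixture(scope="session")
def tumor_model():
    return presets.build_reference_model(with_tumor=True)


@pytest.fixture(scope="session")
def dense_grid():
    return np.arange(0.0, 24.0 + 0.0025, 0.005)


@pytest.fixture(scope="session")
def single_dose_sim(ref_model, dense_grid):
    """Dense 24 h profile after a single 10 mg/kg IP dose."""
    return simulate(ref_model, presets.single_dose_regimen(), t_grid=dense_grid)


@pytest.fixture(scope="session")
def single_dose_tumor_sim(tumor_model, dense_grid):
    return simulate(tumor_model, presets.single_dose_regimen(), t_grid=dense_grid)


@pytest.fixture(scope="session")
def plasma_profile_factory(ref_model):
    """Multi-dose plasma profiles for TGI coupling, cached per scenario."""
    cache = {}

    def make(dose_mg_per_kg: float, schedule: str, duration_days: float):
        key = (dose_mg_per_kg, schedule, duration_days)
        if key not in cache:
            spec = RegimenSpec(dose_mg_per_kg=dose_mg_per_kg, schedule=schedule,
                               duration=duration_days, body_weight=20.0)
            t_h = np.arange(0.0, duration_days * 24.0 + 0.05, 0.05)
            sim = simulate(ref_model, expand_regimen(spec), t_grid=t_h,
                           rtol=1e-6, atol=1e-8)
            cache[key] = (t_h, sim.concentrations["plasma"])
        return cache[key]

    return make
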