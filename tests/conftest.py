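import numpy as np
import pytest

from wearval import SimulationParams, SubjectProfile


@pytest.fixture
def noiseless_params():
    """All stochastic knobs off: generators become deterministic targets."""
    return SimulationParams(
        vo2_noise_cv=0.0,
        onkinetics_tau_s=0.0,
        accel_noise_floor_mg=0.0,
        enmo_noise_cv=0.0,
        device_mvpa_sd_min=0.0,
        device_aee_sd_kcal=0.0,
        seed=42,
    )


@pytest.fixture
def subject30():
    """A boy of 30 kg so per-MET VO2 is a round 150 mL/min at 5 mL/kg/min."""
    return SubjectProfile(
        subject_id="TEST30", sex="male", age_years=9.0, height_cm=135.0,
        weight_kg=30.0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20210925)
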