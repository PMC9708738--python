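import numpy as np
import pytest

from centend.observers import ObserverParams
from centend.schedules import default_reproduction_schedule


@pytest.fixture(scope="session")
def space_schedule():
    return default_reproduction_schedule("space", seed=11)


@pytest.fixture(scope="session")
def time_schedule():
    return default_reproduction_schedule("time", seed=11)


@pytest.fixture
def veridical_observer():
    """w = 0, no noise, no bias: responds with the stimulus exactly."""
    return ObserverParams(w_prior=0.0, sigma_s=0.0, sigma_m=0.0, bias=0.0, sigma_d=1.0)


@pytest.fixture
def pure_prior_observer():
    """w = 1, no motor noise: responds with the prior mean exactly."""
    return ObserverParams(w_prior=1.0, sigma_s=0.0, sigma_m=0.0, bias=0.0, sigma_d=1.0)


@pytest.fixture(scope="session")
def tiny_cohort_spec():
    """A fast, fully specified two-group cohort for pipeline tests."""
    def cond(w, noise_key, noise, bias, sd):
        return {
            "w_prior": w, noise_key: noise, "sigma_m": 0.1 if noise_key == "sigma_s" else 0.03,
            "bias": bias, "lapse": 0.02, "sigma_d": sd,
        }

    return {
        "groups": [
            {"name": "YA", "n": 2,
             "space": cond(0.4, "sigma_s", 1.5, -0.05, 0.9),
             "time": cond(0.3, "weber_coeff", 0.15, -0.05, 0.27)},
            {"name": "OA", "n": 2,
             "space": cond(0.5, "sigma_s", 2.0, -0.12, 1.3),
             "time": cond(0.3, "weber_coeff", 0.18, -0.12, 0.38)},
        ]
    }


@pytest.fixture(scope="session")
def tiny_cohort(tiny_cohort_spec):
    from centend.observers import simulate_cohort

    return simulate_cohort(tiny_cohort_spec, seed=17)
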