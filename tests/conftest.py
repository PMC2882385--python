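import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from casemix import comorbidity, risk_model
from casemix.synthetic_data import GeneratorConfig, simulate

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

#: One seed for the shared large cohort; sub-tests derive their own.
BIG_SEED = 20260926


@pytest.fixture(scope="session")
def big_cohort():
    """~500k discharges from the published coefficient set.

    General-profile hospitals only, zero frailty, intercept calibrated to
    3.7% mortality: the cohort used for coefficient-recovery, calibration
    and discrimination checks.  Charlson score/band columns are appended
    from the emitted ICD-10 codes.
    """
    cfg = GeneratorConfig(
        n_hospitals=125,
        admissions_mean=4000,
        specialized_fraction=0.0,
        convalescent_fraction=0.0,
        seed=BIG_SEED,
    )
    hospitals, records, coeffs = simulate(cfg)
    scored = comorbidity.score_code_strings(records["comorbidity_codes"])
    records = pd.concat([records, scored], axis=1)
    return {"hospitals": hospitals, "records": records, "true": coeffs, "config": cfg}


@pytest.fixture(scope="session")
def big_design(big_cohort):
    return risk_model.encode_frame(big_cohort["records"])


@pytest.fixture(scope="session")
def full_fit(big_cohort, big_design):
    """Model refit on the entire large cohort."""
    return risk_model.fit(big_design, big_cohort["records"]["died"])


@pytest.fixture(scope="session")
def dev_val_fit(big_cohort):
    """(development, validation, model) from a 50/50 split of the cohort."""
    records = big_cohort["records"]
    dev, val = risk_model.split(records, seed=BIG_SEED)
    model = risk_model.fit(risk_model.encode_frame(dev), dev["died"])
    return dev, val, model
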