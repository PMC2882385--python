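"""Generator: panel construction, covariate fidelity, outcome model, determinism."""

import io as _io

import numpy as np
import pandas as pd
import pytest
from scipy.special import logit

from casemix import comorbidity
from casemix import reference
from casemix.risk_model import MDC10_LABELS, ModelCoefficients
from casemix.synthetic_data import (
    CalibrationError,
    CovariateMarginals,
    GeneratorConfig,
    GeneratorConfigError,
    HospitalSpec,
    UncalibratedModelError,
    build_hospital_population,
    calibrate_intercept,
    emit_icd10_for_band,
    population_covariate_sampler,
    sample_discharges,
    simulate,
)

UNIFORM_MIX = np.full(10, 0.1)


def null_coefficients(intercept=None):
    return ModelCoefficients(
        intercept=intercept, values=pd.Series(0.0, index=list(reference.REFERENCE_LOG_ODDS))
    )


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs,field",
        [
            ({"n_hospitals": 0}, "n_hospitals"),
            ({"admissions_mean": -1}, "admissions_mean"),
            ({"target_mortality": 0.0}, "target_mortality"),
            ({"hospital_effect_sd": -0.1}, "hospital_effect_sd"),
            ({"specialized_fraction": 1.2}, "specialized_fraction"),
            ({"specialized_fraction": 0.7, "convalescent_fraction": 0.7}, "convalescent_fraction"),
            ({"casemix_concentration": 0}, "casemix_concentration"),
        ],
    )
    def test_invalid_fields_named(self, kwargs, field):
        with pytest.raises(GeneratorConfigError, match=field):
            GeneratorConfig(**kwargs).validate()

    def test_bad_marginals_named(self):
        marg = CovariateMarginals(age=(0.5, 0.1, 0.1, 0.1, 0.1, 0.2))
        with pytest.raises(GeneratorConfigError, match="age"):
            GeneratorConfig(covariate_marginals=marg).validate()

    def test_age_by_mdc_validation(self):
        marg = CovariateMarginals(age_by_mdc={"not_an_mdc": reference.AGE_PREVALENCE})
        with pytest.raises(GeneratorConfigError, match="age_by_mdc"):
            GeneratorConfig(covariate_marginals=marg).validate()


class TestHospitalPopulation:
    def test_panel_size_469(self):
        specs = build_hospital_population(GeneratorConfig(n_hospitals=469, seed=1))
        assert len(specs) == 469
        assert all(h.n_admissions >= 1 for h in specs)

    def test_zero_effect_sd_means_zero_frailty(self):
        specs = build_hospital_population(GeneratorConfig(n_hospitals=200, hospital_effect_sd=0, seed=4))
        assert all(h.log_frailty == 0.0 for h in specs)

    def test_specialized_have_dominant_mdc(self):
        specs = build_hospital_population(
            GeneratorConfig(n_hospitals=300, specialized_fraction=0.3, seed=2)
        )
        special = [h for h in specs if h.specialized]
        assert special and all(h.case_mix.max() > 0.5 for h in special)

    def test_specialized_fraction_binomial(self):
        # 99% binomial bounds around p=0.053 at n=1000
        specs = build_hospital_population(
            GeneratorConfig(n_hospitals=1000, specialized_fraction=0.053, seed=5)
        )
        k = sum(h.specialized for h in specs)
        se = np.sqrt(0.053 * 0.947 * 1000)
        assert abs(k - 53) < 2.576 * se

    def test_deterministic_and_stable_under_reordering(self):
        cfg = GeneratorConfig(n_hospitals=20, seed=9)
        a = build_hospital_population(cfg)
        b = build_hospital_population(cfg)
        assert all(np.array_equal(x.case_mix, y.case_mix) and x.n_admissions == y.n_admissions
                   for x, y in zip(a, b))
        # records per hospital keyed by id, not list position
        cfg_small = GeneratorConfig(n_hospitals=20, admissions_mean=50, seed=9)
        r1 = sample_discharges(a, _with_intercept(cfg_small))
        r2 = sample_discharges(list(reversed(a)), _with_intercept(cfg_small))
        h5_a = r1[r1.hospital_id == "H0005"].reset_index(drop=True)
        h5_b = r2[r2.hospital_id == "H0005"].reset_index(drop=True)
        pd.testing.assert_frame_equal(h5_a, h5_b)


def _with_intercept(cfg: GeneratorConfig, rate=None) -> GeneratorConfig:
    from dataclasses import replace

    coeffs = cfg.coefficients()
    if coeffs.intercept is None:
        hospitals = build_hospital_population(cfg)
        sampler = population_covariate_sampler(hospitals, cfg)
        b0 = calibrate_intercept(
            coeffs, sampler, rate or cfg.target_mortality,
            rng=np.random.default_rng(0),
        )
        coeffs = replace(coeffs, intercept=b0)
    return replace(cfg, true_coefficients=coeffs)


class TestSampleDischarges:
    def test_uncalibrated_intercept_rejected(self):
        cfg = GeneratorConfig(n_hospitals=2, admissions_mean=10, seed=0)
        hospitals = build_hospital_population(cfg)
        with pytest.raises(UncalibratedModelError):
            sample_discharges(hospitals, cfg)

    def test_null_model_death_rate(self):
        # all coefficients zero, intercept = logit(0.037): rate within 3 MC SE
        cfg = GeneratorConfig(
            n_hospitals=50, admissions_mean=4000, seed=13,
            true_coefficients=null_coefficients(intercept=float(logit(0.037))),
        )
        hospitals = build_hospital_population(cfg)
        records = sample_discharges(hospitals, cfg)
        n = len(records)
        assert n == sum(h.n_admissions for h in hospitals)
        se = np.sqrt(0.037 * 0.963 / n)
        assert abs(records["died"].mean() - 0.037) < 3 * se

    def test_frailty_doubles_death_odds(self):
        cfg = GeneratorConfig(
            n_hospitals=2, seed=21,
            true_coefficients=null_coefficients(intercept=float(logit(0.037))),
        )
        hospitals = [
            HospitalSpec("H0000", 100_000, UNIFORM_MIX, log_frailty=np.log(2.0)),
            HospitalSpec("H0001", 100_000, UNIFORM_MIX, log_frailty=0.0),
        ]
        records = sample_discharges(hospitals, cfg)
        rate = records.groupby("hospital_id")["died"].mean()
        odds = rate / (1 - rate)
        emp_or = odds["H0000"] / odds["H0001"]
        # 3 SE of a log odds ratio with ~3.7k/7.2k deaths
        assert abs(np.log(emp_or) - np.log(2.0)) < 3 * np.sqrt(1 / 3500 + 1 / 7000)

    def test_marginal_fidelity_big_cohort(self, big_cohort):
        # every configured marginal recovered within 4 MC SE at n~500k
        records = big_cohort["records"]
        n = len(records)

        def check(observed, p):
            se = np.sqrt(p * (1 - p) / n)
            assert abs(observed - p) < 4 * se, (observed, p)

        check((records["sex"] == "male").mean(), reference.MALE_PREVALENCE)
        for flag, p in reference.ADMISSION_FLAG_PREVALENCE.items():
            check(records[flag].mean(), p)
        for i, p in enumerate(reference.AGE_PREVALENCE):
            check((records["age_band"] == i).mean(), p)
        for band, p in reference.CHARLSON_BAND_PREVALENCE.items():
            check((records["charlson_band"] == band).mean(), p)
        for level, p in reference.PS_PREVALENCE.items():
            check((records["ps_grade"] == level).mean(), p)
        for level, p in reference.FHJ_PREVALENCE.items():
            check((records["fhj_class"] == level).mean(), p)

    def test_emergency_fraction_matches_cohort_table(self, big_cohort):
        records = big_cohort["records"]
        se = np.sqrt(0.423 * 0.577 / len(records))
        assert abs(records["emergency"].mean() - 0.423) < 3 * se

    def test_overall_mortality_near_target(self, big_cohort):
        # calibration tolerance 5e-4 plus 4 binomial SE
        records = big_cohort["records"]
        slack = 5e-4 + 4 * np.sqrt(0.037 * 0.963 / len(records))
        assert abs(records["died"].mean() - 0.037) < slack

    def test_determinism_byte_identical(self):
        cfg = GeneratorConfig(n_hospitals=5, admissions_mean=200, seed=33)
        _, r1, _ = simulate(cfg)
        _, r2, _ = simulate(cfg)
        b1, b2 = _io.StringIO(), _io.StringIO()
        r1.to_csv(b1, index=False)
        r2.to_csv(b2, index=False)
        assert b1.getvalue() == b2.getvalue()

    def test_age_by_mdc_conditional_shifts_marginal(self):
        old = (0.0, 0.0, 0.0, 0.1, 0.4, 0.5)
        marg = CovariateMarginals(age_by_mdc={"circulatory": old})
        cfg = GeneratorConfig(
            n_hospitals=4, admissions_mean=5000, covariate_marginals=marg, seed=8,
            true_coefficients=null_coefficients(intercept=float(logit(0.037))),
        )
        records = sample_discharges(build_hospital_population(cfg), cfg)
        circ = records[records.mdc10 == "circulatory"]
        other = records[records.mdc10 != "circulatory"]
        assert (circ["age_band"] >= 3).all()
        assert circ["age_band"].mean() > other["age_band"].mean() + 1


class TestCalibrateIntercept:
    def test_null_coefficients_closed_form(self):
        coeffs = null_coefficients()
        sampler = _uniform_sampler()
        b0 = calibrate_intercept(coeffs, sampler, 0.037, rng=np.random.default_rng(1))
        assert b0 == pytest.approx(float(logit(0.037)), abs=1e-6)
        assert b0 == pytest.approx(-3.2594, abs=1e-3)

    def test_reference_coefficients_hit_target(self):
        cfg = GeneratorConfig(n_hospitals=30, seed=17)
        hospitals = build_hospital_population(cfg)
        coeffs = cfg.coefficients()
        sampler = population_covariate_sampler(hospitals, cfg)
        b0 = calibrate_intercept(coeffs, sampler, 0.037, rng=np.random.default_rng(2))
        # independent re-simulation of the achieved mean risk
        X = sampler(200_000, np.random.default_rng(3))
        from scipy.special import expit

        achieved = expit(b0 + X.to_numpy() @ coeffs.values.to_numpy()).mean()
        assert abs(achieved - 0.037) < 5e-4 + 3 * 4e-4

    @pytest.mark.parametrize("rate", [0.0, 1.0, -0.1])
    def test_boundary_target_rejected(self, rate):
        with pytest.raises(ValueError, match="target_rate"):
            calibrate_intercept(null_coefficients(), _uniform_sampler(), rate)

    def test_too_few_samples_rejected(self):
        with pytest.raises(CalibrationError):
            calibrate_intercept(
                null_coefficients(), _uniform_sampler(), 0.037, n_samples=100
            )


def _uniform_sampler():
    cfg = GeneratorConfig(n_hospitals=1, seed=0)
    hospitals = [HospitalSpec("H0000", 10, UNIFORM_MIX)]
    return population_covariate_sampler(hospitals, cfg)


class TestEmitICD10:
    @pytest.mark.parametrize("target", comorbidity.BANDS)
    def test_round_trip_is_exact(self, target):
        rng = np.random.default_rng(6)
        for _ in range(200):
            codes = emit_icd10_for_band(target, rng)
            assert len(codes) <= 6
            assert comorbidity.score_codes(codes).band == target

    def test_band_zero_is_empty(self):
        assert emit_icd10_for_band("0", np.random.default_rng(0)) == []

    def test_top_band_score_at_least_13(self):
        rng = np.random.default_rng(7)
        scores = [comorbidity.score_codes(emit_icd10_for_band("13-", rng)).score for _ in range(50)]
        assert min(scores) >= 13

    def test_unknown_band_rejected(self):
        with pytest.raises(ValueError, match="band"):
            emit_icd10_for_band("5-9", np.random.default_rng(0))
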