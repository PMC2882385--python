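"""Encoding, splitting, logistic fitting and risk prediction."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from casemix import risk_model as rm
from casemix.synthetic_data import GeneratorConfig, simulate
from casemix import comorbidity


def make_record(**overrides):
    base = dict(
        hospital_id="H0000",
        age_band=1,
        sex="male",
        mdc10="musculoskeletal_other",
        emergency=False,
        ambulance=False,
        exam_hospitalization=False,
        planned_short=False,
        comorbidity_codes="",
        ps_grade="grade0_1_missing",
        fhj_class="class1_2_missing",
        died=False,
    )
    base.update(overrides)
    return base


class TestEncode:
    def test_all_reference_levels(self):
        v = rm.encode(make_record(), "0")
        assert v["male"] == 1 and v["age_ordinal"] == 1
        assert v.drop(["male", "age_ordinal"]).eq(0).all()

    def test_direct_mapping(self):
        v = rm.encode(
            make_record(sex="female", age_band=5, mdc10="blood_immune",
                        emergency=True, ambulance=True),
            "13-",
        )
        assert v["male"] == 0 and v["age_ordinal"] == 5
        assert v["mdc_blood_immune"] == 1 and v["charlson_13_plus"] == 1
        assert v["emergency"] == 1 and v["ambulance"] == 1
        assert v.sum() == 9  # 4 dummies + age 5

    def test_missing_ps_fhj_fold_into_reference(self):
        v = rm.encode(make_record(ps_grade="grade4"), "0")
        assert v["ps_grade4"] == 1
        assert v["fhj_class3_4"] == 0 and v["fhj_class5"] == 0

    def test_unknown_mdc_lists_vocabulary(self):
        with pytest.raises(ValueError, match="musculoskeletal_other"):
            rm.encode(make_record(mdc10="oncology"), "0")

    def test_exactly_24_columns(self):
        assert len(rm.COEFFICIENT_NAMES) == 24
        v = rm.encode(make_record(), "0")
        assert list(v.index) == list(rm.COEFFICIENT_NAMES)

    def test_frame_matches_single_record_encoding(self):
        rng = np.random.default_rng(5)
        rows = [
            make_record(
                sex=rng.choice(["male", "female"]),
                age_band=int(rng.integers(0, 6)),
                mdc10=str(rng.choice(rm.MDC10_LABELS)),
                emergency=bool(rng.integers(2)),
                ps_grade=str(rng.choice(rm.PS_LEVELS)),
                fhj_class=str(rng.choice(rm.FHJ_LEVELS)),
            )
            for _ in range(40)
        ]
        bands = rng.choice(comorbidity.BANDS, size=40)
        frame = rm.encode_frame(pd.DataFrame(rows), pd.Series(bands))
        for i, row in enumerate(rows):
            pd.testing.assert_series_equal(
                frame.iloc[i], rm.encode(row, bands[i]), check_names=False
            )


class TestSplit:
    def test_partition_disjoint_exhaustive(self):
        df = pd.DataFrame({"x": np.arange(10_000)})
        dev, val = rm.split(df, seed=3)
        assert len(dev) + len(val) == len(df)
        assert set(dev.index).isdisjoint(val.index)
        assert abs(len(dev) - 5000) < 4 * np.sqrt(10_000 * 0.25)

    def test_reproducible(self):
        df = pd.DataFrame({"x": np.arange(1000)})
        d1, _ = rm.split(df, seed=11)
        d2, _ = rm.split(df, seed=11)
        pd.testing.assert_frame_equal(d1, d2)

    def test_exact_method(self):
        df = pd.DataFrame({"x": np.arange(1001)})
        dev, val = rm.split(df, seed=1, method="exact")
        assert len(dev) == round(0.5 * 1001)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rm.split(pd.DataFrame({"x": [1]}))


class TestFit:
    def test_two_by_two_closed_form(self):
        # exposed 10/100 died, unexposed 5/100: OR = (10*95)/(90*5)
        x = np.repeat([1.0, 0.0], 100)
        y = np.concatenate([np.ones(10), np.zeros(90), np.ones(5), np.zeros(95)])
        res = rm.fit(pd.DataFrame({"exposed": x}), y)
        assert res.odds_ratios["exposed"] == pytest.approx(10 * 95 / (90 * 5), rel=1e-5)
        assert res.intercept == pytest.approx(np.log(5 / 95), rel=1e-5)

    def test_null_covariates_ci_covers_zero(self):
        rng = np.random.default_rng(100)
        n = 20_000
        X = pd.DataFrame(
            {
                "a": rng.integers(0, 2, n).astype(float),
                "b": rng.integers(0, 2, n).astype(float),
                "z": rng.normal(size=n),
            }
        )
        y = rng.random(n) < 0.05  # independent of X
        res = rm.fit(X, y)
        assert (res.values.abs() < 0.15).all()
        assert ((res.conf_int["lower"] <= 0) & (res.conf_int["upper"] >= 0)).all()

    def test_training_calibration_identity(self):
        rng = np.random.default_rng(7)
        n = 30_000
        X = pd.DataFrame({"a": rng.integers(0, 2, n).astype(float), "z": rng.normal(size=n)})
        y = rng.random(n) < expit(-3 + 0.8 * X["a"] + 0.5 * X["z"])
        res = rm.fit(X, y)
        preds = rm.predict_risk(res, X)
        assert abs(preds.sum() - y.sum()) / y.sum() < 1e-6

    def test_single_class_rejected(self):
        X = pd.DataFrame({"a": [0.0, 1.0, 0.0, 1.0]})
        with pytest.raises(ValueError, match="both outcome classes"):
            rm.fit(X, np.zeros(4))

    def test_constant_column_rejected(self):
        X = pd.DataFrame({"a": np.ones(100), "b": np.arange(100.0)})
        with pytest.raises(ValueError, match="constant"):
            rm.fit(X, np.arange(100) % 2)

    def test_perfect_separation_names_column(self):
        rng = np.random.default_rng(0)
        n = 400
        sep = np.repeat([0.0, 1.0], n // 2)
        y = sep.copy()  # deaths exactly where sep = 1
        X = pd.DataFrame({"noise": rng.normal(size=n), "sep": sep})
        with pytest.raises(rm.PerfectSeparationError, match="sep"):
            rm.fit(X, y)

    @pytest.mark.parametrize("seed", [101, 202, 303])
    def test_coefficient_recovery_nominal_coverage(self, seed):
        # refit on a 40k cohort generated from the published coefficients:
        # nearly all 95% Wald CIs should cover the generating values
        cfg = GeneratorConfig(
            n_hospitals=10, admissions_mean=4000,
            specialized_fraction=0, convalescent_fraction=0, seed=seed,
        )
        _, records, truth = simulate(cfg)
        scored = comorbidity.score_code_strings(records["comorbidity_codes"])
        X = rm.encode_frame(records.assign(charlson_band=scored["charlson_band"]))
        res = rm.fit(X, records["died"])
        covered = (
            (res.conf_int["lower"] <= truth.values) & (truth.values <= res.conf_int["upper"])
        )
        assert covered.sum() >= 21  # ≥ 21/24 at nominal 95%


class TestPredictRisk:
    def test_all_reference_vector(self):
        coeffs = rm.ModelCoefficients(intercept=-3.0, values=pd.Series({"a": 0.5, "b": 1.0}))
        X = pd.DataFrame({"a": [0.0], "b": [0.0]})
        assert rm.predict_risk(coeffs, X)[0] == pytest.approx(expit(-3.0))

    def test_log2_doubles_odds_exactly(self):
        coeffs = rm.ModelCoefficients(intercept=-2.0, values=pd.Series({"a": np.log(2)}))
        p0 = rm.predict_risk(coeffs, pd.DataFrame({"a": [0.0]}))[0]
        p1 = rm.predict_risk(coeffs, pd.DataFrame({"a": [1.0]}))[0]
        assert p1 / (1 - p1) == pytest.approx(2 * p0 / (1 - p0), rel=1e-12)

    def test_monotone_in_age(self):
        coeffs = rm.ModelCoefficients.reference_model(intercept=-6.0)
        rows = []
        for a in range(6):
            rows.append(rm.encode(make_record(age_band=a), "0"))
        preds = rm.predict_risk(coeffs, pd.DataFrame(rows))
        assert (np.diff(preds) > 0).all()

    def test_name_mismatch_rejected(self):
        coeffs = rm.ModelCoefficients(intercept=0.0, values=pd.Series({"a": 1.0}))
        with pytest.raises(ValueError, match="mismatch"):
            rm.predict_risk(coeffs, pd.DataFrame({"b": [1.0]}))

    def test_missing_intercept_rejected(self):
        coeffs = rm.ModelCoefficients(intercept=None, values=pd.Series({"a": 1.0}))
        with pytest.raises(ValueError, match="intercept"):
            rm.predict_risk(coeffs, pd.DataFrame({"a": [1.0]}))


def test_model_json_round_trip(tmp_path):
    coeffs = rm.ModelCoefficients.reference_model(intercept=-5.4321)
    path = tmp_path / "model.json"
    coeffs.to_json(path)
    back = rm.ModelCoefficients.from_json(path)
    assert back.intercept == coeffs.intercept
    pd.testing.assert_series_equal(back.values, coeffs.values)
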