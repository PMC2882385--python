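"""Synthetic DPC-like hospital panel and discharge-record generator.

Emulates a nationwide acute-care discharge database: a panel of hospitals of
heterogeneous size and case-mix (general acute, single-specialty, and
convalescent-mixed profiles), each contributing discharge records whose
covariates are drawn from configured marginals and whose in-hospital death
flag is drawn from the case-mix logistic model

    logit P(death) = intercept + x·beta + hospital log-frailty.

Defaults reproduce the published development-cohort covariate marginals, the
published model's log odds ratios, an overall mortality of 3.7%, and a
negative-binomial hospital-size distribution (mean ~4011, SD ~2539).  The
intercept is not published and is calibrated numerically to the target
mortality.

Covariates are sampled independently within a record (only marginals are
published); the Charlson band is sampled directly and then materialized as a
concrete ICD-10 co-existing-diagnosis list that round-trips through the
comorbidity scorer to the same band, so the downstream pipeline exercises
real code-level scoring.

Randomness: one global seed; every hospital draws from its own substream
keyed by a CRC32 counter of its id, so hospital record streams are stable
under reordering of the panel.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from . import comorbidity, reference
from .risk_model import (
    AGE_BAND_LABELS,
    MDC10_LABELS,
    ModelCoefficients,
    PS_LEVELS,
    FHJ_LEVELS,
    encode_frame,
)

__all__ = [
    "GeneratorConfig",
    "GeneratorConfigError",
    "UncalibratedModelError",
    "CalibrationError",
    "CovariateMarginals",
    "HospitalSpec",
    "DischargeRecord",
    "build_hospital_population",
    "sample_discharges",
    "calibrate_intercept",
    "emit_icd10_for_band",
    "population_covariate_sampler",
    "simulate",
]

RECORD_COLUMNS = (
    "hospital_id",
    "age_band",
    "sex",
    "mdc10",
    "emergency",
    "ambulance",
    "exam_hospitalization",
    "planned_short",
    "comorbidity_codes",
    "ps_grade",
    "fhj_class",
    "died",
)


class GeneratorConfigError(ValueError):
    """A generator configuration field is invalid."""


class UncalibratedModelError(RuntimeError):
    """Outcome generation requested without an intercept."""


class CalibrationError(RuntimeError):
    """Intercept calibration failed to reach the target mortality."""


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, key)]))


def _hospital_stream(hospital_id: str) -> int:
    return zlib.crc32(hospital_id.encode("utf-8"))


def _check_probs(name: str, probs, expect_len: Optional[int] = None) -> np.ndarray:
    p = np.asarray(probs, dtype=float)
    if expect_len is not None and p.shape != (expect_len,):
        raise GeneratorConfigError(f"{name}: expected {expect_len} probabilities, got {p.shape}")
    if (p < 0).any() or (p > 1).any():
        raise GeneratorConfigError(f"{name}: probabilities must lie in [0, 1]")
    if abs(p.sum() - 1.0) > 1e-9:
        raise GeneratorConfigError(f"{name}: probabilities sum to {p.sum():.12f}, not 1")
    return p


@dataclass(frozen=True)
class CovariateMarginals:
    """Marginal covariate distributions driving record sampling.

    Defaults are the published development-cohort proportions.  ``flags`` are
    independent non-exclusive Bernoulli probabilities.
    """

    mdc: dict = field(default_factory=lambda: dict(reference.MDC_PREVALENCE))
    age: tuple = reference.AGE_PREVALENCE
    #: Optional MDC-conditional age tables {mdc_label: 6 probabilities}.
    #: Default off: only marginals are published, so covariates are sampled
    #: independently within a record unless a conditional table is supplied.
    age_by_mdc: Optional[dict] = None
    male: float = reference.MALE_PREVALENCE
    charlson: dict = field(default_factory=lambda: dict(reference.CHARLSON_BAND_PREVALENCE))
    flags: dict = field(default_factory=lambda: dict(reference.ADMISSION_FLAG_PREVALENCE))
    ps: dict = field(default_factory=lambda: dict(reference.PS_PREVALENCE))
    fhj: dict = field(default_factory=lambda: dict(reference.FHJ_PREVALENCE))

    def validate(self) -> None:
        if set(self.mdc) != set(MDC10_LABELS):
            raise GeneratorConfigError(
                f"covariate_marginals.mdc: labels must be {sorted(MDC10_LABELS)}"
            )
        _check_probs("covariate_marginals.mdc", [self.mdc[m] for m in MDC10_LABELS])
        _check_probs("covariate_marginals.age", self.age, len(AGE_BAND_LABELS))
        if not 0 <= self.male <= 1:
            raise GeneratorConfigError("covariate_marginals.male: must lie in [0, 1]")
        _check_probs(
            "covariate_marginals.charlson",
            [self.charlson[b] for b in comorbidity.BANDS],
            len(comorbidity.BANDS),
        )
        for flag, p in self.flags.items():
            if not 0 <= p <= 1:
                raise GeneratorConfigError(f"covariate_marginals.flags[{flag}]: must lie in [0, 1]")
        _check_probs("covariate_marginals.ps", [self.ps[l] for l in PS_LEVELS], len(PS_LEVELS))
        _check_probs("covariate_marginals.fhj", [self.fhj[l] for l in FHJ_LEVELS], len(FHJ_LEVELS))
        if self.age_by_mdc is not None:
            unknown = set(self.age_by_mdc) - set(MDC10_LABELS)
            if unknown:
                raise GeneratorConfigError(f"covariate_marginals.age_by_mdc: unknown MDC {sorted(unknown)}")
            for m, probs in self.age_by_mdc.items():
                _check_probs(f"covariate_marginals.age_by_mdc[{m}]", probs, len(AGE_BAND_LABELS))


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic panel; defaults emulate the study cohort."""

    n_hospitals: int = 50
    admissions_mean: float = reference.HOSPITAL_ADMISSIONS_MEAN
    admissions_dispersion: float = reference.HOSPITAL_ADMISSIONS_DISPERSION
    covariate_marginals: CovariateMarginals = field(default_factory=CovariateMarginals)
    true_coefficients: Optional[ModelCoefficients] = None
    target_mortality: float = reference.OVERALL_MORTALITY
    hospital_effect_sd: float = 0.0
    specialized_fraction: float = reference.SPECIALIZED_FRACTION
    convalescent_fraction: float = reference.CONVALESCENT_FRACTION
    public_fraction: float = reference.PUBLIC_FRACTION
    university_fraction: float = reference.UNIVERSITY_FRACTION
    #: Dirichlet concentration of per-hospital case-mix around the global MDC
    #: marginals (lower = more heterogeneous hospitals).
    casemix_concentration: float = 22.0
    #: Dominant-MDC share range for single-specialty hospitals (always > 0.5).
    specialized_share_range: tuple = (0.55, 0.90)
    #: Convalescent-mixed profile: exponential tilt on the age marginal,
    #: multiplicative alpha boost on circulatory/nervous shares, and optional
    #: extra frailty SD emulating poorer model fit in mixed-care hospitals.
    convalescent_age_tilt: float = 0.35
    convalescent_mdc_boost: float = 3.0
    convalescent_frailty_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_hospitals < 1:
            raise GeneratorConfigError("n_hospitals: must be >= 1")
        if self.admissions_mean <= 0:
            raise GeneratorConfigError("admissions_mean: must be > 0")
        if self.admissions_dispersion <= 0:
            raise GeneratorConfigError("admissions_dispersion: must be > 0")
        if not 0 < self.target_mortality < 1:
            raise GeneratorConfigError("target_mortality: must lie in (0, 1)")
        if self.hospital_effect_sd < 0:
            raise GeneratorConfigError("hospital_effect_sd: must be >= 0")
        if self.convalescent_frailty_sd < 0:
            raise GeneratorConfigError("convalescent_frailty_sd: must be >= 0")
        for name in ("specialized_fraction", "convalescent_fraction", "public_fraction", "university_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise GeneratorConfigError(f"{name}: must lie in [0, 1]")
        if self.specialized_fraction + self.convalescent_fraction > 1:
            raise GeneratorConfigError(
                "specialized_fraction + convalescent_fraction: must be <= 1"
            )
        if self.casemix_concentration <= 0:
            raise GeneratorConfigError("casemix_concentration: must be > 0")
        lo, hi = self.specialized_share_range
        if not 0.5 < lo <= hi < 1:
            raise GeneratorConfigError("specialized_share_range: need 0.5 < lo <= hi < 1")
        self.covariate_marginals.validate()

    def coefficients(self) -> ModelCoefficients:
        return self.true_coefficients or ModelCoefficients.reference_model()


@dataclass
class HospitalSpec:
    """One synthetic hospital: size, case-mix, frailty and profile flags."""

    hospital_id: str
    n_admissions: int
    case_mix: np.ndarray  # over MDC10_LABELS, sums to 1
    log_frailty: float = 0.0
    specialized: bool = False
    convalescent: bool = False
    public: bool = False
    university: bool = False

    def __post_init__(self) -> None:
        self.case_mix = np.asarray(self.case_mix, dtype=float)
        if self.n_admissions < 1:
            raise GeneratorConfigError("n_admissions: must be >= 1")
        _check_probs(f"{self.hospital_id}.case_mix", self.case_mix, len(MDC10_LABELS))


@dataclass(frozen=True)
class DischargeRecord:
    """One hospitalization; the tabular API uses one DataFrame row per record."""

    hospital_id: str
    age_band: int
    sex: str
    mdc10: str
    emergency: bool
    ambulance: bool
    exam_hospitalization: bool
    planned_short: bool
    comorbidity_codes: tuple
    ps_grade: str
    fhj_class: str
    died: bool

    def __post_init__(self) -> None:
        if not 0 <= self.age_band <= 5:
            raise ValueError(f"age_band must lie in 0..5, got {self.age_band}")
        if self.mdc10 not in MDC10_LABELS:
            raise ValueError(f"unknown mdc10 {self.mdc10!r}")
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be male/female, got {self.sex!r}")
        if self.ps_grade not in PS_LEVELS:
            raise ValueError(f"unknown ps_grade {self.ps_grade!r}")
        if self.fhj_class not in FHJ_LEVELS:
            raise ValueError(f"unknown fhj_class {self.fhj_class!r}")

    def to_mapping(self) -> dict:
        d = self.__dict__.copy()
        d["comorbidity_codes"] = ";".join(self.comorbidity_codes)
        return d

    @classmethod
    def from_row(cls, row) -> "DischargeRecord":
        codes = row["comorbidity_codes"]
        if isinstance(codes, str):
            codes = tuple(c for c in codes.split(";") if c)
        return cls(
            hospital_id=str(row["hospital_id"]),
            age_band=int(row["age_band"]),
            sex=str(row["sex"]),
            mdc10=str(row["mdc10"]),
            emergency=bool(row["emergency"]),
            ambulance=bool(row["ambulance"]),
            exam_hospitalization=bool(row["exam_hospitalization"]),
            planned_short=bool(row["planned_short"]),
            comorbidity_codes=tuple(codes),
            ps_grade=str(row["ps_grade"]),
            fhj_class=str(row["fhj_class"]),
            died=bool(row["died"]),
        )


# ---------------------------------------------------------------------------
# hospital panel


def build_hospital_population(config: GeneratorConfig) -> list[HospitalSpec]:
    """Draw the hospital panel: sizes, profiles, case-mixes and frailties.

    Each hospital is drawn from its own seed substream, so the panel is
    deterministic given ``config.seed`` and individual hospitals are stable
    under reordering.
    """
    config.validate()
    marg = config.covariate_marginals
    base_probs = np.array([marg.mdc[m] for m in MDC10_LABELS])
    r = config.admissions_dispersion
    p_nb = r / (r + config.admissions_mean)
    s, c = config.specialized_fraction, config.convalescent_fraction
    circ_nerv = [MDC10_LABELS.index("circulatory"), MDC10_LABELS.index("nervous")]

    hospitals = []
    for i in range(config.n_hospitals):
        rng = _rng(config.seed, 0, i)
        u = rng.random()
        specialized = u < s
        convalescent = (not specialized) and u < s + c
        n_adm = max(1, int(rng.negative_binomial(r, p_nb)))
        alpha = config.casemix_concentration * base_probs
        if specialized:
            dominant = int(rng.choice(len(MDC10_LABELS), p=base_probs))
            share = rng.uniform(*config.specialized_share_range)
            rest_alpha = np.delete(alpha, dominant)
            rest = rng.dirichlet(rest_alpha) * (1.0 - share)
            case_mix = np.insert(rest, dominant, share)
        else:
            if convalescent:
                alpha = alpha.copy()
                alpha[circ_nerv] *= config.convalescent_mdc_boost
            case_mix = rng.dirichlet(alpha)
        log_frailty = 0.0
        if config.hospital_effect_sd > 0:
            log_frailty += rng.normal(0.0, config.hospital_effect_sd)
        if convalescent and config.convalescent_frailty_sd > 0:
            log_frailty += rng.normal(0.0, config.convalescent_frailty_sd)
        hospitals.append(
            HospitalSpec(
                hospital_id=f"H{i:04d}",
                n_admissions=n_adm,
                case_mix=case_mix,
                log_frailty=float(log_frailty),
                specialized=specialized,
                convalescent=convalescent,
                public=bool(rng.random() < config.public_fraction),
                university=bool(rng.random() < config.university_fraction),
            )
        )
    return hospitals


def hospital_metadata(hospitals: Sequence[HospitalSpec]) -> pd.DataFrame:
    """Hospital-level metadata table (one row per hospital)."""
    rows = []
    for h in hospitals:
        row = {
            "hospital_id": h.hospital_id,
            "n_admissions_planned": h.n_admissions,
            "log_frailty": h.log_frailty,
            "specialized": h.specialized,
            "convalescent": h.convalescent,
            "public": h.public,
            "university": h.university,
        }
        row.update({f"casemix_{m}": h.case_mix[j] for j, m in enumerate(MDC10_LABELS)})
        rows.append(row)
    return pd.DataFrame(rows).set_index("hospital_id")


# ---------------------------------------------------------------------------
# ICD-10 emission for a target Charlson band

_BAND_SCORE_RANGE = {"0": (0, 0), "1-2": (1, 2), "3-6": (3, 6), "7-12": (7, 12), "13-": (13, 18)}

# Condition pools by weight, restricted to conditions with no hierarchy
# interactions so emitted scores are exactly the sum of chosen weights.
_POOL_W6 = ("metastatic_solid_tumor", "aids_hiv")
_POOL_W3 = ("moderate_severe_liver",)
_POOL_W2 = ("hemiplegia_paraplegia", "renal_disease", "diabetes_complicated")
_POOL_W1 = (
    "myocardial_infarction",
    "congestive_heart_failure",
    "peripheral_vascular_disease",
    "cerebrovascular_disease",
    "dementia",
    "chronic_pulmonary_disease",
    "rheumatic_disease",
    "peptic_ulcer_disease",
)


class BandUnreachableError(RuntimeError):
    """The requested Charlson band cannot be reached within six codes."""


def emit_icd10_for_band(
    target_band: str,
    rng: np.random.Generator,
    cmap: Optional[comorbidity.CharlsonMap] = None,
) -> list[str]:
    """Emit ICD-10 codes whose Charlson score falls in ``target_band``.

    At most six codes (the record format's co-existing diagnosis limit).  The
    target score is drawn uniformly over the band's reachable range, then
    decomposed greedily over hierarchy-free conditions of weights 6/3/2/1;
    each chosen condition contributes one randomly chosen code prefix.
    """
    if target_band not in _BAND_SCORE_RANGE:
        raise ValueError(f"unknown Charlson band {target_band!r}; expected one of {comorbidity.BANDS}")
    cmap = cmap or comorbidity.load_quan_map()
    lo, hi = _BAND_SCORE_RANGE[target_band]
    if hi == 0:
        return []
    target = int(rng.integers(lo, hi + 1))
    remaining = target
    chosen: list[str] = []
    for weight, pool in ((6, _POOL_W6), (3, _POOL_W3), (2, _POOL_W2), (1, _POOL_W1)):
        for cond in rng.permutation(pool):
            if remaining >= weight and len(chosen) < 6:
                chosen.append(str(cond))
                remaining -= weight
    if remaining != 0:
        raise BandUnreachableError(
            f"cannot reach score {target} (band {target_band}) within six codes"
        )
    codes = [str(rng.choice(sorted(cmap.prefixes_of(cond)))) for cond in chosen]
    result = comorbidity.score_codes(codes, cmap)
    if result.band != target_band:  # pragma: no cover - internal consistency
        raise RuntimeError(f"emitted codes {codes} scored into band {result.band}, wanted {target_band}")
    return codes


def _code_pools(
    rng: np.random.Generator,
    cmap: Optional[comorbidity.CharlsonMap] = None,
    pool_size: int = 64,
) -> dict[str, list[str]]:
    """Pre-draw ``pool_size`` code lists per band (joined with ';')."""
    cmap = cmap or comorbidity.load_quan_map()
    return {
        b: [";".join(emit_icd10_for_band(b, rng, cmap)) for _ in range(pool_size)]
        for b in comorbidity.BANDS
    }


# ---------------------------------------------------------------------------
# record sampling


def _age_probs(config: GeneratorConfig, convalescent: bool) -> np.ndarray:
    p = np.asarray(config.covariate_marginals.age, dtype=float)
    if convalescent and config.convalescent_age_tilt:
        p = p * np.exp(config.convalescent_age_tilt * np.arange(len(p)))
        p = p / p.sum()
    return p


def _sample_covariates(
    n: int,
    rng: np.random.Generator,
    config: GeneratorConfig,
    case_mix: Optional[np.ndarray] = None,
    convalescent: bool = False,
) -> pd.DataFrame:
    """Draw ``n`` covariate rows (with a ``charlson_band`` column, no codes)."""
    marg = config.covariate_marginals
    mdc_p = (
        np.asarray(case_mix, dtype=float)
        if case_mix is not None
        else np.array([marg.mdc[m] for m in MDC10_LABELS])
    )
    labels = np.asarray(MDC10_LABELS, dtype=object)
    bands = np.asarray(comorbidity.BANDS, dtype=object)
    ps_levels = np.asarray(PS_LEVELS, dtype=object)
    fhj_levels = np.asarray(FHJ_LEVELS, dtype=object)
    mdc_idx = rng.choice(len(labels), size=n, p=mdc_p)
    if marg.age_by_mdc is None:
        age = rng.choice(len(AGE_BAND_LABELS), size=n, p=_age_probs(config, convalescent))
    else:
        # MDC-conditional age: one uniform per record against the row's CDF
        tilt = np.exp(config.convalescent_age_tilt * np.arange(len(AGE_BAND_LABELS))) if (
            convalescent and config.convalescent_age_tilt
        ) else np.ones(len(AGE_BAND_LABELS))
        table = np.empty((len(labels), len(AGE_BAND_LABELS)))
        for j, m in enumerate(MDC10_LABELS):
            row = np.asarray(marg.age_by_mdc.get(m, marg.age), dtype=float) * tilt
            table[j] = row / row.sum()
        cdf = np.cumsum(table, axis=1)
        age = (rng.random(n)[:, None] > cdf[mdc_idx]).sum(axis=1)
    out = pd.DataFrame(
        {
            "age_band": age,
            "sex": np.where(rng.random(n) < marg.male, "male", "female"),
            "mdc10": labels[mdc_idx],
            "emergency": rng.random(n) < marg.flags["emergency"],
            "ambulance": rng.random(n) < marg.flags["ambulance"],
            "exam_hospitalization": rng.random(n) < marg.flags["exam_hospitalization"],
            "planned_short": rng.random(n) < marg.flags["planned_short"],
            "charlson_band": bands[rng.choice(len(bands), size=n, p=[marg.charlson[b] for b in comorbidity.BANDS])],
            "ps_grade": ps_levels[rng.choice(len(ps_levels), size=n, p=[marg.ps[l] for l in PS_LEVELS])],
            "fhj_class": fhj_levels[rng.choice(len(fhj_levels), size=n, p=[marg.fhj[l] for l in FHJ_LEVELS])],
        }
    )
    return out


def sample_discharges(
    hospitals: Sequence[HospitalSpec],
    config: GeneratorConfig,
    pool_size: int = 64,
) -> pd.DataFrame:
    """Sample every hospital's discharge records with model-generated deaths.

    Requires ``config``'s coefficients to carry a calibrated intercept (see
    :func:`calibrate_intercept`); raises :class:`UncalibratedModelError`
    otherwise.  Returns one DataFrame with :data:`RECORD_COLUMNS`, hospitals
    in panel order, deterministic given ``config.seed``.
    """
    config.validate()
    coeffs = config.coefficients()
    if coeffs.intercept is None:
        raise UncalibratedModelError(
            "true_coefficients has no intercept; run calibrate_intercept (or "
            "simulate(), which calibrates automatically) before sampling outcomes"
        )
    beta = coeffs.values.to_numpy()
    pools = _code_pools(_rng(config.seed, 2), pool_size=pool_size)
    band_index = {b: i for i, b in enumerate(comorbidity.BANDS)}
    pool_arrays = {b: np.asarray(pools[b], dtype=object) for b in comorbidity.BANDS}

    frames = []
    for h in hospitals:
        rng = _rng(config.seed, 1, _hospital_stream(h.hospital_id))
        cov = _sample_covariates(
            h.n_admissions, rng, config, case_mix=h.case_mix, convalescent=h.convalescent
        )
        design = encode_frame(cov)
        lp = coeffs.intercept + design.to_numpy() @ beta + h.log_frailty
        died = rng.random(h.n_admissions) < expit(lp)
        pool_idx = rng.integers(0, pool_size, size=h.n_admissions)
        codes = np.empty(h.n_admissions, dtype=object)
        for b, arr in pool_arrays.items():
            m = (cov["charlson_band"] == b).to_numpy()
            codes[m] = arr[pool_idx[m]]
        frame = cov.drop(columns="charlson_band")
        frame.insert(0, "hospital_id", h.hospital_id)
        frame["comorbidity_codes"] = codes
        frame["died"] = died
        frames.append(frame[list(RECORD_COLUMNS)])
    records = pd.concat(frames, ignore_index=True)
    records["age_band"] = records["age_band"].astype(int)
    return records


def population_covariate_sampler(
    hospitals: Sequence[HospitalSpec],
    config: GeneratorConfig,
) -> Callable[[int, np.random.Generator], pd.DataFrame]:
    """Sampler of encoded covariate vectors from the admission-weighted panel.

    Returns ``sampler(n, rng) -> design DataFrame`` drawing each row from a
    hospital chosen proportionally to its planned admissions — the covariate
    distribution the intercept must be calibrated against.
    """
    sizes = np.array([h.n_admissions for h in hospitals], dtype=float)
    weights = sizes / sizes.sum()

    def sampler(n: int, rng: np.random.Generator) -> pd.DataFrame:
        counts = rng.multinomial(n, weights)
        parts = [
            encode_frame(
                _sample_covariates(int(k), rng, config, case_mix=h.case_mix, convalescent=h.convalescent)
            )
            for h, k in zip(hospitals, counts)
            if k > 0
        ]
        return pd.concat(parts, ignore_index=True)

    return sampler


def calibrate_intercept(
    coefficients: ModelCoefficients,
    covariate_sampler: Callable[[int, np.random.Generator], pd.DataFrame],
    target_rate: float,
    n_samples: int = 200_000,
    tol: float = 5e-4,
    rng: Optional[np.random.Generator] = None,
) -> float:
    """Solve for the intercept giving mean predicted risk = ``target_rate``.

    The mean of ``expit(b0 + lp)`` over sampled covariate linear predictors
    is strictly increasing in ``b0``, so Brent root-finding on a wide bracket
    converges; a :class:`CalibrationError` reporting the achieved rate is
    raised if the solution misses the target by more than ``tol``.
    """
    if not 0 < target_rate < 1:
        raise ValueError(f"target_rate must lie in (0, 1), got {target_rate}")
    rng = rng or np.random.default_rng()
    X = covariate_sampler(n_samples, rng)
    if len(X) < 10_000:
        raise CalibrationError(f"need >= 10,000 sampled covariate vectors, got {len(X)}")
    lp = X.to_numpy() @ coefficients.values.reindex(X.columns).to_numpy()

    def achieved(b0: float) -> float:
        return float(expit(b0 + lp).mean())

    b0 = brentq(lambda b: achieved(b) - target_rate, -40.0, 20.0, xtol=1e-10)
    got = achieved(b0)
    if abs(got - target_rate) > tol:
        raise CalibrationError(
            f"calibration achieved rate {got:.6f}, target {target_rate:.6f} (tol {tol})"
        )
    return float(b0)


def simulate(
    config: GeneratorConfig,
) -> tuple[list[HospitalSpec], pd.DataFrame, ModelCoefficients]:
    """End-to-end generation: panel, intercept calibration, records.

    Returns ``(hospitals, records, coefficients)`` where ``coefficients``
    carries the calibrated (or supplied) intercept actually used.
    """
    config.validate()
    hospitals = build_hospital_population(config)
    coeffs = config.coefficients()
    if coeffs.intercept is None:
        if (coeffs.values == 0).all():
            intercept = float(logit(config.target_mortality))
        else:
            sampler = population_covariate_sampler(hospitals, config)
            intercept = calibrate_intercept(
                coeffs, sampler, config.target_mortality, rng=_rng(config.seed, 3)
            )
        coeffs = replace(coeffs, intercept=intercept)
    run_config = replace(config, true_coefficients=coeffs)
    records = sample_discharges(hospitals, run_config)
    return hospitals, records, coeffs
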