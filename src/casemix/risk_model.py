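"""Case-mix logistic model for in-hospital mortality.

The model regresses the in-hospital death flag on 24 design columns: 9 MDC
indicators (reference: musculoskeletal/injuries/other), a male indicator, age
as a single ordinal linear term over six bands (under 50 .. 90+), four
Charlson-band indicators (reference: score 0), four non-exclusive
admission-status flags, three ECOG performance-status indicators (reference:
grade 0/1 or missing) and two Fletcher-Hugh-Jones indicators (reference:
class 1/2 or missing).  Missing PS/FHJ fold into the reference level by
construction of the collapsed factor levels.

Records are split into development and validation halves by per-record
Bernoulli(1/2) assignment; the model is fit by maximum likelihood on the
development half and per-record death probabilities are the inverse logit of
the fitted linear predictor.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit

from . import reference

__all__ = [
    "MDC10_LABELS",
    "MDC_REFERENCE",
    "AGE_BAND_LABELS",
    "PS_LEVELS",
    "FHJ_LEVELS",
    "COEFFICIENT_NAMES",
    "ModelCoefficients",
    "PerfectSeparationError",
    "encode",
    "encode_frame",
    "split",
    "fit",
    "predict_risk",
]

MDC10_LABELS = (
    "digestive",
    "respiratory",
    "blood_immune",
    "kidney",
    "nervous",
    "circulatory",
    "female_breast",
    "endocrine",
    "skin_eye_pediatric",
    "musculoskeletal_other",
)
MDC_REFERENCE = "musculoskeletal_other"

AGE_BAND_LABELS = ("under50", "50-59", "60-69", "70-79", "80-89", "90+")

PS_LEVELS = ("grade0_1_missing", "grade2", "grade3", "grade4")
FHJ_LEVELS = ("class1_2_missing", "class3_4", "class5")

CHARLSON_BAND_COLUMNS = {
    "1-2": "charlson_1_2",
    "3-6": "charlson_3_6",
    "7-12": "charlson_7_12",
    "13-": "charlson_13_plus",
}

ADMISSION_FLAGS = ("emergency", "ambulance", "exam_hospitalization", "planned_short")

#: Design-matrix columns, fixed order; reference levels carry no column.
COEFFICIENT_NAMES: tuple[str, ...] = (
    tuple(f"mdc_{m}" for m in MDC10_LABELS if m != MDC_REFERENCE)
    + ("male", "age_ordinal")
    + tuple(CHARLSON_BAND_COLUMNS[b] for b in ("1-2", "3-6", "7-12", "13-"))
    + ADMISSION_FLAGS
    + ("ps_grade2", "ps_grade3", "ps_grade4")
    + ("fhj_class3_4", "fhj_class5")
)


class PerfectSeparationError(RuntimeError):
    """The likelihood is unbounded because a column separates the outcome."""


@dataclass
class ModelCoefficients:
    """Intercept plus named log-odds coefficients of the case-mix model.

    ``values`` is indexed by :data:`COEFFICIENT_NAMES`.  ``conf_int`` (when
    present, i.e. after a fit) holds Wald 95% bounds on the log-odds scale.
    """

    intercept: Optional[float]
    values: pd.Series
    conf_int: Optional[pd.DataFrame] = None
    n: Optional[int] = None
    converged: bool = True
    log_likelihood: Optional[float] = None
    seed: Optional[int] = None
    standard_errors: Optional[pd.Series] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.values = pd.Series(self.values, dtype=float)
        if set(self.values.index) == set(COEFFICIENT_NAMES):
            self.values = self.values.reindex(COEFFICIENT_NAMES)
        if self.values.isna().any():
            missing = list(self.values.index[self.values.isna()])
            raise ValueError(f"missing coefficients: {missing}")

    @classmethod
    def from_odds_ratios(
        cls, odds_ratios: dict[str, float], intercept: Optional[float] = None
    ) -> "ModelCoefficients":
        return cls(intercept=intercept, values=pd.Series({k: np.log(v) for k, v in odds_ratios.items()}))

    @classmethod
    def reference_model(cls, intercept: Optional[float] = None) -> "ModelCoefficients":
        """The published model's log odds ratios (intercept not published)."""
        return cls(intercept=intercept, values=pd.Series(reference.REFERENCE_LOG_ODDS))

    @property
    def odds_ratios(self) -> pd.Series:
        return np.exp(self.values)

    def odds_ratio_ci(self) -> Optional[pd.DataFrame]:
        if self.conf_int is None:
            return None
        ci = np.exp(self.conf_int)
        ci.columns = ["or_lower", "or_upper"]
        return ci

    def to_json(self, path=None) -> str:
        payload = {
            "intercept": self.intercept,
            "log_odds": self.values.to_dict(),
            "odds_ratios": self.odds_ratios.round(6).to_dict(),
            "conf_int_log_odds": None
            if self.conf_int is None
            else {k: list(v) for k, v in self.conf_int.iterrows()},
            "n": self.n,
            "converged": self.converged,
            "log_likelihood": self.log_likelihood,
            "seed": self.seed,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "ModelCoefficients":
        if hasattr(source, "read"):
            payload = json.load(source)
        else:
            try:
                payload = json.loads(source)
            except (json.JSONDecodeError, TypeError):
                with open(source) as fh:
                    payload = json.load(fh)
        ci = payload.get("conf_int_log_odds")
        return cls(
            intercept=payload["intercept"],
            values=pd.Series(payload["log_odds"]),
            conf_int=None if ci is None else pd.DataFrame.from_dict(ci, orient="index", columns=["lower", "upper"]),
            n=payload.get("n"),
            converged=payload.get("converged", True),
            log_likelihood=payload.get("log_likelihood"),
            seed=payload.get("seed"),
        )


def encode_frame(records: pd.DataFrame, charlson_band: Optional[pd.Series] = None) -> pd.DataFrame:
    """Encode discharge records into the fixed 24-column design matrix.

    ``records`` needs columns ``mdc10``, ``sex``, ``age_band``, the four
    admission flags, ``ps_grade`` and ``fhj_class``; the Charlson band comes
    either from a ``charlson_band`` column or the like-named argument.
    """
    if charlson_band is None:
        if "charlson_band" not in records.columns:
            raise ValueError("charlson_band column or argument required")
        charlson_band = records["charlson_band"]

    mdc = records["mdc10"]
    unknown = set(pd.unique(mdc)) - set(MDC10_LABELS)
    if unknown:
        raise ValueError(
            f"unknown MDC label(s) {sorted(unknown)}; expected one of {list(MDC10_LABELS)}"
        )
    age = pd.to_numeric(records["age_band"])
    if age.min() < 0 or age.max() > 5:
        raise ValueError("age_band must lie in 0..5")

    X = pd.DataFrame(index=records.index, dtype=float)
    for label in MDC10_LABELS:
        if label != MDC_REFERENCE:
            X[f"mdc_{label}"] = (mdc == label).astype(float)
    X["male"] = (records["sex"] == "male").astype(float)
    X["age_ordinal"] = age.astype(float)
    for band_label, col in CHARLSON_BAND_COLUMNS.items():
        X[col] = (charlson_band == band_label).astype(float)
    for flag in ADMISSION_FLAGS:
        X[flag] = records[flag].astype(bool).astype(float)
    for grade in ("grade2", "grade3", "grade4"):
        X[f"ps_{grade}"] = (records["ps_grade"] == grade).astype(float)
    for klass in ("class3_4", "class5"):
        X[f"fhj_{klass}"] = (records["fhj_class"] == klass).astype(float)
    return X[list(COEFFICIENT_NAMES)]


def encode(record, charlson) -> pd.Series:
    """Encode a single discharge record (see :func:`encode_frame`).

    ``record`` may be a mapping/Series or a ``DischargeRecord``; ``charlson``
    a ``CharlsonResult`` or a band label.
    """
    if hasattr(record, "to_mapping"):
        record = record.to_mapping()
    band = getattr(charlson, "band", charlson)
    frame = pd.DataFrame([dict(record)])
    return encode_frame(frame, charlson_band=pd.Series([band])).iloc[0]


def split(
    records: pd.DataFrame,
    fraction: float = 0.5,
    seed: Optional[int] = None,
    method: str = "bernoulli",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition records into (development, validation) halves.

    ``bernoulli`` assigns each record independently with probability
    ``fraction`` to the development half (an *approximate* split);
    ``exact`` permutes and cuts at ``round(fraction * n)``.
    """
    n = len(records)
    if n < 2:
        raise ValueError("need at least 2 records to split")
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    if method == "bernoulli":
        mask = rng.random(n) < fraction
    elif method == "exact":
        mask = np.zeros(n, dtype=bool)
        mask[rng.permutation(n)[: round(fraction * n)]] = True
    else:
        raise ValueError(f"unknown split method {method!r}")
    return records.iloc[mask.nonzero()[0]], records.iloc[(~mask).nonzero()[0]]


def fit(
    design: pd.DataFrame,
    outcomes: Sequence,
    maxiter: int = 100,
) -> ModelCoefficients:
    """Maximum-likelihood logistic fit of death on the design matrix.

    Raises :class:`PerfectSeparationError` naming the offending column when
    some column perfectly separates deaths from survivors, and ``ValueError``
    for single-class outcomes or constant columns.
    """
    y = np.asarray(outcomes, dtype=float)
    if len(y) != len(design):
        raise ValueError("design and outcomes differ in length")
    n_dead = int(y.sum())
    if n_dead == 0 or n_dead == len(y):
        raise ValueError("both outcome classes must be present to fit")
    nunique = design.nunique()
    constant = list(nunique.index[nunique <= 1])
    if constant:
        raise ValueError(f"constant design column(s): {constant}")
    sep = _separating_columns(design, y)
    if sep:
        raise PerfectSeparationError(
            f"column(s) perfectly separate the outcome: {sep}"
        )

    X = sm.add_constant(design, prepend=True, has_constant="raise")
    model = sm.Logit(y, X)
    try:
        res = model.fit(disp=0, maxiter=maxiter)
    except Exception as exc:  # statsmodels raises on hopeless separation
        if "erfect" in str(exc):
            raise PerfectSeparationError(str(exc)) from exc
        raise
    if not res.mle_retvals.get("converged", False):
        raise RuntimeError(
            "logistic fit did not converge: "
            f"iterations={res.mle_retvals.get('iterations')}, "
            f"gopt={res.mle_retvals.get('gopt')}"
        )
    params = pd.Series(np.asarray(res.params), index=X.columns)
    ci = pd.DataFrame(np.asarray(res.conf_int()), index=X.columns, columns=["lower", "upper"])
    bse = pd.Series(np.asarray(res.bse), index=X.columns)
    return ModelCoefficients(
        intercept=float(params["const"]),
        values=params.drop("const"),
        conf_int=ci.drop("const"),
        n=len(y),
        converged=True,
        log_likelihood=float(res.llf),
        standard_errors=bse.drop("const"),
    )


def _separating_columns(design: pd.DataFrame, y: np.ndarray) -> list[str]:
    """Binary columns whose active level contains only deaths or survivors."""
    out = []
    dead = y == 1
    for col in design.columns:
        v = design[col].to_numpy()
        if set(np.unique(v)) <= {0.0, 1.0}:
            active = v == 1
            if active.any() and (dead[active].all() or not dead[active].any()):
                out.append(col)
    return out


def predict_risk(coefficients: ModelCoefficients, design) -> np.ndarray:
    """Inverse-logit of intercept + design · coefficients.

    ``design`` is a DataFrame (columns must match the coefficient names) or a
    single encoded Series; returns probabilities in (0, 1).
    """
    if coefficients.intercept is None:
        raise ValueError("model has no intercept; calibrate or fit first")
    if isinstance(design, pd.Series):
        design = design.to_frame().T
    extra = set(design.columns) - set(coefficients.values.index)
    missing = set(coefficients.values.index) - set(design.columns)
    if extra or missing:
        raise ValueError(
            f"design/coefficient name mismatch: missing={sorted(missing)}, extra={sorted(extra)}"
        )
    X = design[list(coefficients.values.index)].to_numpy(dtype=float)
    lp = coefficients.intercept + X @ coefficients.values.to_numpy()
    return expit(lp)
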