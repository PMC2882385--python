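"""Comparison of hospital characteristics between model-fit groups.

After hospitals are split at the c-index cutoff, continuous characteristics
(admission volume, mortality rates, case-mix and demographic shares) are
compared with a two-sample t-test (Welch by default) and binary hospital
flags (public, university, specialized, convalescent wards) with Fisher's
exact test.  All tests are two-sided; significance is declared at p < 0.05
per test, with no multiplicity correction.

A hospital is "specialized" when a single MDC accounts for strictly more
than half of its hospitalizations.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .risk_model import AGE_BAND_LABELS, MDC10_LABELS

__all__ = [
    "flag_specialized",
    "fisher_exact_2x2",
    "t_test_two_sample",
    "hospital_profile_table",
    "compare_groups",
]

ALPHA = 0.05


def flag_specialized(case_mix) -> bool:
    """True iff one MDC holds strictly more than half of all cases."""
    p = np.asarray(case_mix, dtype=float)
    if p.ndim != 1 or len(p) == 0 or (p < 0).any() or abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("case_mix must be a non-negative probability vector summing to 1")
    return bool(p.max() > 0.5)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 count table.

    Two-sided by summing hypergeometric probabilities no greater than the
    observed table's, the common convention.  Margins must be positive.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if not np.issubdtype(t.dtype, np.integer):
        if not np.all(t == np.floor(t)):
            raise ValueError("counts must be integers")
        t = t.astype(int)
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("all margins must be positive")
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def t_test_two_sample(x, y, equal_var: bool = False) -> float:
    """Two-sided two-sample t-test p-value (Welch/Satterthwaite by default)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in input")
    return float(stats.ttest_ind(x, y, equal_var=equal_var).pvalue)


def hospital_profile_table(
    records: pd.DataFrame,
    metadata: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Per-hospital covariate shares and flags, shaped for group comparison.

    Computes, per hospital: MDC shares, age-band shares, male share and
    admission-status shares from the discharge records, plus the
    ``specialized`` flag from the observed case distribution (single MDC
    > 50% of cases).  ``metadata`` (e.g. from the generator) may contribute
    ``public``, ``university`` and ``convalescent`` flags.
    """
    g = records.groupby("hospital_id", sort=True)
    prof = pd.DataFrame(index=g.size().index)
    prof["n_admissions"] = g.size()
    for m in MDC10_LABELS:
        prof[f"share_mdc_{m}"] = g["mdc10"].apply(lambda s, m=m: (s == m).mean())
    for i, label in enumerate(AGE_BAND_LABELS):
        prof[f"share_age_{label}"] = g["age_band"].apply(lambda s, i=i: (s == i).mean())
    prof["share_male"] = g["sex"].apply(lambda s: (s == "male").mean())
    for flag in ("emergency", "ambulance", "exam_hospitalization", "planned_short"):
        prof[f"share_{flag}"] = g[flag].mean()
    mdc_share_cols = [f"share_mdc_{m}" for m in MDC10_LABELS]
    prof["specialized"] = prof[mdc_share_cols].max(axis=1) > 0.5
    if metadata is not None:
        for col in ("public", "university", "convalescent"):
            if col in metadata.columns:
                prof[col] = metadata[col].reindex(prof.index).astype(bool)
    return prof


def compare_groups(
    benchmarks: pd.DataFrame,
    profiles: pd.DataFrame,
    continuous: Optional[Sequence[str]] = None,
    binary: Optional[Sequence[str]] = None,
    equal_var: bool = False,
) -> pd.DataFrame:
    """High-fit vs low-fit hospital characteristics report.

    ``benchmarks`` must carry a ``group`` column (see
    :func:`casemix.benchmarking.classify_by_cindex`); excluded hospitals are
    dropped.  Continuous characteristics get group means/SDs and a t-test p;
    binary flags get counts/proportions and a Fisher exact p.  Defaults
    compare every benchmark rate, every ``share_*`` profile column, and every
    available flag.
    """
    merged = benchmarks.join(profiles.drop(columns=[c for c in profiles.columns if c in benchmarks.columns]))
    if "group" not in merged.columns:
        raise ValueError("benchmarks must carry a 'group' column")
    merged = merged[merged["group"].isin(["high", "low"])]
    high = merged[merged["group"] == "high"]
    low = merged[merged["group"] == "low"]
    if len(high) == 0 or len(low) == 0:
        raise ValueError(
            f"both groups must be non-empty (high={len(high)}, low={len(low)})"
        )
    if continuous is None:
        base = ["c_index", "n_admissions", "observed_rate", "expected_rate", "standardized_rate"]
        continuous = base + [c for c in profiles.columns if c.startswith("share_")]
    if binary is None:
        binary = [c for c in ("public", "university", "specialized", "convalescent") if c in merged.columns]

    rows = []
    for name in continuous:
        x, y = high[name].to_numpy(float), low[name].to_numpy(float)
        p = t_test_two_sample(x, y, equal_var=equal_var)
        rows.append(
            {
                "characteristic": name,
                "test": "t",
                "high_mean": x.mean(),
                "high_sd": x.std(ddof=1),
                "low_mean": y.mean(),
                "low_sd": y.std(ddof=1),
                "p_value": p,
                "significant": p < ALPHA,
            }
        )
    for name in binary:
        a = int(high[name].sum())
        b = int(low[name].sum())
        table = [[a, len(high) - a], [b, len(low) - b]]
        try:
            p = fisher_exact_2x2(table)
        except ValueError:  # a zero margin (flag absent or universal)
            p = np.nan
        rows.append(
            {
                "characteristic": name,
                "test": "fisher",
                "high_mean": a / len(high),
                "high_sd": np.nan,
                "low_mean": b / len(low),
                "low_sd": np.nan,
                "p_value": p,
                "significant": p < ALPHA,
            }
        )
    return pd.DataFrame(rows)
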