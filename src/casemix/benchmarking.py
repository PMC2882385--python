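"""Hospital-level performance measures built on the case-mix model.

For each hospital: observed mortality, expected mortality (mean predicted
risk), the standardized mortality ratio SMR = observed / expected, the
standardized mortality rate SMR x overall mean mortality, and a per-hospital
c-index where both outcome classes occur.  Hospitals are grouped at a
c-index cutoff (0.8 by default; >= is the high-fit group), binned by average
predicted risk for observed/expected (OE) ratio tables, and cross-tabulated
by raw-rate vs standardized-rate quartiles to quantify how much risk
adjustment reclassifies hospital rankings.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .validation import CIndexUndefinedError, c_index

__all__ = [
    "HOSPITAL_COLUMNS",
    "ReclassificationMatrix",
    "summarize_hospitals",
    "classify_by_cindex",
    "oe_table",
    "quartile_matrix",
    "expected_observed_correlation",
    "DEFAULT_OE_BIN_EDGES",
]

HOSPITAL_COLUMNS = (
    "n_admissions",
    "deaths",
    "observed_rate",
    "expected_rate",
    "smr",
    "standardized_rate",
    "c_index",
)

#: Expected-mortality bin edges for the OE table, in percent.
DEFAULT_OE_BIN_EDGES = (2.0, 2.5, 3.0, 3.5, 4.0, 4.5, 5.0, 5.5, 6.0)


def summarize_hospitals(hospital_ids, predictions, outcomes) -> pd.DataFrame:
    """One benchmark row per hospital.

    ``hospital_ids`` may be a Series/array aligned with ``predictions`` and
    ``outcomes``, or a records DataFrame carrying a ``hospital_id`` column.
    The overall mean mortality used for standardized rates is computed over
    all supplied records.
    """
    if isinstance(hospital_ids, pd.DataFrame):
        hospital_ids = hospital_ids["hospital_id"]
    df = pd.DataFrame(
        {
            "hospital_id": np.asarray(hospital_ids),
            "prediction": np.asarray(predictions, dtype=float),
            "died": np.asarray(outcomes, dtype=bool),
        }
    )
    overall = df["died"].mean()
    rows = []
    for hid, grp in df.groupby("hospital_id", sort=True):
        n = len(grp)
        deaths = int(grp["died"].sum())
        expected = float(grp["prediction"].mean())
        if expected <= 0:
            raise ValueError(f"hospital {hid}: expected rate is zero, SMR undefined")
        observed = deaths / n
        smr = observed / expected
        try:
            ci = c_index(grp["prediction"].to_numpy(), grp["died"].to_numpy())
        except CIndexUndefinedError:
            ci = np.nan
        rows.append(
            {
                "hospital_id": hid,
                "n_admissions": n,
                "deaths": deaths,
                "observed_rate": observed,
                "expected_rate": expected,
                "smr": smr,
                "standardized_rate": smr * overall,
                "c_index": ci,
            }
        )
    out = pd.DataFrame(rows).set_index("hospital_id")
    out.attrs["overall_mortality"] = float(overall)
    return out


def classify_by_cindex(
    benchmarks: pd.DataFrame, cutoff: float = 0.8
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Label hospitals high (c-index >= cutoff) / low (< cutoff) / excluded.

    Hospitals whose c-index is undefined (zero deaths or zero survivors) are
    excluded.  Returns ``(labelled benchmarks, group summary)`` where the
    summary holds per-group hospital counts and mean c-index with a normal
    95% CI of the mean across hospitals.
    """
    out = benchmarks.copy()
    out["group"] = np.where(out["c_index"] >= cutoff, "high", "low")
    out.loc[out["c_index"].isna(), "group"] = "excluded"
    rows = []
    for name in ("high", "low"):
        vals = out.loc[out["group"] == name, "c_index"].to_numpy()
        if len(vals) == 0:
            rows.append({"group": name, "n_hospitals": 0, "mean_c_index": np.nan,
                         "ci_lower": np.nan, "ci_upper": np.nan})
            continue
        mean = float(vals.mean())
        se = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
        rows.append(
            {
                "group": name,
                "n_hospitals": len(vals),
                "mean_c_index": mean,
                "ci_lower": mean - 1.96 * se,
                "ci_upper": mean + 1.96 * se,
            }
        )
    rows.append(
        {
            "group": "excluded",
            "n_hospitals": int((out["group"] == "excluded").sum()),
            "mean_c_index": np.nan,
            "ci_lower": np.nan,
            "ci_upper": np.nan,
        }
    )
    return out, pd.DataFrame(rows).set_index("group")


def oe_table(
    benchmarks: pd.DataFrame,
    bin_edges_percent: Sequence[float] = DEFAULT_OE_BIN_EDGES,
) -> pd.DataFrame:
    """Average OE (observed/expected) ratio by hospital expected-risk bin.

    Bins are ``[lower, upper)`` on the expected rate in percent, with open
    first ("Under x%") and last ("x% and over") bins.  The 95% CI is the
    t-based interval for the mean OE across hospitals in the bin; bins with
    fewer than two hospitals get undefined statistics.
    """
    if len(benchmarks) == 0:
        raise ValueError("benchmarks must be non-empty")
    edges = list(bin_edges_percent)
    if edges != sorted(edges):
        raise ValueError("bin edges must be increasing")
    pct = benchmarks["expected_rate"].to_numpy() * 100.0
    bin_idx = np.searchsorted(edges, pct, side="right")
    labels = (
        [f"Under {edges[0]:.1f}%"]
        + [f"{lo:.1f}-{hi:.1f}%" for lo, hi in zip(edges[:-1], edges[1:])]
        + [f"{edges[-1]:.1f}% and over"]
    )
    rows = []
    for i, label in enumerate(labels):
        oe = benchmarks["smr"].to_numpy()[bin_idx == i]
        n = len(oe)
        if n == 0:
            rows.append({"risk_bin": label, "n_hospitals": 0, "mean_oe": np.nan,
                         "ci_lower": np.nan, "ci_upper": np.nan})
            continue
        mean = float(oe.mean())
        if n >= 2:
            half = float(stats.t.ppf(0.975, n - 1) * oe.std(ddof=1) / np.sqrt(n))
            lo, hi = mean - half, mean + half
        else:
            lo = hi = np.nan
        rows.append({"risk_bin": label, "n_hospitals": n, "mean_oe": mean,
                     "ci_lower": lo, "ci_upper": hi})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ReclassificationMatrix:
    """4x4 raw-rate x standardized-rate quartile cross-tabulation."""

    counts: np.ndarray  # rows: raw-rate quartile, cols: standardized-rate quartile
    raw_cuts: Optional[tuple] = None
    standardized_cuts: Optional[tuple] = None

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        if counts.shape != (4, 4) or (counts < 0).any():
            raise ValueError("counts must be a non-negative 4x4 matrix")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def off_diagonal_count(self) -> int:
        return self.total - int(np.trace(self.counts))

    @property
    def off_diagonal_percent(self) -> float:
        return 100.0 * self.off_diagonal_count / self.total

    @classmethod
    def from_counts(cls, counts) -> "ReclassificationMatrix":
        """Summarize an externally tabulated 4x4 quartile matrix."""
        return cls(counts=np.asarray(counts, dtype=int))

    def to_frame(self) -> pd.DataFrame:
        idx = [f"raw_q{i}" for i in range(1, 5)]
        cols = [f"std_q{i}" for i in range(1, 5)]
        return pd.DataFrame(self.counts, index=idx, columns=cols)


def _quartile_assign(values: np.ndarray) -> tuple[np.ndarray, tuple]:
    """Left-closed/right-open quartiles: value == cut joins the upper one."""
    cuts = np.percentile(values, [25, 50, 75])
    return np.searchsorted(cuts, values, side="right"), tuple(float(c) for c in cuts)


def quartile_matrix(benchmarks: pd.DataFrame) -> ReclassificationMatrix:
    """Cross-tabulate raw-rate vs standardized-rate hospital quartiles."""
    if len(benchmarks) < 4:
        raise ValueError("need at least 4 hospitals for quartiles")
    raw_q, raw_cuts = _quartile_assign(benchmarks["observed_rate"].to_numpy())
    std_q, std_cuts = _quartile_assign(benchmarks["standardized_rate"].to_numpy())
    counts = np.zeros((4, 4), dtype=int)
    np.add.at(counts, (raw_q, std_q), 1)
    return ReclassificationMatrix(counts=counts, raw_cuts=raw_cuts, standardized_cuts=std_cuts)


def expected_observed_correlation(benchmarks: pd.DataFrame) -> tuple[float, float]:
    """Pearson r (with two-sided p) between hospital expected and observed rates."""
    x = benchmarks["expected_rate"].to_numpy()
    y = benchmarks["observed_rate"].to_numpy()
    if len(x) < 3:
        raise ValueError("need at least 3 hospitals")
    if np.isclose(x.std(), 0) or np.isclose(y.std(), 0):
        raise ValueError("zero variance in expected or observed rates")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def plot_expected_observed(benchmarks: pd.DataFrame, path=None):
    """Scatter of expected vs observed hospital mortality, by fit group."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5.5, 5.5))
    groups = benchmarks["group"] if "group" in benchmarks.columns else pd.Series("high", index=benchmarks.index)
    for name, marker, color in (("high", "o", "#1f77b4"), ("low", "^", "#d62728")):
        sub = benchmarks[groups == name]
        if len(sub):
            ax.scatter(sub["expected_rate"] * 100, sub["observed_rate"] * 100,
                       s=18, marker=marker, alpha=0.7, color=color, label=f"{name} c-index")
    lim = max(ax.get_xlim()[1], ax.get_ylim()[1])
    ax.plot([0, lim], [0, lim], lw=0.8, color="grey")
    ax.set_xlabel("expected mortality rate (%)")
    ax.set_ylabel("observed mortality rate (%)")
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
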