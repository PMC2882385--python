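"""Model discrimination and calibration on held-out records.

Discrimination is the c-index (concordance): the probability that a randomly
chosen death received a higher predicted risk than a randomly chosen
survivor, with tied predictions counted 1/2.  Calibration is assessed by
partitioning records into ten near-equal groups by ascending predicted risk
and comparing mean predicted risk with the observed death rate (Wilson 95%
interval) per decile.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from statsmodels.stats.proportion import proportion_confint

__all__ = ["CIndexUndefinedError", "c_index", "decile_calibration", "binomial_ci"]


class CIndexUndefinedError(ValueError):
    """The c-index is undefined because only one outcome class is present.

    This is the condition that forces the zero-mortality hospital exclusion
    in the benchmarking stage.
    """


def c_index(predictions, outcomes) -> float:
    """Concordance index via midranks, O(n log n).

    Equals the brute-force count over all death-survivor pairs with ties
    contributing 1/2 (standard AUC convention).
    """
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(outcomes, dtype=bool)
    if p.shape != y.shape or p.ndim != 1:
        raise ValueError("predictions and outcomes must be equal-length 1-D arrays")
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise CIndexUndefinedError(
            f"c-index undefined with {n1} deaths and {n0} survivors"
        )
    ranks = rankdata(p)  # midranks handle ties
    return float((ranks[y].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def binomial_ci(deaths: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= deaths <= n:
        raise ValueError(f"deaths must lie in 0..{n}, got {deaths}")
    lower, upper = proportion_confint(deaths, n, alpha=alpha, method="wilson")
    return float(lower), float(upper)


def decile_calibration(predictions, outcomes, n_bins: int = 10) -> pd.DataFrame:
    """Predicted-vs-observed mortality by risk decile.

    Records are stably sorted by predicted risk and cut into ``n_bins``
    near-equal groups (records with identical predictions may straddle
    adjacent groups).  Returns one row per decile with columns
    ``decile, n, deaths, mean_predicted, observed_rate, ci_lower, ci_upper``.
    """
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(outcomes, dtype=bool)
    if len(p) != len(y):
        raise ValueError("predictions and outcomes must be equal length")
    if len(p) < n_bins:
        raise ValueError(f"need at least {n_bins} records, got {len(p)}")
    order = np.argsort(p, kind="stable")
    rows = []
    for i, idx in enumerate(np.array_split(order, n_bins), start=1):
        deaths = int(y[idx].sum())
        n = len(idx)
        lo, hi = binomial_ci(deaths, n)
        rows.append(
            {
                "decile": i,
                "n": n,
                "deaths": deaths,
                "mean_predicted": float(p[idx].mean()),
                "observed_rate": deaths / n,
                "ci_lower": lo,
                "ci_upper": hi,
            }
        )
    return pd.DataFrame(rows)


def plot_calibration(table: pd.DataFrame, path=None):
    """Bar (predicted) and point-with-CI (observed) calibration display."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4.5))
    x = table["decile"].to_numpy()
    ax.bar(x, table["mean_predicted"], width=0.7, color="#b5c7e7", label="predicted")
    yerr = np.vstack(
        [
            table["observed_rate"] - table["ci_lower"],
            table["ci_upper"] - table["observed_rate"],
        ]
    )
    ax.errorbar(
        x, table["observed_rate"], yerr=yerr, fmt="s", color="#333333",
        capsize=3, label="observed (95% CI)",
    )
    ax.set_xlabel("predicted mortality risk decile")
    ax.set_ylabel("mortality rate")
    ax.set_xticks(x)
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
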