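"""Two-group comparison statistics for the monitored cohort.

Implements the comparison layer of the study design: descriptive summaries
(mean ± SD for approximately normal variables, median and IQR otherwise),
the equal-variance two-sample t-test (computable from printed summary
statistics alone, which is how published tables are re-derived), the
Mann–Whitney U test with tie-corrected normal approximation, and the
uncorrected Pearson chi-square for 2×2 counts. ``build_table1`` assembles
the full baseline-comparison table for a cohort, with the per-variable test
assignment made explicit in configuration rather than inferred.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupSummary",
    "TTestResult",
    "MannWhitneyResult",
    "ChiSquareResult",
    "CohortComparison",
    "DegenerateVarianceError",
    "describe",
    "pooled_t",
    "pooled_t_raw",
    "mann_whitney",
    "chi_square_2x2",
    "DEFAULT_TESTS",
    "TABLE1_ORDER",
    "build_table1",
    "comparisons_to_frame",
    "format_report",
]


class DegenerateVarianceError(ValueError):
    """Both groups have zero variance; the t statistic is undefined."""


@dataclass
class GroupSummary:
    """Descriptive summary of one group for one variable."""

    n: int
    mean: float
    sd: float
    median: float
    iqr: float


@dataclass
class TTestResult:
    statistic: float
    df: int
    p_value: float


@dataclass
class MannWhitneyResult:
    """Mann–Whitney U. ``u_less`` counts pairs with sample1 < sample2 (ties
    half), ``u_greater`` = n1·n2 − u_less; ``u`` is the smaller of the two,
    the value conventionally reported."""

    u_less: float
    u_greater: float
    u: float
    p_value: float


@dataclass
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float


@dataclass
class CohortComparison:
    """One row of the baseline-comparison table."""

    variable: str
    good: Optional[GroupSummary]
    poor: Optional[GroupSummary]
    test: str
    statistic: float
    df: Optional[int]
    p_value: float


def describe(sample: Sequence[float]) -> GroupSummary:
    """Mean/SD (n−1 denominator) and median/IQR (linear-interpolation
    quartiles) of a sample of at least two values."""
    x = np.asarray(sample, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 observations to summarise a group")
    q1, q3 = np.percentile(x, [25.0, 75.0])
    return GroupSummary(
        n=int(x.size),
        mean=float(x.mean()),
        sd=float(x.std(ddof=1)),
        median=float(np.median(x)),
        iqr=float(q3 - q1),
    )


def pooled_t(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> TTestResult:
    """Equal-variance two-sample t-test from group summaries.

    This is the form that reproduces published t statistics from a table's
    mean ± SD columns. df = n1 + n2 − 2; two-sided p.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    if sd1 == 0 and sd2 == 0:
        raise DegenerateVarianceError("both groups have zero variance")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    t = (mean1 - mean2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * stats.t.sf(abs(t), df)
    return TTestResult(statistic=float(t), df=int(df), p_value=float(p))


def pooled_t_raw(sample1: Sequence[float], sample2: Sequence[float]) -> TTestResult:
    """Equal-variance t-test on raw samples (identical to the summary form)."""
    s1, s2 = describe(sample1), describe(sample2)
    return pooled_t(s1.mean, s1.sd, s1.n, s2.mean, s2.sd, s2.n)


def mann_whitney(sample1: Sequence[float], sample2: Sequence[float]) -> MannWhitneyResult:
    """Mann–Whitney U test, two-sided.

    p uses the normal approximation with tie-corrected variance and a
    continuity correction of 1/2, applied to the smaller U. With every pair
    tied the test is uninformative and p = 1.
    """
    x = np.asarray(sample1, dtype=float)
    y = np.asarray(sample2, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    r1 = ranks[:n1].sum()
    u_greater = r1 - n1 * (n1 + 1) / 2.0  # pairs with x > y, ties half
    u_less = n1 * n2 - u_greater
    u = min(u_less, u_greater)

    n = n1 + n2
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))) if n > 1 else 0.0
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        p = 1.0
    else:
        mu = n1 * n2 / 2.0
        z = (u - mu + 0.5) / np.sqrt(sigma2)
        p = min(1.0, 2.0 * stats.norm.cdf(z))
    return MannWhitneyResult(
        u_less=float(u_less), u_greater=float(u_greater), u=float(u), p_value=float(p)
    )


def chi_square_2x2(table) -> ChiSquareResult:
    """Pearson chi-square on a 2×2 count table, without continuity correction."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    if (t.sum(axis=0) <= 0).any() or (t.sum(axis=1) <= 0).any():
        raise ValueError("every row and column marginal must be positive")
    chi2, p, dof, _ = stats.chi2_contingency(t, correction=False)
    return ChiSquareResult(statistic=float(chi2), df=int(dof), p_value=float(p))


# Per-variable test assignment of the baseline table, in its published order.
DEFAULT_TESTS: dict[str, str] = {
    "age": "pooled_t",
    "sex": "chi_square",
    "gcs": "mann_whitney",
    "hematoma_ml": "pooled_t",
    "mean_icp": "pooled_t",
    "prx": "pooled_t",
    "rap": "pooled_t",
    "cpp": "pooled_t",
    "dicp": "mann_whitney",
}
TABLE1_ORDER = list(DEFAULT_TESTS)

_KNOWN_TESTS = {"pooled_t", "mann_whitney", "chi_square"}


def build_table1(
    patients: pd.DataFrame, tests: Optional[dict[str, str]] = None
) -> list[CohortComparison]:
    """Baseline-comparison table for a cohort.

    ``patients`` holds one row per patient with a ``group`` column
    (``good``/``poor``) plus the variables named in ``tests`` (default: age,
    sex, GCS, hematoma volume and the five patient-level monitoring
    indices). Rows with a missing value for a variable are dropped from that
    variable's comparison only.
    """
    tests = dict(tests) if tests is not None else dict(DEFAULT_TESTS)
    for var, test in tests.items():
        if test not in _KNOWN_TESTS:
            raise ValueError(f"unknown test '{test}' for variable '{var}'")
        if var not in patients.columns:
            raise ValueError(f"unknown variable '{var}': not a column of the patient table")
    if "group" not in patients.columns:
        raise ValueError("patient table needs a 'group' column")
    good = patients[patients["group"] == "good"]
    poor = patients[patients["group"] == "poor"]
    if good.empty or poor.empty:
        raise ValueError("both prognosis groups must be non-empty")

    out: list[CohortComparison] = []
    for var, test in tests.items():
        if test == "chi_square":
            counts = []
            for grp in (poor, good):
                male = int((grp[var] == "M").sum())
                counts.append([male, len(grp) - male])
            res = chi_square_2x2(counts)
            out.append(
                CohortComparison(var, None, None, test, res.statistic, res.df, res.p_value)
            )
            continue
        g = good[var].dropna().to_numpy(dtype=float)
        p_ = poor[var].dropna().to_numpy(dtype=float)
        sg, sp_ = describe(g), describe(p_)
        if test == "pooled_t":
            res_t = pooled_t(sp_.mean, sp_.sd, sp_.n, sg.mean, sg.sd, sg.n)
            out.append(
                CohortComparison(var, sg, sp_, test, res_t.statistic, res_t.df, res_t.p_value)
            )
        else:
            res_u = mann_whitney(p_, g)
            out.append(CohortComparison(var, sg, sp_, test, res_u.u, None, res_u.p_value))
    return out


def comparisons_to_frame(comparisons: Sequence[CohortComparison]) -> pd.DataFrame:
    rows = []
    for c in comparisons:
        rows.append(
            {
                "variable": c.variable,
                "n_good": c.good.n if c.good else None,
                "n_poor": c.poor.n if c.poor else None,
                "good_mean": c.good.mean if c.good else None,
                "good_sd": c.good.sd if c.good else None,
                "good_median": c.good.median if c.good else None,
                "good_iqr": c.good.iqr if c.good else None,
                "poor_mean": c.poor.mean if c.poor else None,
                "poor_sd": c.poor.sd if c.poor else None,
                "poor_median": c.poor.median if c.poor else None,
                "poor_iqr": c.poor.iqr if c.poor else None,
                "test": c.test,
                "statistic": c.statistic,
                "df": c.df,
                "p_value": c.p_value,
            }
        )
    return pd.DataFrame(rows)


_SYMBOL = {"pooled_t": "t", "mann_whitney": "U", "chi_square": "chi2"}


def format_report(comparisons: Sequence[CohortComparison]) -> str:
    """Human-readable baseline-comparison table."""
    lines = [
        f"{'variable':<14}{'poor group':>22}{'good group':>22}{'test':>14}{'p':>10}",
        "-" * 82,
    ]
    for c in comparisons:
        if c.test == "chi_square":
            poor_s = good_s = "(counts)"
        elif c.test == "mann_whitney":
            poor_s = f"{c.poor.median:.2f} ({c.poor.iqr:.2f})"
            good_s = f"{c.good.median:.2f} ({c.good.iqr:.2f})"
        else:
            poor_s = f"{c.poor.mean:.2f} +/- {c.poor.sd:.2f}"
            good_s = f"{c.good.mean:.2f} +/- {c.good.sd:.2f}"
        stat = f"{_SYMBOL[c.test]} = {c.statistic:.3f}"
        p = "<0.001" if c.p_value < 0.001 else f"{c.p_value:.3f}"
        lines.append(f"{c.variable:<14}{poor_s:>22}{good_s:>22}{stat:>14}{p:>10}")
    return "\n".join(lines)
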