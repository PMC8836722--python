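"""ROC evaluation of patient-level indices as prognosis predictors.

Each index is scored against the binary outcome "poor prognosis". The
orientation of every predictor is declared explicitly (mean ICP, PRx, RAP
and DICP predict poor outcome when high; CPP when low) and is never
auto-flipped — an anti-predictive index is reported with AUC < 0.5 rather
than silently inverted. Confidence intervals for the AUC are available by
DeLong's covariance method (default) or the Hanley–McNeil variance formula.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "ROCResult",
    "DEFAULT_DIRECTIONS",
    "roc_curve",
    "auc",
    "auc_ci",
    "rank_predictors",
    "roc_summary_frame",
]

logger = logging.getLogger(__name__)

HIGHER_IS_POOR = "higher_is_poor"
LOWER_IS_POOR = "lower_is_poor"

# Published orientation of the five indices against poor outcome.
DEFAULT_DIRECTIONS: dict[str, str] = {
    "mean_icp": HIGHER_IS_POOR,
    "prx": HIGHER_IS_POOR,
    "rap": HIGHER_IS_POOR,
    "dicp": HIGHER_IS_POOR,
    "cpp": LOWER_IS_POOR,
}


@dataclass
class ROCResult:
    """Empirical ROC curve and AUC for one predictor.

    ``thresholds`` are on the original variable scale; ``scores`` and
    ``labels`` keep the oriented data so confidence intervals can be
    computed afterwards.
    """

    variable: str
    direction: str
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    ci_method: Optional[str] = None
    scores: np.ndarray = field(default_factory=lambda: np.empty(0))
    labels: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=bool))


def roc_curve(
    scores: Sequence[float],
    labels: Sequence[bool],
    direction: str = HIGHER_IS_POOR,
    variable: str = "",
) -> ROCResult:
    """Empirical ROC curve over all distinct score thresholds.

    ``labels`` are True for the positive class (poor prognosis). Scores are
    oriented so that higher predicts poor; the curve includes the (0,0) and
    (1,1) endpoints, and the AUC is the trapezoidal area (equal to the
    normalised Mann–Whitney statistic with ties counted half).
    """
    if direction not in (HIGHER_IS_POOR, LOWER_IS_POOR):
        raise ValueError(f"unknown direction '{direction}'")
    y = np.asarray(labels, dtype=bool)
    s = np.asarray(scores, dtype=float)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have the same length")
    if y.all() or not y.any():
        raise ValueError("both outcome classes must be present")
    oriented = s if direction == HIGHER_IS_POOR else -s
    fpr, tpr, thr = _sk_roc_curve(y.astype(int), oriented, drop_intermediate=False)
    area = float(np.trapezoid(tpr, fpr))
    if area == 0.0:
        logger.warning(
            "AUC = 0 for '%s': the direction flag is likely mis-specified", variable
        )
    thresholds = thr if direction == HIGHER_IS_POOR else -thr
    return ROCResult(
        variable=variable,
        direction=direction,
        thresholds=thresholds,
        sensitivity=tpr,
        specificity=1.0 - fpr,
        auc=area,
        scores=oriented,
        labels=y,
    )


def auc(result: ROCResult) -> float:
    """Trapezoidal area under the stored curve."""
    return float(np.trapezoid(result.sensitivity, 1.0 - result.specificity))


def _delong_ci(pos: np.ndarray, neg: np.ndarray, level: float) -> tuple[float, float, float]:
    m, n = pos.size, neg.size
    psi = (pos[:, None] > neg[None, :]).astype(float)
    psi += 0.5 * (pos[:, None] == neg[None, :])
    a = psi.mean()
    v10 = psi.mean(axis=1)
    v01 = psi.mean(axis=0)
    var = v10.var(ddof=1) / m + v01.var(ddof=1) / n
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(var)
    return float(a), float(a - half), float(a + half)


def _hanley_mcneil_ci(
    pos: np.ndarray, neg: np.ndarray, level: float
) -> tuple[float, float, float]:
    m, n = pos.size, neg.size
    psi = (pos[:, None] > neg[None, :]).astype(float)
    psi += 0.5 * (pos[:, None] == neg[None, :])
    a = float(psi.mean())
    q1 = a / (2.0 - a)
    q2 = 2.0 * a**2 / (1.0 + a)
    var = (a * (1 - a) + (m - 1) * (q1 - a**2) + (n - 1) * (q2 - a**2)) / (m * n)
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(max(var, 0.0))
    return a, a - half, a + half


def auc_ci(
    result: ROCResult, method: str = "delong", level: float = 0.95
) -> tuple[float, float]:
    """Confidence interval for the AUC, truncated to [0, 1].

    ``method`` is ``"delong"`` (covariance of the placement values) or
    ``"hanley_mcneil"`` (exponential-approximation variance).
    """
    if result.scores.size == 0:
        raise ValueError("ROCResult carries no scores; recompute with roc_curve")
    pos = result.scores[result.labels]
    neg = result.scores[~result.labels]
    if pos.size < 2 or neg.size < 2:
        raise ValueError("each outcome class needs at least 2 patients for a CI")
    if method == "delong":
        _, lo, hi = _delong_ci(pos, neg, level)
    elif method == "hanley_mcneil":
        _, lo, hi = _hanley_mcneil_ci(pos, neg, level)
    else:
        raise ValueError(f"unknown CI method '{method}'")
    lo, hi = max(lo, 0.0), min(hi, 1.0)
    result.ci_low, result.ci_high, result.ci_method = lo, hi, method
    return lo, hi


def rank_predictors(
    patients: pd.DataFrame,
    directions: Optional[dict[str, str]] = None,
    ci_method: str = "delong",
    level: float = 0.95,
) -> list[ROCResult]:
    """ROC analysis of every index against poor prognosis, best AUC first.

    ``patients`` holds one row per patient with a ``group`` column and the
    index columns named in ``directions`` (default: the five monitoring
    indices with their published orientations).
    """
    directions = dict(directions) if directions is not None else dict(DEFAULT_DIRECTIONS)
    if "group" not in patients.columns:
        raise ValueError("patient table needs a 'group' column")
    results = []
    for var, direction in directions.items():
        if var not in patients.columns:
            raise KeyError(f"missing index column '{var}' in the patient table")
        sub = patients[[var, "group"]].dropna(subset=[var])
        labels = (sub["group"] == "poor").to_numpy()
        res = roc_curve(sub[var].to_numpy(dtype=float), labels, direction, variable=var)
        auc_ci(res, method=ci_method, level=level)
        results.append(res)
    return sorted(results, key=lambda r: r.auc, reverse=True)


def roc_summary_frame(results: Sequence[ROCResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "variable": r.variable,
                "direction": r.direction,
                "auc": r.auc,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "ci_method": r.ci_method,
            }
            for r in results
        ]
    )
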