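"""Univariate logistic screening of candidate ALNM risk factors.

Each clinical feature is regressed one at a time (intercept + slope)
against the binary axillary-lymph-node label on the training cohort.
The fit is maximum likelihood by iteratively reweighted least squares
(IRLS); standard errors are Wald, from the inverse observed
information; confidence intervals are symmetric on the log-odds scale
and reported as odds ratios.  Degenerate fits — zero-variance
predictors, or (quasi-)complete separation — are flagged rather than
reported as spurious numbers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .synthetic_cohort import FEATURE_COLUMNS, LABEL_COLUMN

#: two-sided 95% Wald critical value
Z_CRIT = 1.959964

#: |slope| beyond which a fit is treated as separated (log-odds scale)
SEPARATION_BETA = 15.0

#: the ten-factor candidate panel used as the pipeline's reproduction
#: default: ultrasound tumour size, tumour location, and eight binary
#: axillary-ultrasound findings.
CANDIDATE_FACTOR_PANEL = (
    "us_size", "location",
    "term1", "term2", "term3", "term4", "term5", "term6", "term7", "term9",
)


@dataclass
class ScreenResult:
    """Univariate logistic output for one feature."""

    feature: str
    coefficient: float
    std_error: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    status: str            # "converged" | "degenerate"
    selected: bool = False

    @property
    def is_degenerate(self) -> bool:
        return self.status == "degenerate"


class ScreenInputError(ValueError):
    """Raised for invalid screening inputs."""


def _log_likelihood(eta: np.ndarray, y: np.ndarray) -> float:
    # stable Bernoulli log-likelihood: sum y*eta - log(1 + e^eta)
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_univariate_logistic(x, y, max_iter: int = 100, tol: float = 1e-8,
                            return_trace: bool = False) -> ScreenResult:
    """Intercept-plus-slope logistic regression of binary `y` on `x`.

    IRLS (Newton-Raphson on the log-likelihood) until the largest
    coefficient change falls below `tol` or `max_iter` iterations.
    Degenerate inputs — constant `x`, an empty cell in the 2x2 table of
    a binary predictor, or a fitted |slope| above ``SEPARATION_BETA`` —
    yield ``status="degenerate"`` with NaN estimates.

    With `return_trace`, also returns the per-iteration log-likelihood
    sequence (diagnostic; it is non-decreasing for a well-posed fit).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ScreenInputError(f"length mismatch: x has {x.size}, y has {y.size}")
    if x.size < 2:
        raise ScreenInputError("need at least 2 observations")
    classes = np.unique(y)
    if not np.isin(classes, [0.0, 1.0]).all():
        raise ScreenInputError("y must be binary 0/1")
    if classes.size < 2:
        raise ScreenInputError("y contains a single class; logistic fit undefined")

    def degenerate():
        res = ScreenResult("", np.nan, np.nan, np.nan, np.nan, np.nan, np.nan,
                           status="degenerate")
        return (res, []) if return_trace else res

    if np.ptp(x) == 0.0:
        return degenerate()
    uniq_x = np.unique(x)
    if uniq_x.size == 2 and set(uniq_x) == {0.0, 1.0}:
        # empty cell in the 2x2 table => infinite MLE
        counts = [np.sum((x == a) & (y == b)) for a in (0, 1) for b in (0, 1)]
        if min(counts) == 0:
            return degenerate()

    X = np.column_stack([np.ones_like(x), x])
    beta = np.zeros(2)
    trace = [_log_likelihood(X @ beta, y)]
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30.0, 30.0)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        info = X.T @ (w[:, None] * X)
        try:
            step = np.linalg.solve(info, X.T @ (y - mu))
        except np.linalg.LinAlgError:
            return degenerate()
        beta = beta + step
        trace.append(_log_likelihood(X @ beta, y))
        if np.max(np.abs(step)) < tol:
            break
    if not np.isfinite(beta).all() or abs(beta[1]) > SEPARATION_BETA:
        return degenerate()

    eta = np.clip(X @ beta, -30.0, 30.0)
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    info = X.T @ (w[:, None] * X)
    cov = np.linalg.inv(info)
    se = float(np.sqrt(cov[1, 1]))
    b = float(beta[1])
    z = b / se
    res = ScreenResult(
        feature="",
        coefficient=b,
        std_error=se,
        odds_ratio=float(np.exp(b)),
        ci_low=float(np.exp(b - Z_CRIT * se)),
        ci_high=float(np.exp(b + Z_CRIT * se)),
        p_value=float(2.0 * norm.sf(abs(z))),
        status="converged",
    )
    return (res, trace) if return_trace else res


def odds_ratio_from_coefficient(beta: float) -> float:
    """Odds ratio corresponding to a log-odds coefficient: exp(beta)."""
    if not np.isfinite(beta):
        raise ScreenInputError(f"coefficient must be finite, got {beta}")
    return float(np.exp(beta))


def screen_features(table: pd.DataFrame, alpha: float = 0.05,
                    include=None) -> list[ScreenResult]:
    """Screen every feature of a cohort table against the ALN label.

    Default selection keeps convergent features with Wald p < `alpha`.
    An explicit `include` list overrides the p-value rule: exactly the
    listed features are flagged selected, regardless of significance.
    """
    missing = [c for c in FEATURE_COLUMNS if c not in table.columns]
    if missing:
        raise ScreenInputError(f"cohort table lacks feature columns: {missing}")
    if include is not None:
        unknown = [f for f in include if f not in FEATURE_COLUMNS]
        if unknown:
            raise ScreenInputError(f"unknown features in include list: {unknown}")
    y = table[LABEL_COLUMN].to_numpy()
    results = []
    for feat in FEATURE_COLUMNS:
        res = fit_univariate_logistic(table[feat].to_numpy(), y)
        res.feature = feat
        if include is not None:
            res.selected = feat in include
        else:
            res.selected = (res.status == "converged") and (res.p_value < alpha)
        results.append(res)
    return results


def screen_to_frame(results: list[ScreenResult]) -> pd.DataFrame:
    """Tabulate screen results (one row per feature, OR-scale CI bounds)."""
    return pd.DataFrame(
        [{
            "feature": r.feature,
            "coefficient": r.coefficient,
            "odds_ratio": r.odds_ratio,
            "ci_low": r.ci_low,
            "ci_high": r.ci_high,
            "p_value": r.p_value,
            "status": r.status,
            "selected": r.selected,
        } for r in results]
    )


def write_screen_csv(results: list[ScreenResult], path) -> None:
    screen_to_frame(results).to_csv(path, index=False)


def selected_features(results: list[ScreenResult]) -> list[str]:
    return [r.feature for r in results if r.selected]
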