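"""Test-set performance metrics: discrimination, calibration, classification,
and clinical utility.

* AUROC is the concordance statistic, computed by rank-sum with midranks so
  ties count 1/2 — the probability that a random event receives a higher
  prediction than a random nonevent.
* The calibration intercept is the intercept of a logistic regression of
  the outcome on the model's logit predictions entered as an offset
  (coefficient fixed at 1); negative values mean over-estimated risks.
* The calibration slope is the slope of the two-parameter logistic
  recalibration logit P(Y=1) = a' + b * LP; b < 1 means predictions that
  are too extreme.
* A flexible calibration curve smooths the observed outcome against the
  predicted risk (lowess) to show calibration conditional on the estimate.
* Classification metrics and Net Benefit are computed at a risk threshold
  ``t`` with the rule "high risk iff predicted probability >= t";
  NB = (TP - (t / (1-t)) * FP) / N weighs false positives at the odds
  implied by the threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, logit
from scipy.stats import rankdata
from statsmodels.nonparametric.smoothers_lowess import lowess

from .models import PROB_CLIP, _newton_logistic

__all__ = [
    "ThresholdMetrics",
    "PerformanceRecord",
    "CalibrationCurve",
    "auroc",
    "calibration_intercept",
    "calibration_slope",
    "flexible_calibration_curve",
    "classification_metrics",
    "net_benefit",
    "net_benefit_treat_all",
    "decision_curve",
    "evaluate",
    "DEFAULT_DECISION_THRESHOLDS",
]

DEFAULT_DECISION_THRESHOLDS = np.round(np.arange(0.05, 0.501, 0.05), 2)


@dataclass(frozen=True)
class ThresholdMetrics:
    """Classification counts, rates and Net Benefit at one risk threshold."""

    threshold: float
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float
    net_benefit: float

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class PerformanceRecord:
    """One model's full set of test-set metrics."""

    auroc: float
    cal_intercept: float
    cal_slope: float
    cal_slope_intercept: float
    thresholds: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)


@dataclass(frozen=True)
class CalibrationCurve:
    """Smoothed observed event probability against predicted probability."""

    predicted: np.ndarray
    observed: np.ndarray


def _clip(probs: np.ndarray) -> np.ndarray:
    return np.clip(np.asarray(probs, dtype=float), PROB_CLIP, 1.0 - PROB_CLIP)


def auroc(probs: np.ndarray, y: np.ndarray) -> float:
    """Concordance statistic via the rank-sum formulation with midranks.

    Returns NaN when only one class is present (the probability is then
    undefined).
    """
    probs = np.asarray(probs, dtype=float)
    y = np.asarray(y)
    n1 = int(y.sum())
    n0 = y.size - n1
    if n0 == 0 or n1 == 0:
        return float("nan")
    r = rankdata(probs)  # midranks for ties
    u = r[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n0 * n1))


def calibration_intercept(probs: np.ndarray, y: np.ndarray) -> float:
    """Intercept of logit P(Y=1) = a + LP with LP offset at coefficient 1.

    The MLE of the intercept-only offset model solves the score equation
    mean(expit(a + LP)) = mean(y), a monotone 1-D root problem.
    """
    y = np.asarray(y, dtype=float)
    if not 0.0 < y.mean() < 1.0:
        raise ValueError("both classes must be present")
    lp = logit(_clip(probs))
    ones = np.ones((lp.size, 1))
    a0 = np.array([float(logit(y.mean()) - lp.mean())])
    beta, converged = _newton_logistic(
        ones, y, lam=0.0, beta0=a0, offset=lp, tol=1e-10
    )
    if converged:
        return float(beta[0])
    # fall back to bracketing on the monotone score equation

    def score(a: float) -> float:
        return float(np.mean(expit(a + lp)) - y.mean())

    return float(optimize.brentq(score, -60.0, 60.0, xtol=1e-12))


def calibration_slope(
    probs: np.ndarray, y: np.ndarray
) -> tuple[float, float]:
    """Two-parameter logistic recalibration logit P(Y=1) = a' + b * LP.

    Returns ``(a_prime, b)``.  Fit by Newton iterations with step-halving.
    Degenerate (constant) logits leave the slope undefined: (nan, nan).
    """
    y = np.asarray(y, dtype=float)
    lp = logit(_clip(probs))
    if np.ptp(lp) < 1e-12:
        return (float("nan"), float("nan"))
    X = np.column_stack([np.ones_like(lp), lp])
    b0 = np.array([float(logit(y.mean()) - lp.mean()), 1.0])
    beta, converged = _newton_logistic(
        X, y, lam=0.0, beta0=b0, maxiter=100, tol=1e-10
    )
    if not converged:
        return (float("nan"), float("nan"))
    return (float(beta[0]), float(beta[1]))


def flexible_calibration_curve(
    probs: np.ndarray,
    y: np.ndarray,
    span: float = 0.75,
    grid_size: int = 100,
) -> CalibrationCurve | None:
    """Lowess-smoothed observed event probability against predicted risk.

    The outcome is smoothed against the logit of the prediction (span =
    lowess fraction) and the smooth is read off on an evenly spaced grid of
    predicted probabilities covering the observed range.  Returns ``None``
    with a warning when there are fewer than 50 observations.
    """
    probs = _clip(probs)
    y = np.asarray(y, dtype=float)
    if probs.size < 50:
        warnings.warn("too few observations for a calibration curve", stacklevel=2)
        return None
    lp = logit(probs)
    sm_xy = lowess(y, lp, frac=span, it=0, return_sorted=True)
    p_grid = np.linspace(probs.min(), probs.max(), grid_size)
    obs = np.interp(logit(p_grid), sm_xy[:, 0], sm_xy[:, 1])
    return CalibrationCurve(
        predicted=p_grid, observed=np.clip(obs, 0.0, 1.0)
    )


def classification_metrics(
    probs: np.ndarray, y: np.ndarray, t: float
) -> ThresholdMetrics:
    """Confusion counts and rates at threshold ``t`` (high risk iff prob >= t)."""
    if not 0.0 < t < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    probs = np.asarray(probs, dtype=float)
    y = np.asarray(y)
    high = probs >= t
    tp = int(np.sum(high & (y == 1)))
    fp = int(np.sum(high & (y == 0)))
    fn = int(np.sum(~high & (y == 1)))
    tn = int(np.sum(~high & (y == 0)))
    n = y.size
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    nb = (tp - t / (1.0 - t) * fp) / n
    return ThresholdMetrics(
        threshold=t,
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        accuracy=(tp + tn) / n,
        sensitivity=sens,
        specificity=spec,
        net_benefit=nb,
    )


def net_benefit(probs: np.ndarray, y: np.ndarray, t: float) -> float:
    """Net Benefit (TP - (t / (1-t)) * FP) / N of classifying at threshold t."""
    return classification_metrics(probs, y, t).net_benefit


def net_benefit_treat_all(y: np.ndarray, t: float) -> float:
    """Net Benefit of classifying everyone as high risk."""
    if not 0.0 < t < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    prev = float(np.asarray(y).mean())
    return prev - t / (1.0 - t) * (1.0 - prev)


def decision_curve(
    probs: np.ndarray,
    y: np.ndarray,
    thresholds: np.ndarray | None = None,
) -> pd.DataFrame:
    """Net Benefit of the model and of treat-all / treat-none per threshold."""
    if thresholds is None:
        thresholds = DEFAULT_DECISION_THRESHOLDS
    rows = [
        {
            "threshold": float(t),
            "nb_model": net_benefit(probs, y, float(t)),
            "nb_all": net_benefit_treat_all(y, float(t)),
            "nb_none": 0.0,
        }
        for t in np.asarray(thresholds, dtype=float)
    ]
    return pd.DataFrame(rows)


def evaluate(
    probs: np.ndarray,
    y: np.ndarray,
    thresholds: tuple[float, ...] = (0.5,),
    meta: dict | None = None,
) -> PerformanceRecord:
    """Full test-set evaluation of one probability vector."""
    a_prime, b = calibration_slope(probs, y)
    rec = PerformanceRecord(
        auroc=auroc(probs, y),
        cal_intercept=calibration_intercept(probs, y),
        cal_slope=b,
        cal_slope_intercept=a_prime,
        thresholds={
            float(t): classification_metrics(probs, y, float(t))
            for t in thresholds
        },
        meta=dict(meta or {}),
    )
    return rec
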