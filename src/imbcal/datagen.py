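"""Synthetic data generation for the imbalance-correction simulation study.

The data-generating mechanism is a logistic regression on ``p`` independent
standard-normal predictors of equal strength:

    Pr(Y = 1 | x) = expit(b0 + beta * sum_j x_j)

Because the predictors are i.i.d. N(0, 1), the linear predictor is
Normal(b0, p * beta**2), so the marginal event fraction and the c-statistic
of the true model depend on ``(b0, s)`` only, with ``s = beta * sqrt(p)``.
:func:`calibrate_generator` exploits this to solve for coefficients hitting a
target prevalence and a target c-statistic (default 0.75) by nested 1-D
root-finding on deterministic quadrature, so the same targets yield the same
coefficients regardless of seed.

A separate fixture generator emulates the structure of an ovarian-tumour
diagnosis cohort (age, lesion diameter, papillation count, ~20% malignant)
for exercising the spline-based modelling path; it is fully synthetic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, logit

__all__ = [
    "GeneratorCoefficients",
    "Dataset",
    "ScenarioConfig",
    "CalibrationError",
    "calibrate_generator",
    "generate_dataset",
    "generate_case_study_fixture",
    "true_prevalence",
    "true_cstat",
]

# quadrature grid for the Normal linear predictor (half-width in SDs, points)
_GRID_SD = 10.0
_GRID_N = 4001


class CalibrationError(RuntimeError):
    """Raised when the coefficient root-finder cannot bracket or converge.

    Carries the last iterate in ``last`` for diagnosis.
    """

    def __init__(self, message: str, last: tuple[float, float] | None = None):
        super().__init__(message)
        self.last = last


@dataclass(frozen=True)
class GeneratorCoefficients:
    """True logistic mechanism for one scenario.

    All ``p`` predictors share the same slope ``beta`` (equal-strength
    predictors); ``intercept`` is on the logit scale.
    """

    intercept: float
    beta: float
    p: int

    def __post_init__(self) -> None:
        if self.p < 1:
            raise ValueError("p must be a positive integer")
        if self.beta < 0:
            raise ValueError("beta must be non-negative")

    @property
    def lp_sd(self) -> float:
        """Standard deviation of the linear predictor, beta * sqrt(p)."""
        return self.beta * np.sqrt(self.p)

    def to_json(self) -> str:
        return json.dumps(
            {"intercept": self.intercept, "beta": self.beta, "p": self.p}
        )

    @classmethod
    def from_json(cls, s: str) -> "GeneratorCoefficients":
        d = json.loads(s)
        return cls(intercept=d["intercept"], beta=d["beta"], p=int(d["p"]))


@dataclass
class Dataset:
    """An n x p predictor matrix with a binary outcome.

    ``true_probability`` is present only for generated data, where the
    data-generating probabilities are known.
    """

    predictors: np.ndarray
    outcome: np.ndarray
    true_probability: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.predictors = np.asarray(self.predictors, dtype=float)
        self.outcome = np.asarray(self.outcome)
        if self.predictors.ndim != 2:
            raise ValueError("predictors must be a 2-D matrix")
        if self.predictors.shape[0] != self.outcome.shape[0]:
            raise ValueError("predictors and outcome lengths differ")
        if not np.isin(self.outcome, (0, 1)).all():
            raise ValueError("outcome must be binary 0/1")
        if np.isnan(self.predictors).any():
            raise ValueError("predictors contain missing values")
        self.outcome = self.outcome.astype(np.int64)
        if self.true_probability is not None:
            self.true_probability = np.asarray(self.true_probability, dtype=float)

    @property
    def n(self) -> int:
        return self.predictors.shape[0]

    @property
    def p(self) -> int:
        return self.predictors.shape[1]

    @property
    def event_fraction(self) -> float:
        return float(self.outcome.mean())

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.predictors, columns=[f"x{j + 1}" for j in range(self.p)]
        )
        df["y"] = self.outcome
        if self.true_probability is not None:
            df["pi_true"] = self.true_probability
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Dataset":
        df = pd.read_csv(path)
        xcols = [c for c in df.columns if c.startswith("x")]
        pi = df["pi_true"].to_numpy() if "pi_true" in df.columns else None
        return cls(df[xcols].to_numpy(), df["y"].to_numpy(), pi)


@dataclass(frozen=True)
class ScenarioConfig:
    """One cell of the factorial simulation grid."""

    n_train: int
    p: int
    event_fraction: float
    n_reps: int = 2000
    n_test: int = 100_000
    target_cstat: float = 0.75
    base_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.event_fraction <= 0.5:
            raise ValueError("event_fraction must lie in (0, 0.5]")
        if self.n_test < self.n_train:
            raise ValueError("n_test must be at least n_train")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")

    @property
    def label(self) -> str:
        return f"n{self.n_train}_p{self.p}_ef{self.event_fraction:g}"

    def to_json(self) -> str:
        return json.dumps(self.__dict__)

    @classmethod
    def from_json(cls, s: str) -> "ScenarioConfig":
        return cls(**json.loads(s))


def _lp_grid(b0: float, s: float) -> tuple[np.ndarray, np.ndarray]:
    """Grid and normal density weights for the linear predictor N(b0, s^2)."""
    z = np.linspace(-_GRID_SD, _GRID_SD, _GRID_N)
    w = np.exp(-0.5 * z**2)
    w /= w.sum()
    return b0 + s * z, w


def true_prevalence(b0: float, s: float) -> float:
    """Marginal event probability E[expit(LP)] for LP ~ N(b0, s^2)."""
    if s == 0.0:
        return float(expit(b0))
    lp, w = _lp_grid(b0, s)
    return float(np.sum(w * expit(lp)))


def true_cstat(b0: float, s: float) -> float:
    """C-statistic of the true linear predictor, LP ~ N(b0, s^2).

    c = P(LP_case > LP_control) where cases/controls are drawn with
    probability expit(LP) / 1 - expit(LP).  Computed as the integral of the
    case density against the control CDF on a fine grid.
    """
    if s == 0.0:
        return 0.5
    lp, w = _lp_grid(b0, s)
    pi = expit(lp)
    f_case = w * pi
    f_ctrl = w * (1.0 - pi)
    prev = f_case.sum()
    if prev <= 0.0 or prev >= w.sum():
        return 0.5
    # P(LP1 > LP2) + 0.5 * P(LP1 == LP2) on the discrete grid
    cdf_ctrl = np.cumsum(f_ctrl) - 0.5 * f_ctrl
    return float(np.sum(f_case * cdf_ctrl) / (f_case.sum() * f_ctrl.sum()))


def _solve_intercept(s: float, target_ef: float) -> float:
    """Intercept b0 matching the target prevalence at fixed LP spread s."""
    lo, hi = -60.0, 20.0
    return optimize.brentq(
        lambda b0: true_prevalence(b0, s) - target_ef, lo, hi, xtol=1e-12
    )


def calibrate_generator(
    p: int,
    target_event_fraction: float,
    target_cstat: float = 0.75,
    tolerance: float = 1e-6,
) -> GeneratorCoefficients:
    """Solve for (intercept, beta) hitting a target prevalence and c-statistic.

    Nested 1-D root-finding: the inner solve adjusts the intercept for the
    prevalence at fixed LP spread ``s = beta * sqrt(p)`` (monotone in b0);
    the outer solve adjusts ``s`` for the c-statistic (monotone in s).  Both
    maps are evaluated by deterministic quadrature over the Normal linear
    predictor, so calibration involves no randomness.

    Parameters
    ----------
    p : number of equal-strength predictors.
    target_event_fraction : marginal prevalence, in (0, 0.5].
    target_cstat : c-statistic of the true model, in [0.5, 1).
    tolerance : root-finding tolerance on the c-statistic scale.
    """
    if not 0 < target_event_fraction <= 0.5:
        raise ValueError("target_event_fraction must lie in (0, 0.5]")
    if not 0.5 <= target_cstat < 1:
        raise ValueError("target_cstat must lie in [0.5, 1)")
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    if target_cstat == 0.5:
        # no discrimination: zero slopes, intercept set by prevalence alone
        return GeneratorCoefficients(
            intercept=float(logit(target_event_fraction)), beta=0.0, p=p
        )

    def cstat_gap(s: float) -> float:
        b0 = _solve_intercept(s, target_event_fraction)
        return true_cstat(b0, s) - target_cstat

    s_lo, s_hi = 1e-8, 20.0
    last = None
    try:
        s_star = optimize.brentq(
            cstat_gap, s_lo, s_hi, xtol=1e-10, rtol=8.9e-16, maxiter=200
        )
    except (ValueError, RuntimeError) as exc:  # bracket or convergence failure
        raise CalibrationError(
            f"c-statistic root-finding failed for p={p}, "
            f"ef={target_event_fraction}, c={target_cstat}: {exc}",
            last=last,
        ) from exc
    b0 = _solve_intercept(s_star, target_event_fraction)
    achieved = true_cstat(b0, s_star)
    if abs(achieved - target_cstat) > max(tolerance, 1e-6):
        raise CalibrationError(
            f"calibration did not converge: achieved c={achieved:.6f} "
            f"vs target {target_cstat}",
            last=(b0, s_star),
        )
    return GeneratorCoefficients(
        intercept=float(b0), beta=float(s_star / np.sqrt(p)), p=p
    )


def generate_dataset(
    n: int,
    coefs: GeneratorCoefficients,
    rng: np.random.Generator,
    exact_event_count: bool = False,
) -> Dataset:
    """Draw a dataset of size ``n`` from the logistic mechanism ``coefs``.

    Predictors are i.i.d. standard normal with zero correlation; the outcome
    is Bernoulli with probability expit(b0 + beta * sum_j x_j).

    With ``exact_event_count=True`` the outcome vector is drawn from the
    conditional Bernoulli law given that the total number of events equals
    its expectation ``round(n * prevalence)`` (exact sampling by redrawing
    the outcome vector until the total matches).  This is a variance
    reduction device for large evaluation sets: it removes the event-count
    noise of a single draw — at n = 50,000 and 1% prevalence worth ~0.045
    SD on the logit scale, enough to swamp cell-level calibration summaries
    — while leaving the conditional law of the predictors given the outcome
    untouched.  Training sets should use the default: replicate-to-
    replicate variation in the event count is part of what a simulation
    study measures.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    X = rng.standard_normal((n, coefs.p))
    pi = expit(coefs.intercept + coefs.beta * X.sum(axis=1))
    y = (rng.random(n) < pi).astype(np.int64)
    if exact_event_count:
        m = int(round(n * true_prevalence(coefs.intercept, coefs.lp_sd)))
        m = min(max(m, 0), n)
        best_y = y
        for _ in range(20_000):
            if y.sum() == m:
                best_y = y
                break
            if abs(int(y.sum()) - m) < abs(int(best_y.sum()) - m):
                best_y = y
            y = (rng.random(n) < pi).astype(np.int64)
        y = best_y
    return Dataset(predictors=X, outcome=y, true_probability=pi)


# --- synthetic case-study fixture ------------------------------------------
#
# Emulates the structure of a premenopausal ovarian-tumour cohort: age in
# years (18-59), maximum lesion diameter in mm, papillation count (ordinal
# 0-4), ~20% malignant.  Coefficients are fixed synthetic constants: the
# diameter enters through log-diameter plus a squared log term, so its effect
# on the logit is deliberately nonlinear (exercises the spline machinery).
# The intercept was solved once by quadrature/Monte Carlo so that the
# expected event fraction is 0.20.

_CS_AGE_MEAN, _CS_AGE_SD = 40.0, 10.0
_CS_AGE_LO, _CS_AGE_HI = 18.0, 59.0
_CS_LOGD_MEAN, _CS_LOGD_SD = np.log(55.0), 0.55
_CS_PAP_PROBS = (0.72, 0.10, 0.07, 0.05, 0.06)
_CS_B_AGE = 0.025          # per year, centred at 40
_CS_B_LOGD = 0.9           # per unit log(diameter / 55 mm)
_CS_B_LOGD2 = 0.55         # curvature of the diameter effect
_CS_B_PAP = 0.75           # per papillation level
_CS_INTERCEPT = -2.2904    # solved for E[Y] = 0.20 under the mixture above


def _case_study_linear_predictor(
    age: np.ndarray, diameter: np.ndarray, papillation: np.ndarray
) -> np.ndarray:
    ld = np.log(diameter) - _CS_LOGD_MEAN
    return (
        _CS_INTERCEPT
        + _CS_B_AGE * (age - _CS_AGE_MEAN)
        + _CS_B_LOGD * ld
        + _CS_B_LOGD2 * ld**2
        + _CS_B_PAP * papillation
    )


def generate_case_study_fixture(n: int, rng: np.random.Generator) -> Dataset:
    """Generate a synthetic stand-in for the ovarian-tumour case study.

    Columns (in order): age in years, truncated normal on [18, 59]; maximum
    lesion diameter in mm, log-normal; papillation count, ordinal 0-4.  The
    outcome is logistic with a nonlinear (quadratic-in-log) diameter effect
    and expected event fraction 0.20.  Entirely synthetic — no real cohort
    values are used.
    """
    if n < 50:
        raise ValueError("n must be >= 50")
    # truncated-normal age by rejection; acceptance rate ~0.95
    age = np.empty(0)
    while age.size < n:
        draw = rng.normal(_CS_AGE_MEAN, _CS_AGE_SD, size=2 * n)
        draw = draw[(draw >= _CS_AGE_LO) & (draw <= _CS_AGE_HI)]
        age = np.concatenate([age, draw])
    age = age[:n]
    diameter = np.exp(rng.normal(_CS_LOGD_MEAN, _CS_LOGD_SD, size=n))
    papillation = rng.choice(5, size=n, p=_CS_PAP_PROBS).astype(float)
    pi = expit(_case_study_linear_predictor(age, diameter, papillation))
    y = (rng.random(n) < pi).astype(np.int64)
    X = np.column_stack([age, diameter, papillation])
    return Dataset(predictors=X, outcome=y, true_probability=pi)
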