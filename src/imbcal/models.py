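"""Logistic model fitting: maximum likelihood, ridge with CV, splines.

Two learners are supported, mirroring common risk-modelling practice:

* ``fit_slr`` — standard maximum-likelihood logistic regression (via
  statsmodels GLM), with quasi-/complete-separation detection.
* ``fit_ridge`` — logistic regression with an L2 penalty on the slopes
  (never the intercept), the penalty weight chosen by grid search over a
  stratified 10-fold cross-validation on out-of-fold binomial deviance.
  The solver is a penalized Newton (IRLS) iteration warm-started along the
  lambda path; predictors are standardized internally and coefficients are
  returned on the original scale.

Continuous predictors can be expanded with restricted cubic splines
(:func:`rcs_basis`): piecewise-cubic, linear beyond the boundary knots,
knots at quantiles; 3 knots yield 2 design columns per variable.

``recalibrate_intercept`` performs logistic recalibration-in-the-large:
the model's logit predictions enter as an offset and only the intercept is
refit, which by the score equation makes the mean recalibrated probability
equal the observed event fraction of the recalibration data.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from numba import njit
from scipy import optimize
from scipy.special import expit, logit

from .datagen import Dataset

__all__ = [
    "PROB_CLIP",
    "DesignBasis",
    "FittedModel",
    "FitError",
    "rcs_knots",
    "rcs_basis",
    "fit_slr",
    "fit_ridge",
    "recalibrate_intercept",
    "predict_probabilities",
    "detect_separation",
    "DEFAULT_LAMBDA_GRID",
]

# probabilities are clipped to [PROB_CLIP, 1 - PROB_CLIP] before any logit
PROB_CLIP = 1e-10
# |standardized coefficient| beyond this is treated as divergence/separation
SEPARATION_COEF_BOUND = 20.0
# fitted training probabilities all outside this band also indicate separation
SEPARATION_PROB_BAND = 1e-8

# wide default: 30 log-spaced penalty weights on the standardized scale
DEFAULT_LAMBDA_GRID = np.logspace(-4, 2, 30)


class FitError(RuntimeError):
    """A model fit could not be completed (degenerate input)."""


# --- restricted cubic splines ----------------------------------------------

def rcs_knots(x: np.ndarray, n_knots: int = 3) -> np.ndarray:
    """Knot locations at equally extreme quantiles (0.10/0.50/0.90 for 3)."""
    if n_knots < 3:
        raise ValueError("restricted cubic splines need at least 3 knots")
    if n_knots == 3:
        q = [0.10, 0.50, 0.90]
    else:
        q = np.linspace(0.05, 0.95, n_knots)
    return np.quantile(np.asarray(x, dtype=float), q)


def rcs_basis(
    x: np.ndarray, n_knots: int = 3, knots: np.ndarray | None = None
) -> np.ndarray:
    """Restricted cubic spline design columns for one variable.

    Returns an ``(n, n_knots - 1)`` matrix: the linear term followed by the
    truncated-cubic terms constrained to overall linearity beyond the
    boundary knots (Harrell's parameterization, normalized by the squared
    knot range).  With too few distinct values to place knots, falls back to
    the linear column alone with a warning.
    """
    x = np.asarray(x, dtype=float)
    if knots is None:
        if np.unique(x).size < n_knots:
            warnings.warn(
                "too few distinct values for spline knots; using linear term",
                stacklevel=2,
            )
            return x[:, None]
        knots = rcs_knots(x, n_knots)
    knots = np.asarray(knots, dtype=float)
    if np.unique(knots).size < knots.size:
        warnings.warn("degenerate (tied) knots; using linear term", stacklevel=2)
        return x[:, None]
    k = knots.size
    tk, tk1 = knots[-1], knots[-2]
    norm = (knots[-1] - knots[0]) ** 2

    def cub(u: np.ndarray) -> np.ndarray:
        return np.maximum(u, 0.0) ** 3

    cols = [x]
    for j in range(k - 2):
        tj = knots[j]
        term = (
            cub(x - tj)
            - cub(x - tk1) * (tk - tj) / (tk - tk1)
            + cub(x - tk) * (tk1 - tj) / (tk - tk1)
        )
        cols.append(term / norm)
    return np.column_stack(cols)


@dataclass(frozen=True)
class DesignBasis:
    """Mapping from raw predictors to the model design matrix.

    ``knots`` holds one entry per raw predictor column: ``None`` for a
    linear term, or an array of spline knots for a restricted cubic spline
    expansion of that column.  The identity basis has all entries ``None``.
    """

    knots: tuple = ()

    @classmethod
    def identity(cls, p: int) -> "DesignBasis":
        return cls(knots=tuple([None] * p))

    @classmethod
    def with_rcs(
        cls, X: np.ndarray, spline_columns: Sequence[int], n_knots: int = 3
    ) -> "DesignBasis":
        """Spline basis with knots placed from the data in ``X``."""
        X = np.asarray(X, dtype=float)
        ks: list = [None] * X.shape[1]
        for j in spline_columns:
            ks[j] = rcs_knots(X[:, j], n_knots)
        return cls(knots=tuple(ks))

    @property
    def n_inputs(self) -> int:
        return len(self.knots)

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_inputs:
            raise ValueError(
                f"design basis expects {self.n_inputs} columns, got {X.shape[1]}"
            )
        if all(k is None for k in self.knots):
            return X
        cols = []
        for j, kj in enumerate(self.knots):
            if kj is None:
                cols.append(X[:, j][:, None])
            else:
                cols.append(rcs_basis(X[:, j], knots=np.asarray(kj)))
        return np.hstack(cols)


@dataclass
class FittedModel:
    """A fitted logistic risk model on a fixed design basis.

    ``lambda_`` is the L2 penalty weight on the standardized slope scale
    (0 for a maximum-likelihood fit).  ``coefficients`` are on the original
    design scale, one per design column.
    """

    intercept: float
    coefficients: np.ndarray
    basis: DesignBasis
    lambda_: float = 0.0
    converged: bool = True
    separation_detected: bool = False
    training_meta: dict = field(default_factory=dict)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return predict_probabilities(self, X)

    def to_json(self) -> str:
        return json.dumps(
            {
                "intercept": self.intercept,
                "coefficients": np.asarray(self.coefficients).tolist(),
                "knots": [
                    None if k is None else np.asarray(k).tolist()
                    for k in self.basis.knots
                ],
                "lambda": self.lambda_,
                "converged": self.converged,
                "separation_detected": self.separation_detected,
                "training_meta": self.training_meta,
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "FittedModel":
        d = json.loads(s)
        basis = DesignBasis(
            knots=tuple(
                None if k is None else np.asarray(k) for k in d["knots"]
            )
        )
        return cls(
            intercept=d["intercept"],
            coefficients=np.asarray(d["coefficients"]),
            basis=basis,
            lambda_=d["lambda"],
            converged=d["converged"],
            separation_detected=d["separation_detected"],
            training_meta=d.get("training_meta", {}),
        )


def predict_probabilities(model: FittedModel, X: np.ndarray) -> np.ndarray:
    """expit(intercept + basis(X) @ coefficients), clipped away from 0 and 1."""
    D = model.basis.transform(np.asarray(X, dtype=float))
    eta = model.intercept + D @ np.asarray(model.coefficients, dtype=float)
    return np.clip(expit(eta), PROB_CLIP, 1.0 - PROB_CLIP)


def _check_two_classes(y: np.ndarray) -> None:
    if y.min() == y.max():
        raise FitError("training outcome contains a single class")


def detect_separation(
    design: np.ndarray,
    y: np.ndarray,
    intercept: float,
    coefficients: np.ndarray,
) -> bool:
    """Flag (quasi-)complete separation from a finished or aborted ML fit.

    True when any |coefficient| on the standardized (unit-SD) scale exceeds
    a divergence bound, or when every fitted training probability is
    numerically 0 or 1.
    """
    design = np.asarray(design, dtype=float)
    coefficients = np.asarray(coefficients, dtype=float)
    sd = design.std(axis=0)
    std_coef = coefficients * sd
    if np.any(np.abs(std_coef) > SEPARATION_COEF_BOUND):
        return True
    probs = expit(intercept + design @ coefficients)
    lo, hi = SEPARATION_PROB_BAND, 1.0 - SEPARATION_PROB_BAND
    return bool(np.all((probs <= lo) | (probs >= hi)))


def fit_slr(train: Dataset, basis: DesignBasis | None = None) -> FittedModel:
    """Standard maximum-likelihood logistic regression.

    Fits by IRLS (statsmodels GLM, binomial family).  Separation does not
    raise: the model is returned with ``separation_detected`` (and possibly
    ``converged=False``) set, so a simulation engine can record the event
    and carry on.
    """
    if basis is None:
        basis = DesignBasis.identity(train.p)
    _check_two_classes(train.outcome)
    D = basis.transform(train.predictors)
    n, q = D.shape
    if n <= q + 1:
        raise FitError(f"n={n} too small for q={q} design columns")
    Dc = sm.add_constant(D, has_constant="add")
    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(train.outcome, Dc, family=sm.families.Binomial()).fit(
                maxiter=100
            )
        params = np.asarray(res.params)
        converged = bool(getattr(res, "converged", True))
    except Exception:
        # IRLS aborted (e.g. perfect separation): fall back to a bounded
        # Newton iteration and keep the last iterate for diagnosis
        params, converged = _newton_logistic(
            Dc, train.outcome, lam=0.0, maxiter=25
        )
    intercept, coefs = float(params[0]), params[1:]
    sep = detect_separation(D, train.outcome, intercept, coefs)
    return FittedModel(
        intercept=intercept,
        coefficients=coefs,
        basis=basis,
        lambda_=0.0,
        converged=converged and not sep,
        separation_detected=sep,
    )


def _pen_dev(eta: np.ndarray, y: np.ndarray, pen: np.ndarray, beta: np.ndarray) -> float:
    # -2 loglik + penalty, numerically stable: log(1+e^eta) - y*eta
    return 2.0 * float(np.sum(np.logaddexp(0.0, eta)) - eta @ y) + float(
        pen @ (beta * beta)
    )


def _newton_logistic(
    Dc: np.ndarray,
    y: np.ndarray,
    lam: float,
    beta0: np.ndarray | None = None,
    offset: np.ndarray | None = None,
    maxiter: int = 60,
    tol: float = 1e-9,
) -> tuple[np.ndarray, bool]:
    """Penalized Newton/IRLS for logistic regression.

    ``Dc`` includes the intercept as its first column; the L2 penalty
    ``lam`` applies to all columns except the first.  ``offset`` is added
    to the linear predictor with coefficient fixed at 1.  Large steps are
    guarded by halving against the penalized deviance; small steps (the
    quadratic-convergence regime) are accepted outright, so the deviance is
    only evaluated when it can matter.  Returns (coefficients, converged).
    """
    n, q = Dc.shape
    y = np.asarray(y, dtype=float)
    pen = np.full(q, lam)
    pen[0] = 0.0
    if beta0 is None:
        beta = np.zeros(q)
        ybar = y.mean()
        beta[0] = logit(min(max(ybar, PROB_CLIP), 1 - PROB_CLIP))
    else:
        beta = beta0.copy()

    def lin_pred(b: np.ndarray) -> np.ndarray:
        eta = Dc @ b
        return eta if offset is None else eta + offset

    eta = lin_pred(beta)
    converged = False
    for _ in range(maxiter):
        mu = expit(eta)
        w = mu * (1.0 - mu) + 1e-12
        grad = Dc.T @ (mu - y) + pen * beta
        H = (Dc * w[:, None]).T @ Dc
        H.flat[:: q + 1] += pen
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        step_max = float(np.max(np.abs(step)))
        if step_max < tol:
            converged = True
            break
        if step_max <= 0.5:
            # quadratic-convergence regime: full step, no deviance check
            beta = beta - step
            eta = lin_pred(beta)
            continue
        dev = _pen_dev(eta, y, pen, beta)
        t = 1.0
        cand = beta - step
        cand_eta = lin_pred(cand)
        for _ in range(30):
            if _pen_dev(cand_eta, y, pen, cand) <= dev + 1e-12:
                break
            t *= 0.5
            cand = beta - t * step
            cand_eta = lin_pred(cand)
        if t * step_max < tol:
            beta, eta = cand, cand_eta
            converged = True
            break
        beta, eta = cand, cand_eta
    return beta, converged


@njit(cache=True, fastmath=True)
def _cv_fold_devs(
    Ztr: np.ndarray,
    ytr: np.ndarray,
    Zte: np.ndarray,
    yte: np.ndarray,
    lambdas: np.ndarray,
    warm: np.ndarray,
    tol: float,
    maxiter: int,
) -> np.ndarray:
    """Held-out binomial deviance per penalty weight for one CV fold.

    Each penalty is fit by Newton iterations warm-started from the supplied
    full-data solution, with an infinity-norm trust-region cap of 2 on the
    step (warm starts leave the fold fit one or two steps from its optimum,
    so the cap almost never binds).  Compiled with numba: the fold x lambda
    grid is the simulation's inner loop.
    """
    n_l = lambdas.size
    q = Ztr.shape[1]
    devs = np.zeros(n_l)
    # predictor-corrector warm start: the fold solution differs from the
    # full-data solution by an offset that varies slowly along the path
    offset_prev = np.zeros(q)
    for i in range(n_l):
        lam = lambdas[i]
        beta = warm[i] + offset_prev
        for _ in range(maxiter):
            eta = Ztr @ beta
            mu = 1.0 / (1.0 + np.exp(-eta))
            w = np.sqrt(mu * (1.0 - mu) + 1e-12)
            grad = Ztr.T @ (mu - ytr)
            for j in range(1, q):
                grad[j] += lam * beta[j]
            Zw = Ztr * w.reshape(-1, 1)
            H = Zw.T @ Zw
            for j in range(1, q):
                H[j, j] += lam
            step = np.linalg.solve(H, grad)
            smax = np.max(np.abs(step))
            if smax > 2.0:
                step *= 2.0 / smax
            beta -= step
            if smax < tol:
                break
        offset_prev = beta - warm[i]
        eta_te = Zte @ beta
        acc = 0.0
        for t in range(eta_te.size):
            x = eta_te[t]
            if x > 0.0:
                acc += (x + np.log1p(np.exp(-x))) - yte[t] * x
            else:
                acc += np.log1p(np.exp(x)) - yte[t] * x
        devs[i] = 2.0 * acc
    return devs


def _stratified_folds(
    y: np.ndarray, n_folds: int, rng: np.random.Generator
) -> np.ndarray:
    """Fold labels with events and nonevents dealt round-robin after shuffling."""
    fold = np.empty(y.size, dtype=int)
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        idx = rng.permutation(idx)
        fold[idx] = np.arange(idx.size) % n_folds
    return fold


def fit_ridge(
    train: Dataset,
    lambda_grid: np.ndarray | None = None,
    n_folds: int = 10,
    rng: np.random.Generator | None = None,
    basis: DesignBasis | None = None,
) -> FittedModel:
    """Ridge-penalized logistic regression with cross-validated penalty.

    The grid of penalty weights is searched by stratified ``n_folds``-fold
    cross-validation minimizing out-of-fold binomial deviance; fits are
    warm-started from the next-larger penalty.  The penalty applies to
    standardized slopes only, never the intercept, and the final model is
    refit on the full training data at the selected weight.  Ties in the CV
    criterion resolve to the larger (more conservative) penalty.
    """
    if rng is None:
        raise TypeError("fit_ridge requires an explicit rng for fold assignment")
    if lambda_grid is None:
        lambda_grid = DEFAULT_LAMBDA_GRID
    lambdas = np.sort(np.asarray(lambda_grid, dtype=float))[::-1]
    if basis is None:
        basis = DesignBasis.identity(train.p)
    _check_two_classes(train.outcome)
    D = basis.transform(train.predictors)
    y = train.outcome.astype(float)
    n = y.size

    n_min = int(min(y.sum(), n - y.sum()))
    n_folds = max(2, min(n_folds, n_min))
    fold = _stratified_folds(train.outcome, n_folds, rng)

    # predictors standardized once on the full training data; the penalty
    # acts on this scale and coefficients are mapped back at the end
    mu_, sd_ = D.mean(axis=0), D.std(axis=0)
    sd_ = np.where(sd_ > 0, sd_, 1.0)
    Z = np.column_stack([np.ones(n), (D - mu_) / sd_])

    # full-data solution path (warm-started, largest penalty first); fold
    # fits warm-start from it, which leaves them a step or two from their
    # own optimum
    path = np.empty((lambdas.size, Z.shape[1]))
    beta = None
    for i, lam in enumerate(lambdas):
        beta, _ = _newton_logistic(Z, y, lam, beta0=beta, tol=1e-6)
        path[i] = beta

    if lambdas.size > 1:
        oof_dev = np.zeros(lambdas.size)
        for f in range(n_folds):
            tr = fold != f
            te = ~tr
            ytr = y[tr]
            if ytr.min() == ytr.max():
                raise FitError("a CV training fold contains a single class")
            oof_dev += _cv_fold_devs(
                np.ascontiguousarray(Z[tr]),
                ytr,
                np.ascontiguousarray(Z[te]),
                y[te],
                lambdas,
                path,
                5e-3,
                6,
            )
        best = int(np.argmin(oof_dev))  # first minimum = largest lambda
        lam_star = float(lambdas[best])
    else:
        best = 0
        lam_star = float(lambdas[0])

    beta_std, converged = _newton_logistic(
        Z, y, lam_star, beta0=path[best], tol=1e-10
    )
    slopes = beta_std[1:] / sd_
    intercept = float(beta_std[0] - np.sum(beta_std[1:] * mu_ / sd_))
    return FittedModel(
        intercept=intercept,
        coefficients=slopes,
        basis=basis,
        lambda_=lam_star,
        converged=converged,
        separation_detected=False,
    )


def recalibrate_intercept(model: FittedModel, recal_data: Dataset) -> FittedModel:
    """Logistic recalibration-in-the-large on ``recal_data``.

    The model's logit predictions enter as an offset with coefficient fixed
    at 1 and the intercept is the only free parameter.  The MLE solves the
    score equation mean(expit(a + LP)) = mean(y), a strictly monotone
    1-D problem solved by bracketing.  Slopes are untouched.
    """
    probs = predict_probabilities(model, recal_data.predictors)
    lp = logit(probs)
    ybar = recal_data.outcome.mean()
    if not 0.0 < ybar < 1.0:
        raise FitError("recalibration data contains a single class")

    def score(a: float) -> float:
        return float(np.mean(expit(a + lp))) - ybar

    a_hat = optimize.brentq(score, -50.0, 50.0, xtol=1e-12)
    meta = dict(model.training_meta)
    meta["recalibrated"] = True
    return replace(
        model, intercept=model.intercept + a_hat, training_meta=meta
    )
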