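"""Sigmoidal growth modeling of shoot dry weight from projected canopy size.

The relationship between projected canopy size x (cm²) and shoot dry
weight y (g) is modeled with a three-parameter logistic

    y = a / (1 + exp(-b (x - c)))

where a is the asymptote (maximum attainable dry weight, g), b the
steepness (1/cm²) and c the midpoint (the canopy size at which growth
rate is half its maximum, cm²).  Fitting is bounded trust-region
nonlinear least squares with a heuristic start and jittered multi-start
fallback; goodness of fit is reported as R², RMSE (1/n convention) and a
model-vs-intercept F-test p-value.

``SigmoidRegressor`` is a scikit-learn compatible estimator; the
module-level ``fit_sigmoid`` / ``sigmoid_predict`` functions are thin
wrappers over it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

_EXP_CLIP = 500.0  # exp argument guard


@dataclass(frozen=True)
class SigmoidParams:
    """Logistic parameters: asymptote ``a`` (g), steepness ``b`` (1/cm²), midpoint ``c`` (cm²)."""

    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError(f"asymptote a must be positive, got {self.a}")
        if not math.isfinite(self.c):
            raise ValueError(f"midpoint c must be finite, got {self.c}")


@dataclass(frozen=True)
class FitSummary:
    r_squared: float
    rmse: float
    p_value: float
    n: int
    converged: bool
    degenerate: bool = False


def sigmoid_predict(params: SigmoidParams, x) -> np.ndarray | float:
    """Evaluate y = a / (1 + exp(-b (x - c))); overflow-guarded."""
    x = np.asarray(x, dtype=np.float64)
    z = np.clip(-params.b * (x - params.c), -_EXP_CLIP, _EXP_CLIP)
    y = params.a / (1.0 + np.exp(z))
    return float(y) if y.ndim == 0 else y


def goodness_of_fit(observed, predicted, n_params: int = 3) -> FitSummary:
    """R², RMSE (1/n) and model-vs-intercept F-test for paired vectors."""
    y = np.asarray(observed, dtype=np.float64)
    yhat = np.asarray(predicted, dtype=np.float64)
    if y.shape != yhat.shape:
        raise ValueError(f"length mismatch: observed {y.shape} vs predicted {yhat.shape}")
    n = y.size
    if n < 2:
        raise ValueError(f"need at least 2 observations, got {n}")
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    rmse = math.sqrt(ss_res / n)
    if ss_tot == 0.0:
        return FitSummary(float("nan"), rmse, float("nan"), n, True, degenerate=True)
    r2 = 1.0 - ss_res / ss_tot
    df1 = n_params - 1
    df2 = n - n_params
    if df2 <= 0 or ss_res == 0.0:
        p = 0.0 if ss_res == 0.0 else float("nan")
    else:
        f_stat = ((ss_tot - ss_res) / df1) / (ss_res / df2)
        p = float(stats.f.sf(f_stat, df1, df2))
    return FitSummary(r2, rmse, p, n, True)


def initial_guess(x, y) -> SigmoidParams:
    """Heuristic start: a0 = 1.05 max(y); c0 = x nearest to a0/2; b0 = 4/range(x)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if y.max() <= 0:
        raise ValueError("cannot form an initial guess: max(y) is not positive")
    if np.unique(x).size < 3:
        raise ValueError("need at least 3 distinct x values")
    a0 = 1.05 * float(y.max())
    c0 = float(x[np.argmin(np.abs(y - a0 / 2.0))])
    span = float(x.max() - x.min())
    b0 = 4.0 / span if span > 0 else 1.0
    return SigmoidParams(a0, b0, c0)


class SigmoidRegressor(RegressorMixin, BaseEstimator):
    """Three-parameter logistic regression of y on a single feature x.

    Parameters
    ----------
    bounds : ((a_lo, b_lo, c_lo), (a_hi, b_hi, c_hi)) or None
        Box constraints for the optimizer.  Defaults to a > 0, b > 0,
        c unconstrained.
    max_iter, tol : optimizer budget and convergence tolerance.
    n_starts : number of jittered restarts tried if the first start fails.
    log_transform : fit on ln(y + log_eps) instead of y; predictions are
        transformed back.
    random_state : seed for the restart jitter.

    Attributes
    ----------
    params_ : SigmoidParams
    asymptote_, steepness_, midpoint_ : the fitted a, b, c.
    summary_ : FitSummary with r_squared, rmse, p_value, n, converged.
    """

    def __init__(
        self,
        bounds=None,
        max_iter: int = 5000,
        tol: float = 1e-10,
        n_starts: int = 3,
        log_transform: bool = False,
        log_eps: float = 0.0,
        random_state=None,
    ):
        self.bounds = bounds
        self.max_iter = max_iter
        self.tol = tol
        self.n_starts = n_starts
        self.log_transform = log_transform
        self.log_eps = log_eps
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y, ensure_min_samples=4)
        if X.shape[1] != 1:
            raise ValueError(f"SigmoidRegressor expects a single feature, got {X.shape[1]}")
        x = X[:, 0].astype(np.float64)
        y = np.asarray(y, dtype=np.float64)
        if np.unique(x).size < 3:
            raise ValueError("need at least 3 distinct x values to fit a sigmoid")
        y_fit = log_transform(y, self.log_eps) if self.log_transform else y

        lo, hi = self.bounds if self.bounds is not None else ((1e-12, 1e-12, -np.inf), (np.inf, np.inf, np.inf))
        guess = initial_guess(x, y_fit if y_fit.max() > 0 else y)
        theta0 = np.clip(
            [guess.a, guess.b, guess.c],
            np.nextafter(np.asarray(lo, dtype=float), np.inf),
            np.nextafter(np.asarray(hi, dtype=float), -np.inf),
        )

        def residuals(theta):
            z = np.clip(-theta[1] * (x - theta[2]), -_EXP_CLIP, _EXP_CLIP)
            return theta[0] / (1.0 + np.exp(z)) - y_fit

        rng = np.random.default_rng(self.random_state)
        best = None
        for start in range(max(1, self.n_starts)):
            t0 = theta0 if start == 0 else np.clip(
                theta0 * rng.uniform(0.5, 1.5, size=3),
                np.nextafter(np.asarray(lo, dtype=float), np.inf),
                np.nextafter(np.asarray(hi, dtype=float), -np.inf),
            )
            res = optimize.least_squares(
                residuals,
                t0,
                bounds=(lo, hi),
                method="trf",
                xtol=self.tol,
                ftol=self.tol,
                gtol=self.tol,
                max_nfev=self.max_iter,
            )
            if best is None or res.cost < best.cost:
                best = res
            if res.success:
                break

        a, b, c = best.x
        self.params_ = SigmoidParams(float(a), float(b), float(c))
        self.asymptote_, self.steepness_, self.midpoint_ = a, b, c
        yhat_fit = sigmoid_predict(self.params_, x)
        gof = goodness_of_fit(y_fit, yhat_fit)
        self.summary_ = FitSummary(
            gof.r_squared, gof.rmse, gof.p_value, gof.n, bool(best.success), gof.degenerate
        )
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        check_is_fitted(self, "params_")
        X = check_array(X)
        y = sigmoid_predict(self.params_, X[:, 0])
        if self.log_transform:
            y = inverse_log_transform(y, self.log_eps)
        return np.asarray(y)


def fit_sigmoid(
    x,
    y,
    bounds=None,
    max_iter: int = 5000,
    tol: float = 1e-10,
    seed=None,
    log_transform: bool = False,
) -> tuple[SigmoidParams, FitSummary]:
    """Fit the logistic growth curve to paired (x, y) vectors."""
    x = np.asarray(x, dtype=np.float64)
    est = SigmoidRegressor(
        bounds=bounds,
        max_iter=max_iter,
        tol=tol,
        random_state=seed,
        log_transform=log_transform,
    ).fit(x.reshape(-1, 1), y)
    return est.params_, est.summary_


def daily_average(values) -> tuple[float | None, int]:
    """Mean of the captures taken within one day; (None, 0) marks a missing day."""
    values = [v for v in values if v is not None and not (isinstance(v, float) and math.isnan(v))]
    if not values:
        return None, 0
    return float(np.mean(values)), len(values)


def log_transform(y, eps: float = 0.0) -> np.ndarray:
    """y' = ln(y + eps); requires y + eps > 0 everywhere."""
    y = np.asarray(y, dtype=np.float64)
    if np.any(y + eps <= 0):
        raise ValueError("log transform requires y + eps > 0 for all observations")
    return np.log(y + eps)


def inverse_log_transform(y_transformed, eps: float = 0.0) -> np.ndarray:
    """Inverse of :func:`log_transform`: y = exp(y') - eps."""
    return np.exp(np.asarray(y_transformed, dtype=np.float64)) - eps
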