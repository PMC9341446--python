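"""Threshold dose-response models of daily heatstroke transport risk vs WBGT.

Three models describe the expected number of heat-related ambulance
transportations per million population per day, n(T), as a function of the
daily maximum WBGT T (°C):

``hockey``
    n(T) = beta1 for T < Tw, and beta1 + beta2*(T - Tw) above: constant
    baseline risk with a linear rise past an estimated threshold
    (hockey-stick / broken-stick regression).
``two_step``
    Two thresholds Tw1 < Tw2 with gradients beta2 then beta3, continuous at
    both breakpoints; motivated by the warning-system levels at 28 and 31 °C.
``exponential``
    n(T) = beta1 for T < Tw and beta1*exp(r*(T - Tw)) above: baseline risk
    with an exponential acceleration past the threshold.

Daily counts are modelled as Poisson with mean n(T) * population/1e6 for the
age group's population that calendar year.  Thresholds are profiled over a
grid (the likelihood is non-differentiable in them); the remaining
parameters are maximised by bounded quasi-Newton with analytic gradients.
Models are compared by AIC, counting thresholds as free parameters
(k = 3 / 5 / 3).  Parameter uncertainty is propagated by a parametric
bootstrap: multivariate-normal draws of the non-threshold parameters around
the MLE with the inverse observed information as covariance, thresholds held
at their point estimates (a normal approximation is invalid for
grid-profiled breakpoints); a case-resampling bootstrap is available as an
alternative.

The scikit-learn style estimator :class:`ThresholdPoissonRegressor` is the
primary interface; the module-level functions (:func:`fit_model`,
:func:`predict_risk`, ...) are thin wrappers over it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import gammaln
from sklearn.base import BaseEstimator

__all__ = [
    "MODEL_KINDS",
    "ModelParams",
    "FitResult",
    "FitDiagnostics",
    "ThresholdPoissonRegressor",
    "predict_risk",
    "poisson_loglik",
    "fit_model",
    "compare_models",
    "mae_by_wbgt",
    "bootstrap_params",
]

#: Model kinds in declaration order (used for AIC tie-breaking).
MODEL_KINDS: tuple[str, ...] = ("hockey", "two_step", "exponential")

#: Free parameters per model, thresholds counted as estimated.
N_FREE = {"hockey": 3, "two_step": 5, "exponential": 3}

_BETA_FLOOR = 1e-9  # keeps the Poisson mean strictly positive below threshold


@dataclass(frozen=True)
class ModelParams:
    """Point parameters of one dose-response model.

    Risk units are transports per million population per day; thresholds and
    temperatures are °C; ``r`` is per °C.
    """

    kind: str
    beta1: float
    beta2: float | None = None
    beta3: float | None = None
    r: float | None = None
    tw: float | None = None
    tw1: float | None = None
    tw2: float | None = None

    def __post_init__(self):
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {self.kind!r}")
        if self.beta1 < 0:
            raise ValueError("beta1 must be >= 0")
        if self.kind == "hockey":
            if self.beta2 is None or self.tw is None:
                raise ValueError("hockey model needs beta2 and tw")
        elif self.kind == "two_step":
            if None in (self.beta2, self.beta3, self.tw1, self.tw2):
                raise ValueError("two_step model needs beta2, beta3, tw1, tw2")
            if not self.tw1 < self.tw2:
                raise ValueError("two_step model requires tw1 < tw2")
        else:  # exponential
            if self.r is None or self.tw is None:
                raise ValueError("exponential model needs r and tw")

    @property
    def free_names(self) -> tuple[str, ...]:
        """Names of the non-threshold parameters, in covariance order."""
        if self.kind == "hockey":
            return ("beta1", "beta2")
        if self.kind == "two_step":
            return ("beta1", "beta2", "beta3")
        return ("beta1", "r")

    def free_values(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in self.free_names], dtype=float)

    def with_free_values(self, values: np.ndarray) -> "ModelParams":
        return replace(self, **dict(zip(self.free_names, map(float, values))))


@dataclass(frozen=True)
class FitResult:
    """Maximum-likelihood fit of one model to one age group's data."""

    params: ModelParams
    loglik: float
    aic: float
    vcov: np.ndarray = field(repr=False)
    n_obs: int
    age_group: str | None = None

    @property
    def k(self) -> int:
        return N_FREE[self.params.kind]


@dataclass(frozen=True)
class FitDiagnostics:
    """Per-WBGT-value mean absolute error of a fitted model."""

    table: pd.DataFrame = field(repr=False)  # columns wbgt, mae, n
    max_mae: float
    max_mae_wbgt: float


def predict_risk(params: ModelParams, T):
    """Expected transports per million population per day at WBGT ``T`` (°C).

    Continuous in T at every threshold.  Vectorised over ``T``.
    """
    T = np.asarray(T, dtype=float)
    if params.kind == "hockey":
        out = params.beta1 + params.beta2 * np.maximum(T - params.tw, 0.0)
    elif params.kind == "two_step":
        mid = np.clip(T - params.tw1, 0.0, params.tw2 - params.tw1)
        out = params.beta1 + params.beta2 * mid + params.beta3 * np.maximum(T - params.tw2, 0.0)
    else:
        out = params.beta1 * np.exp(params.r * np.maximum(T - params.tw, 0.0))
    return out if out.ndim else float(out)


def _exposure(data: pd.DataFrame) -> np.ndarray:
    """Population in millions, the multiplier from per-million risk to counts."""
    pop = np.asarray(data["population"], dtype=float)
    if np.any(pop <= 0):
        raise ValueError("population must be > 0")
    return pop / 1e6


def poisson_loglik(params: ModelParams, data: pd.DataFrame) -> float:
    """Poisson log-likelihood of observed daily counts under ``params``.

    ``data`` needs columns ``count``, ``wbgt_c`` and ``population``.  The
    Poisson mean for a day is predict_risk(params, wbgt) * population/1e6.
    A zero mean with a positive count yields -inf (signalled, not raised);
    a zero mean with a zero count contributes 0.
    """
    y = np.asarray(data["count"], dtype=float)
    if np.any(y < 0) or np.any(y != np.round(y)):
        raise ValueError("counts must be non-negative integers")
    lam = predict_risk(params, np.asarray(data["wbgt_c"], dtype=float)) * _exposure(data)
    if np.any((lam <= 0) & (y > 0)):
        return -np.inf
    ok = lam > 0
    # lam == 0 with y == 0 contributes log(1) = 0
    return float(np.sum(y[ok] * np.log(lam[ok]) - lam[ok] - gammaln(y[ok] + 1.0)))


# ---------------------------------------------------------------------------
# inner optimisers (threshold fixed)

def _negll_linear(theta, Z, y, c):
    mu = Z @ theta
    lam = c * mu
    return float(np.sum(lam) - np.sum(y * np.log(lam)))


def _grad_linear(theta, Z, y, c):
    mu = Z @ theta
    return Z.T @ (c - y / mu)


def _fit_linear(Z, y, c, x0):
    """Maximise the Poisson likelihood with mean c*(Z @ theta), theta >= 0.

    The first column of Z must be the intercept so the mean stays positive
    under the bound beta1 >= _BETA_FLOOR.
    """
    bounds = [(_BETA_FLOOR, None)] + [(0.0, None)] * (Z.shape[1] - 1)
    res = minimize(
        _negll_linear,
        x0,
        args=(Z, y, c),
        jac=_grad_linear,
        method="L-BFGS-B",
        bounds=bounds,
    )
    return res


def _negll_exp(theta, u, y, c):
    beta1, r = theta
    lam = c * beta1 * np.exp(r * u)
    return float(np.sum(lam) - np.sum(y * (np.log(c * beta1) + r * u)))


def _grad_exp(theta, u, y, c):
    beta1, r = theta
    lam = c * beta1 * np.exp(r * u)
    return np.array([(np.sum(lam) - np.sum(y)) / beta1, np.sum(u * (lam - y))])


# |r| bound keeps exp() finite over any plausible WBGT excess; the MLE for
# daily heat risk sits well inside it.
_R_BOUNDS = (-2.0, 5.0)


def _fit_exp(u, y, c, x0):
    res = minimize(
        _negll_exp,
        x0,
        args=(u, y, c),
        jac=_grad_exp,
        method="L-BFGS-B",
        bounds=[(_BETA_FLOOR, None), _R_BOUNDS],
    )
    return res


def _numeric_hessian(fun, theta, args, rel_step=1e-4):
    """Central-difference Hessian; adequate for the smooth inner likelihoods."""
    k = len(theta)
    h = rel_step * (np.abs(theta) + 1e-3)
    H = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = h[i]
            ej[j] = h[j]
            fpp = fun(theta + ei + ej, *args)
            fpm = fun(theta + ei - ej, *args)
            fmp = fun(theta - ei + ej, *args)
            fmm = fun(theta - ei - ej, *args)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * h[i] * h[j])
    return H


def _safe_inverse(H: np.ndarray) -> np.ndarray:
    """Symmetrised pseudo-inverse with negative eigenvalues clipped to zero."""
    H = 0.5 * (H + H.T)
    vals, vecs = np.linalg.eigh(H)
    inv_vals = np.where(vals > 1e-12, 1.0 / np.maximum(vals, 1e-12), 0.0)
    V = (vecs * inv_vals) @ vecs.T
    vals_v, vecs_v = np.linalg.eigh(0.5 * (V + V.T))
    vals_v = np.clip(vals_v, 0.0, None)
    return (vecs_v * vals_v) @ vecs_v.T


class ThresholdPoissonRegressor(BaseEstimator):
    """Poisson regression of daily counts on WBGT with estimated thresholds.

    Parameters
    ----------
    model : {"hockey", "two_step", "exponential"}
        Dose-response shape (see module docstring).
    grid_step : float
        Threshold profile-grid resolution, °C.  The default 0.1 matches the
        precision at which thresholds are conventionally reported.
    threshold_margin : float
        Thresholds are searched in
        [min(T) + threshold_margin, max(T) - threshold_margin].
    min_gap_steps : int
        For the two-step model, minimum gap between the two thresholds in
        grid steps.

    Attributes
    ----------
    params_ : ModelParams
        Point estimates.
    loglik_ : float
        Maximised log-likelihood (including the log y! constant).
    aic_ : float
        2k - 2*loglik with k = 3, 5 or 3 free parameters by model.
    vcov_ : ndarray
        Inverse observed information of the non-threshold parameters at the
        optimum, in ``params_.free_names`` order.
    n_obs_ : int
        Number of days used.

    Examples
    --------
    >>> est = ThresholdPoissonRegressor(model="hockey", grid_step=0.5)
    >>> est.fit(wbgt, counts, population=3.08e6)  # doctest: +SKIP
    >>> est.predict([25.0, 30.0])                 # doctest: +SKIP
    """

    def __init__(
        self,
        model: str = "exponential",
        grid_step: float = 0.1,
        threshold_margin: float = 0.5,
        min_gap_steps: int = 1,
    ):
        self.model = model
        self.grid_step = grid_step
        self.threshold_margin = threshold_margin
        self.min_gap_steps = min_gap_steps

    # -- internal ----------------------------------------------------------

    def _threshold_grid(self, T: np.ndarray) -> np.ndarray:
        lo = T.min() + self.threshold_margin
        hi = T.max() - self.threshold_margin
        if hi < lo:
            raise ValueError("WBGT range too narrow for any admissible threshold")
        n = int(np.floor((hi - lo) / self.grid_step + 1e-9)) + 1
        return lo + self.grid_step * np.arange(n)

    def _design(self, T: np.ndarray, thresholds: tuple) -> np.ndarray:
        ones = np.ones_like(T)
        if self.model == "hockey":
            (tw,) = thresholds
            return np.column_stack([ones, np.maximum(T - tw, 0.0)])
        tw1, tw2 = thresholds
        return np.column_stack(
            [ones, np.clip(T - tw1, 0.0, tw2 - tw1), np.maximum(T - tw2, 0.0)]
        )

    def _profile_candidates(self, T: np.ndarray):
        grid = self._threshold_grid(T)
        if self.model in ("hockey", "exponential"):
            for tw in grid:
                # at least one observation strictly below and at/above tw
                if np.any(T < tw) and np.any(T >= tw):
                    yield (float(tw),)
        else:
            gap = self.min_gap_steps * self.grid_step
            for i, tw1 in enumerate(grid):
                if not np.any(T < tw1):
                    continue
                for tw2 in grid[i + 1 :]:
                    if tw2 - tw1 < gap - 1e-12:
                        continue
                    # every segment needs data for its slope to be identified
                    if np.any((T >= tw1) & (T < tw2)) and np.any(T >= tw2):
                        yield (float(tw1), float(tw2))

    # -- sklearn API -------------------------------------------------------

    def fit(self, X, y, population=1_000_000.0):
        """Fit by profiled maximum likelihood.

        Parameters
        ----------
        X : array-like, shape (n,) or (n, 1)
            Daily maximum WBGT, °C.
        y : array-like of int, shape (n,)
            Observed daily transport counts.
        population : float or array-like
            Age-group population for each day's calendar year (scalar if
            constant).  The Poisson mean is risk(T) * population / 1e6.
        """
        T = np.asarray(X, dtype=float)
        if T.ndim == 2 and T.shape[1] == 1:
            T = T[:, 0]
        if T.ndim != 1:
            raise ValueError("X must be 1-d WBGT values (or a single column)")
        y = np.asarray(y, dtype=float)
        if y.shape != T.shape:
            raise ValueError("X and y have mismatched lengths")
        if np.any(y < 0) or np.any(y != np.round(y)):
            raise ValueError("counts must be non-negative integers")
        c = np.broadcast_to(np.asarray(population, dtype=float) / 1e6, T.shape).copy()
        if np.any(c <= 0):
            raise ValueError("population must be > 0")
        if self.model not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {self.model!r}")

        rate0 = max(float(np.mean(y / c)), 1e-3)  # per-million baseline guess
        best = None
        warm: dict[int, np.ndarray] = {}
        for thresholds in self._profile_candidates(T):
            if self.model == "exponential":
                u = np.maximum(T - thresholds[0], 0.0)
                x0 = warm.get(2, np.array([rate0, 0.3]))
                res = _fit_exp(u, y, c, x0)
                args = (u, y, c)
                fun = _negll_exp
            else:
                Z = self._design(T, thresholds)
                p = Z.shape[1]
                x0 = warm.get(p, np.concatenate([[rate0], np.full(p - 1, 0.5)]))
                res = _fit_linear(Z, y, c, x0)
                args = (Z, y, c)
                fun = _negll_linear
            if not np.isfinite(res.fun):
                continue
            warm[len(res.x)] = res.x
            if best is None or res.fun < best[0]:
                best = (res.fun, thresholds, res, args, fun)

        if best is None:
            raise ValueError("no admissible threshold candidate for this data")
        negll, thresholds, res, args, fun = best
        if not res.success:
            raise RuntimeError(
                f"optimiser failed at best threshold {thresholds}: {res.message}"
            )

        theta = res.x
        if self.model == "hockey":
            params = ModelParams(
                kind="hockey", beta1=theta[0], beta2=theta[1], tw=thresholds[0]
            )
        elif self.model == "two_step":
            params = ModelParams(
                kind="two_step",
                beta1=theta[0],
                beta2=theta[1],
                beta3=theta[2],
                tw1=thresholds[0],
                tw2=thresholds[1],
            )
        else:
            params = ModelParams(
                kind="exponential", beta1=theta[0], r=theta[1], tw=thresholds[0]
            )

        # the inner objectives drop additive constants; recover the true
        # log-likelihood (incl. log y!) with the exact evaluator
        data = pd.DataFrame({"count": y, "wbgt_c": T, "population": c * 1e6})
        loglik = poisson_loglik(params, data)

        H = _numeric_hessian(fun, theta, args)
        self.vcov_ = _safe_inverse(H)
        self.params_ = params
        self.loglik_ = float(loglik)
        self.aic_ = 2.0 * N_FREE[self.model] - 2.0 * self.loglik_
        self.n_obs_ = int(T.size)
        return self

    def predict(self, X):
        """Expected transports per million per day at the given WBGT values."""
        if not hasattr(self, "params_"):
            raise AttributeError("estimator is not fitted")
        T = np.asarray(X, dtype=float)
        if T.ndim == 2 and T.shape[1] == 1:
            T = T[:, 0]
        return predict_risk(self.params_, T)

    def result_(self, age_group: str | None = None) -> FitResult:
        """Bundle the fitted attributes as an immutable :class:`FitResult`."""
        if not hasattr(self, "params_"):
            raise AttributeError("estimator is not fitted")
        return FitResult(
            params=self.params_,
            loglik=self.loglik_,
            aic=self.aic_,
            vcov=self.vcov_,
            n_obs=self.n_obs_,
            age_group=age_group,
        )


# ---------------------------------------------------------------------------
# functional wrappers

def _season_mask(dates: pd.Series, season: tuple[int, int, int, int]) -> np.ndarray:
    m1, d1, m2, d2 = season
    md = dates.dt.month * 100 + dates.dt.day
    return ((md >= m1 * 100 + d1) & (md <= m2 * 100 + d2)).to_numpy()


def fit_model(
    data: pd.DataFrame,
    model_kind: str,
    grid_step: float = 0.1,
    age_group: str | None = None,
    season: tuple[int, int, int, int] | None = (5, 1, 9, 30),
) -> FitResult:
    """Fit one dose-response model to one age group's daily case data.

    ``data`` needs columns ``wbgt_c``, ``count`` and ``population`` (and
    ``date`` / ``age_group`` when season filtering or group selection apply).
    By default only days in the May 1 - Sep 30 risk season enter the
    likelihood, matching the window over which risk is later projected;
    pass ``season=None`` to use all days.
    """
    df = data
    if age_group is not None:
        df = df[df["age_group"] == age_group]
        if df.empty:
            raise ValueError(f"no rows for age group {age_group!r}")
    if season is not None and "date" in df.columns:
        df = df[_season_mask(pd.to_datetime(df["date"]), season)]
    if df.empty:
        raise ValueError("no observations after filtering")
    est = ThresholdPoissonRegressor(model=model_kind, grid_step=grid_step)
    est.fit(
        df["wbgt_c"].to_numpy(),
        df["count"].to_numpy(),
        population=df["population"].to_numpy(),
    )
    return est.result_(age_group=age_group)


def compare_models(fits) -> FitResult:
    """Best fit by AIC; ties broken by fewest parameters, then model order."""
    fits = list(fits)
    if not fits:
        raise ValueError("no fits to compare")
    return min(
        fits, key=lambda f: (f.aic, f.k, MODEL_KINDS.index(f.params.kind))
    )


def mae_by_wbgt(
    fit: FitResult, data: pd.DataFrame, precision: float = 0.1
) -> FitDiagnostics:
    """Mean absolute error of per-million risk, grouped by WBGT value.

    Observations are grouped by WBGT rounded to ``precision`` °C; within each
    group the MAE is the mean absolute difference between observed per-million
    counts and the model's prediction.
    """
    if data.empty:
        raise ValueError("data must be nonempty")
    T = np.asarray(data["wbgt_c"], dtype=float)
    obs = np.asarray(data["count"], dtype=float) / _exposure(data)
    pred = predict_risk(fit.params, T)
    key = np.round(T / precision) * precision
    tbl = (
        pd.DataFrame({"wbgt": key, "abs_err": np.abs(obs - pred)})
        .groupby("wbgt", sort=True)
        .agg(mae=("abs_err", "mean"), n=("abs_err", "size"))
        .reset_index()
    )
    imax = int(tbl["mae"].idxmax())
    return FitDiagnostics(
        table=tbl,
        max_mae=float(tbl.loc[imax, "mae"]),
        max_mae_wbgt=float(tbl.loc[imax, "wbgt"]),
    )


def bootstrap_params(
    fit: FitResult,
    B: int,
    seed,
    data: pd.DataFrame | None = None,
    method: str = "normal",
    grid_step: float = 0.1,
    max_tries: int = 1000,
) -> list[ModelParams]:
    """Parametric bootstrap draws of the dose-response parameters.

    ``method="normal"`` (default) draws the non-threshold parameters from a
    multivariate normal centred at the MLE with covariance ``fit.vcov``;
    thresholds stay at their point estimates and draws violating the
    parameter constraints (beta >= 0) are redrawn.  ``method="case"``
    refits the model to case-resampled data (requires ``data``); it is much
    slower but also propagates threshold uncertainty.
    Deterministic given ``seed``.
    """
    if B <= 0:
        raise ValueError("B must be positive")
    rng = np.random.default_rng(seed)

    if method == "case":
        if data is None:
            raise ValueError("case-resampling bootstrap needs the original data")
        draws = []
        n = len(data)
        for _ in range(B):
            idx = rng.integers(0, n, size=n)
            res = fit_model(
                data.iloc[idx],
                fit.params.kind,
                grid_step=grid_step,
                season=None,
            )
            draws.append(res.params)
        return draws
    if method != "normal":
        raise ValueError("method must be 'normal' or 'case'")

    center = fit.params.free_values()
    names = fit.params.free_names
    nonneg = np.array([not name == "r" for name in names])  # r may be negative
    draws_arr = np.empty((B, len(center)))
    filled = 0
    for _ in range(max_tries):
        need = B - filled
        if need == 0:
            break
        cand = rng.multivariate_normal(center, fit.vcov, size=need, method="eigh")
        ok = np.all(cand[:, nonneg] >= 0.0, axis=1)
        good = cand[ok]
        take = min(len(good), need)
        draws_arr[filled : filled + take] = good[:take]
        filled += take
    if filled < B:
        raise RuntimeError("could not draw enough constraint-satisfying samples")
    return [fit.params.with_free_values(row) for row in draws_arr]
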