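"""Conway-Maxwell Poisson (CMP) counts: distribution, regression, scenarios.

The CMP distribution generalizes the Poisson with a dispersion parameter:

    P(Y = y) = lambda^y / (y!)^nu / Z(lambda, nu),
    Z(lambda, nu) = sum_{j>=0} lambda^j / (j!)^nu,

with ``nu = 1`` the Poisson, ``nu > 1`` under-dispersion (variance below
the mean) and ``nu < 1`` over-dispersion; ``nu = 0`` is geometric and
requires ``lambda < 1``.  All series work is done in log space with an
explicit tail bound.

:class:`CMPRegression` fits counts by maximum likelihood with

    log lambda_i = x_i' beta        (mean structure)
    log nu_i     = z_i' gamma       (dispersion structure)

using analytic gradients (the score involves E[Y] and E[log Y!] under the
fitted cell distribution).  The dispersion design ``Z`` defaults to an
intercept; passing a regressor (e.g. mean BMI) reproduces the
"dispersion regressor" model used for incidence projections.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import gammaln, logsumexp
from sklearn.base import BaseEstimator

DEFAULT_TOL = 1e-12
_MAX_TERMS = 20000


class CMPDivergenceError(ValueError):
    """The normalizing series diverges (nu = 0 with lambda >= 1)."""


class ConvergenceError(RuntimeError):
    pass


def _support_grid(log_lam, nu, tol):
    """Shared truncation point for a batch of (lambda, nu) pairs."""
    log_lam = np.atleast_1d(log_lam)
    nu = np.atleast_1d(nu)
    if np.any((nu == 0) & (log_lam >= 0)):
        raise CMPDivergenceError("Z diverges for nu = 0 with lambda >= 1")
    # mode ~ lambda^(1/nu); pad by a generous multiple of its sqrt scale
    with np.errstate(over="ignore", divide="ignore"):
        mode = np.where(nu > 0, np.exp(np.minimum(log_lam / np.maximum(nu, 1e-12), 20)), 0.0)
    geo = np.where(nu < 0.05, np.log(tol) / np.minimum(log_lam, -1e-12), 0.0)
    upper = np.maximum(mode + 15 * np.sqrt(mode / np.maximum(nu, 0.05) + 20), geo + 20)
    J = int(min(np.max(upper), _MAX_TERMS))
    return max(J, 10)


def _log_terms(log_lam, nu, j):
    """log of lambda^j/(j!)^nu for a batch of rows over support grid j."""
    with np.errstate(invalid="ignore"):
        lt = log_lam[:, None] * j[None, :] - nu[:, None] * gammaln(j + 1)[None, :]
    lt[:, 0] = 0.0  # lambda^0/(0!)^nu = 1, also when lambda = 0
    return np.where(np.isneginf(log_lam)[:, None] & (j[None, :] > 0), -np.inf, lt)


def cmp_log_normalizer(lam, nu, tol: float = DEFAULT_TOL, return_terms: bool = False):
    """log Z(lambda, nu), vectorized over (lambda, nu) pairs.

    The series is truncated when the remaining tail is provably below
    ``tol`` relative to the accumulated sum; the truncation index is
    available via ``return_terms``.
    """
    lam = np.asarray(lam, dtype=float)
    nu_arr = np.asarray(nu, dtype=float)
    scalar = lam.ndim == 0 and nu_arr.ndim == 0
    lam, nu_arr = np.atleast_1d(lam), np.atleast_1d(nu_arr)
    lam, nu_arr = np.broadcast_arrays(lam, nu_arr)
    if np.any(lam < 0) or np.any(nu_arr < 0):
        raise ValueError("lambda and nu must be non-negative")
    with np.errstate(divide="ignore"):
        log_lam = np.log(lam)
    J = _support_grid(log_lam, nu_arr, tol)
    j = np.arange(J + 1)
    log_terms = _log_terms(log_lam, nu_arr, j)
    logZ = logsumexp(log_terms, axis=1)
    # tail bound: beyond J the term ratio lam/(j+1)^nu is below
    # r = lam/(J+1)^nu, so the tail is at most term_J * r/(1 - r)
    with np.errstate(divide="ignore"):
        log_ratio = log_lam - nu_arr * np.log(J + 1)
    tail_bad = (log_ratio >= 0) | (
        (log_terms[:, -1] + log_ratio - np.log1p(-np.exp(np.minimum(log_ratio, -1e-12))))
        > logZ + np.log(tol)
    )
    if np.any(tail_bad & np.isfinite(log_lam)):
        raise CMPDivergenceError(
            f"series not converged within {J} terms; lambda too large for cap"
        )
    if scalar:
        logZ = float(logZ[0])
    return (logZ, J) if return_terms else logZ


def cmp_pmf(y, lam, nu, tol: float = DEFAULT_TOL):
    """CMP probability mass at count(s) ``y``."""
    y = np.asarray(y, dtype=float)
    logZ = cmp_log_normalizer(lam, nu, tol)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_lam = np.log(lam)
        logp = y * log_lam - nu * gammaln(y + 1) - logZ
    logp = np.where(y == 0, -logZ, logp)
    logp = np.where(np.isneginf(log_lam) & (y > 0), -np.inf, logp)
    return np.exp(logp)


def _cmp_weights(log_lam, nu, tol=DEFAULT_TOL):
    """Normalized pmf matrix over a shared support grid (rows: observations)."""
    log_lam = np.atleast_1d(np.asarray(log_lam, dtype=float))
    nu = np.atleast_1d(np.asarray(nu, dtype=float))
    J = _support_grid(log_lam, nu, tol)
    j = np.arange(J + 1)
    log_terms = _log_terms(log_lam, nu, j)
    logZ = logsumexp(log_terms, axis=1, keepdims=True)
    return np.exp(log_terms - logZ), j


def cmp_moments(lam, nu, tol: float = DEFAULT_TOL):
    """E[Y], Var[Y] and E[log Y!] under CMP(lambda, nu)."""
    with np.errstate(divide="ignore"):
        log_lam = np.log(np.asarray(lam, dtype=float))
    W, j = _cmp_weights(log_lam, nu, tol)
    ey = W @ j
    ey2 = W @ (j**2)
    elgam = W @ gammaln(j + 1)
    var = ey2 - ey**2
    if np.ndim(lam) == 0 and np.ndim(nu) == 0:
        return float(ey[0]), float(var[0]), float(elgam[0])
    return ey, var, elgam


def cmp_rvs(lam, nu, size: int, rng: np.random.Generator, tol: float = DEFAULT_TOL):
    """Sample counts by inverse-CDF over the truncated support."""
    with np.errstate(divide="ignore"):
        log_lam = np.log(np.asarray(lam, dtype=float))
    W, j = _cmp_weights(log_lam, nu, tol)
    cdf = np.cumsum(W[0], axis=-1) if W.shape[0] == 1 else None
    if cdf is not None:
        return j[np.searchsorted(cdf, rng.random(size), side="right").clip(0, len(j) - 1)]
    if W.shape[0] != size:
        raise ValueError("vector lam/nu requires size == len(lam)")
    cdfs = np.cumsum(W, axis=1)
    u = rng.random(size)
    idx = (cdfs < u[:, None]).sum(axis=1)
    return j[idx.clip(0, len(j) - 1)]


# ---------------------------------------------------------------------------
# regression
# ---------------------------------------------------------------------------


class CMPRegression(BaseEstimator):
    """CMP count regression with modeled dispersion.

    ``fit(X, y, Z=None)`` maximizes the exact CMP likelihood over
    ``beta`` (log lambda = X beta) and ``gamma`` (log nu = Z gamma).
    ``Z`` defaults to an intercept-only design (constant dispersion).
    Designs should carry their own intercept columns.

    ``dof_correction`` (default on) rescales the fitted ``nu`` and ``beta``
    by ``(n - p)/n``: the profiled dispersion is biased up by about
    ``n/(n - p)`` because the ``p`` mean parameters absorb residual
    variation (the analogue of the MLE variance estimator's bias, corrected
    the way GLM software scales dispersion by residual degrees of freedom),
    and ``beta`` inherits that bias through the ratio ``beta/nu`` that the
    mean structure identifies.  ``fix_nu`` in :meth:`fit` pins the
    dispersion instead (``fix_nu=1`` makes the fit exactly a Poisson GLM).

    Attributes
    ----------
    coef_ : ndarray            mean-structure coefficients (beta)
    disp_coef_ : ndarray       dispersion coefficients (gamma)
    cov_params_ : ndarray      inverse observed information at the MLE
    loglik_, aic_ : float
    converged_ : bool
    """

    def __init__(self, tol: float = 1e-8, series_tol: float = DEFAULT_TOL,
                 max_iter: int = 500, on_failure: str = "raise",
                 dof_correction: bool = True):
        self.tol = tol
        self.series_tol = series_tol
        self.max_iter = max_iter
        self.on_failure = on_failure
        self.dof_correction = dof_correction

    def _nll_grad(self, theta, X, y, Z, lgy, nu_fixed=None):
        p = X.shape[1]
        beta, gamma = theta[:p], theta[p:]
        log_lam = X @ beta
        if nu_fixed is not None:
            nu = np.broadcast_to(np.asarray(nu_fixed, dtype=float), len(y))
        else:
            nu = np.exp(np.clip(Z @ gamma, -10, 5))
        if np.any(log_lam > 500):
            return np.inf, np.zeros_like(theta)
        try:
            W, j = _cmp_weights(log_lam, nu, self.series_tol)
        except CMPDivergenceError:
            return np.inf, np.zeros_like(theta)
        log_terms0 = log_lam[:, None] * j[None, :] - nu[:, None] * gammaln(j + 1)[None, :]
        logZ = logsumexp(log_terms0, axis=1)
        ll = np.sum(y * log_lam - nu * lgy - logZ)
        ey = W @ j
        elgam = W @ gammaln(j + 1)
        g_beta = X.T @ (y - ey)
        if nu_fixed is not None:
            return -ll, -g_beta
        g_gamma = Z.T @ (nu * (elgam - lgy))
        return -ll, -np.concatenate([g_beta, g_gamma])

    def fit(self, X, y, Z=None, start=None, fix_nu=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if np.any(y < 0) or np.any(y % 1 != 0):
            raise ValueError("counts must be non-negative integers")
        if y.sum() == 0:
            warnings.warn("all counts are zero: boundary fit", UserWarning)
        n, p = X.shape
        if Z is None:
            Z = np.ones((n, 1))
        Z = np.asarray(Z, dtype=float)
        q = 0 if fix_nu is not None else Z.shape[1]
        lgy = gammaln(y + 1)

        if start is None:
            # Poisson GLM start for beta; gamma = 0 (nu = 1)
            import statsmodels.api as sm

            try:
                glm = sm.GLM(y, X, family=sm.families.Poisson()).fit()
                beta0 = np.asarray(glm.params, dtype=float)
            except Exception:
                beta0 = np.zeros(p)
                beta0[0] = np.log(max(y.mean(), 0.1))
            start = np.concatenate([beta0, np.zeros(q)])

        args = (X, y, Z, lgy, fix_nu)
        res = minimize(
            self._nll_grad, start, args=args, jac=True,
            method="L-BFGS-B",
            options={"maxiter": self.max_iter, "ftol": self.tol, "gtol": 1e-7},
        )
        grad_norm = float(np.max(np.abs(res.jac))) if np.all(np.isfinite(res.jac)) else np.inf
        converged = bool(res.success or grad_norm < 1e-3 * max(1.0, y.sum() ** 0.5))
        if not converged:
            res2 = minimize(self._nll_grad, res.x, args=args, jac=True,
                            method="BFGS", options={"maxiter": self.max_iter})
            if res2.fun <= res.fun:
                res = res2
            grad_norm = float(np.max(np.abs(res.jac)))
            converged = bool(res.success or grad_norm < 1e-2 * max(1.0, y.sum() ** 0.5))
        if not converged and self.on_failure == "raise":
            raise ConvergenceError(
                f"CMP fit failed: {res.message} (|grad|_inf = {grad_norm:.3g})"
            )

        theta = res.x
        self.coef_ = theta[:p]
        self.fixed_nu_ = fix_nu
        self.disp_coef_ = theta[p:] if fix_nu is None else np.array([])
        self.loglik_ = -float(res.fun)
        self.aic_ = 2 * (p + q) - 2 * self.loglik_
        self.converged_ = converged
        self.n_obs_ = n
        cov = self._numeric_cov(theta, X, y, Z, lgy, fix_nu)
        if fix_nu is None and self.dof_correction and n > p:
            # dispersion degrees-of-freedom adjustment, the analogue of
            # estimating a variance with n - p rather than n: the profiled
            # nu is biased up by ~n/(n - p) because the p mean parameters
            # absorb residual variation, and beta scales with nu through
            # the well-identified ratio beta/nu.  Shrink both by (n - p)/n.
            c = (n - p) / n
            self.coef_ = self.coef_ * c
            self.disp_coef_ = self.disp_coef_.copy()
            self.disp_coef_[0] += np.log(c)
            T = np.diag(np.concatenate([np.full(p, c), np.ones(q)]))
            cov = T @ cov @ T
        self.cov_params_ = cov
        if fix_nu is None:
            self.nu_ = np.exp(np.clip(Z @ self.disp_coef_, -10, 5))
        else:
            self.nu_ = np.broadcast_to(np.asarray(fix_nu, dtype=float), n).copy()
        self.lambda_ = np.exp(X @ self.coef_)
        return self

    def _numeric_cov(self, theta, X, y, Z, lgy, nu_fixed=None):
        k = len(theta)
        H = np.zeros((k, k))
        eps = 1e-5
        for i in range(k):
            tp, tm = theta.copy(), theta.copy()
            tp[i] += eps
            tm[i] -= eps
            _, gp = self._nll_grad(tp, X, y, Z, lgy, nu_fixed)
            _, gm = self._nll_grad(tm, X, y, Z, lgy, nu_fixed)
            H[i] = (gp - gm) / (2 * eps)
        H = (H + H.T) / 2
        try:
            return np.linalg.inv(H)
        except np.linalg.LinAlgError:
            return np.full((k, k), np.nan)

    def predict(self, X, Z=None):
        """Expected counts E[Y] under the fitted distribution."""
        self._check_fitted()
        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        Z = np.ones((n, 1)) if Z is None else np.asarray(Z, dtype=float)
        log_lam = X @ self.coef_
        if self.fixed_nu_ is not None:
            nu = np.broadcast_to(np.asarray(self.fixed_nu_, dtype=float), n)
        else:
            nu = np.exp(np.clip(Z @ self.disp_coef_, -10, 5))
        W, j = _cmp_weights(log_lam, nu, self.series_tol)
        return W @ j

    def _check_fitted(self):
        if not hasattr(self, "coef_"):
            raise AttributeError("CMPRegression is not fitted")


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------


def weight_to_bmi_delta(delta_weight_kg: float, mean_height_m: float) -> float:
    """BMI change implied by a mean body-weight change at fixed height."""
    if mean_height_m <= 0:
        raise ValueError("height must be positive")
    return delta_weight_kg / mean_height_m**2


@dataclass(frozen=True)
class ScenarioSpec:
    """A named population-weight trajectory for projection.

    Exactly one rule applies:

    - ``period_trend_to_target``: BMI follows the secular trend to the
      externally supplied ``target_bmi`` at the horizon;
    - ``frozen_at_baseline``: BMI held at its baseline-year level;
    - ``weight_delta_kg``: baseline BMI shifted by ``delta_kg / height^2``.
    """

    name: str
    horizon_year: int
    baseline_year: int
    rule: str  # period_trend_to_target | frozen_at_baseline | weight_delta_kg
    delta_kg: float = 0.0
    target_bmi: dict = field(default_factory=dict)  # sex -> BMI at horizon
    mean_heights: dict = field(default_factory=dict)  # sex -> metres

    def __post_init__(self):
        if self.rule not in ("period_trend_to_target", "frozen_at_baseline",
                             "weight_delta_kg"):
            raise ValueError(f"unknown scenario rule {self.rule!r}")
        if self.horizon_year <= self.baseline_year:
            raise ValueError("horizon must lie after the baseline year")

    def bmi_at_horizon(self, sex: str, baseline_bmi: float) -> float:
        if self.rule == "period_trend_to_target":
            if sex not in self.target_bmi:
                raise ValueError(f"no target BMI configured for sex {sex!r}")
            return float(self.target_bmi[sex])
        if self.rule == "frozen_at_baseline":
            return float(baseline_bmi)
        return float(baseline_bmi + weight_to_bmi_delta(self.delta_kg,
                                                        self.mean_heights[sex]))


def project_scenario(model: CMPRegression, scenario: ScenarioSpec,
                     strata: pd.DataFrame, design_builder, standard,
                     per: float = 1000.0, level: float = 0.95) -> dict:
    """Project age-standardized incidence at the scenario horizon.

    ``strata`` holds one row per (sex, age_group) with columns
    ``baseline_bmi`` (mean BMI in the baseline year) and ``population``
    (projected horizon population of the stratum).  ``design_builder`` maps
    a strata frame with a ``bmi`` column to the (X, Z) designs used in
    fitting, guaranteeing the same column layout.  Delta-method CIs
    propagate the MLE covariance through the standardized rate.
    """
    df = strata.copy()
    df["bmi"] = [
        scenario.bmi_at_horizon(s, b) for s, b in zip(df["sex"], df["baseline_bmi"])
    ]
    X, Z = design_builder(df)

    def standardized_rate(theta):
        p = X.shape[1]
        log_lam = X @ theta[:p]
        nu = np.exp(np.clip(Z @ theta[p:], -10, 5))
        W, j = _cmp_weights(log_lam, nu, model.series_tol)
        counts = W @ j
        rates = counts / df["population"].to_numpy() * per
        tmp = df.assign(rate=rates)
        by_sex = {}
        for sex, sub in tmp.groupby("sex", observed=False):
            w = standard[sex] if isinstance(standard, dict) else standard
            aligned = sub.set_index("age_group")["rate"].reindex(w.index)
            by_sex[sex] = float((aligned * w).sum())
        pops = tmp.groupby("sex", observed=False)["population"].sum()
        national = float(sum(by_sex[s] * pops[s] for s in by_sex) / pops.sum())
        return by_sex, national

    theta_hat = np.concatenate([model.coef_, model.disp_coef_])
    by_sex, national = standardized_rate(theta_hat)

    # delta-method over the full parameter vector
    eps = 1e-5
    k = len(theta_hat)
    sex_names = sorted(by_sex)
    grads = np.zeros((len(sex_names) + 1, k))
    for i in range(k):
        tp, tm = theta_hat.copy(), theta_hat.copy()
        tp[i] += eps
        tm[i] -= eps
        bp, np_ = standardized_rate(tp)
        bm, nm = standardized_rate(tm)
        for r, s in enumerate(sex_names):
            grads[r, i] = (bp[s] - bm[s]) / (2 * eps)
        grads[-1, i] = (np_ - nm) / (2 * eps)
    from scipy import stats

    z = stats.norm.ppf(0.5 + level / 2)
    out = {"scenario": scenario.name, "horizon_year": scenario.horizon_year}
    cov = model.cov_params_
    for r, s in enumerate(sex_names):
        se = float(np.sqrt(max(grads[r] @ cov @ grads[r], 0.0)))
        out[s] = {"rate": by_sex[s], "ci": (by_sex[s] - z * se, by_sex[s] + z * se)}
    se = float(np.sqrt(max(grads[-1] @ cov @ grads[-1], 0.0)))
    out["national"] = {"rate": national, "ci": (national - z * se, national + z * se)}
    return out
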