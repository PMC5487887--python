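"""The birth-cohort (Styblo) incidence estimator.

From serial cross-sectional prevalences arranged on a Lexis grid, annual
incidence is recovered in three steps, per sex and 5-year age group:

1.  Each prevalence ``P`` observed at age-group midpoint ``a`` in survey
    year ``t`` implies a *mean annual disease-free probability* over the
    cohort's exposure of ``E = a - onset_age`` years:

        q_bar = (1 - P)^(1/E).

2.  For each age group, a straight line is fitted by ordinary least squares
    to ``ln q_bar`` against survey year; its slope ``beta`` is the secular
    trend of the log annual disease-free probability.

3.  ``q_bar`` is a geometric mean over exposure years centred ``(E - 1)/2``
    years before the survey, so the current-year disease-free probability is
    the trend-projected

        q_t = (1 - P)^(1/E) * exp(beta * (E - 1) / 2),

    and annual incidence is ``i = 1 - q_t``.  Negative estimates (possible
    under sampling noise or a strongly positive beta) are revised to zero
    and flagged.

When the true hazard is constant over age and log-linear in calendar time
— the model this method assumes — the three steps invert the cohort
survival product exactly, which the test-suite oracles exploit.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .lexis import AgePeriodMatrix, build_age_period_matrix, interpolate_annual, midpoint_age


class DegenerateCellWarning(UserWarning):
    pass


def mean_annual_disease_free_prob(P, exposure_years):
    """q_bar = (1 - P)^(1/E), the geometric-mean annual survival.

    ``P = 1`` is degenerate (q_bar = 0; its log transform is undefined
    downstream) and allowed here but flagged by the caller.
    """
    P = np.asarray(P, dtype=float)
    E = np.asarray(exposure_years, dtype=float)
    if np.any((P < 0) | (P > 1)):
        raise ValueError("prevalence must lie in [0, 1]")
    if np.any(E < 1):
        raise ValueError("exposure_years must be >= 1")
    with np.errstate(divide="ignore"):  # P = 1 -> q_bar = 0, degenerate
        return np.exp(np.log1p(-P) / E)


def fit_log_trend(years, q_bar, weights=None):
    """OLS slope/intercept of ln(q_bar) on calendar year.

    Returns ``(beta, intercept, n_used, rss)``.  Cells with q_bar <= 0 or
    NaN are excluded; with fewer than two distinct years the fit degrades
    to ``beta = 0`` anchored at the mean (callers flag this).
    """
    years = np.asarray(years, dtype=float)
    q_bar = np.asarray(q_bar, dtype=float)
    ok = np.isfinite(q_bar) & (q_bar > 0) & np.isfinite(years)
    years, q_bar = years[ok], q_bar[ok]
    w = None if weights is None else np.asarray(weights, dtype=float)[ok]
    n = len(years)
    if n == 0:
        return 0.0, np.nan, 0, np.nan
    y = np.log(q_bar)
    if len(np.unique(years)) < 2:
        return 0.0, float(np.mean(y)), n, 0.0
    X = np.column_stack([np.ones(n), years])
    if w is None:
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    else:
        sw = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    resid = y - X @ coef
    return float(coef[1]), float(coef[0]), n, float(resid @ resid)


def annual_incidence(P, exposure_years, beta, clamp: bool = True):
    """Current-year incidence from one prevalence cell and the fitted trend.

    Returns ``(incidence, clamped_flag)`` as arrays.  With ``clamp`` the
    negative estimates that a positive beta can produce are revised to zero
    and flagged; without it the raw value is returned.
    """
    P = np.asarray(P, dtype=float)
    E = np.asarray(exposure_years, dtype=float)
    beta = np.asarray(beta, dtype=float)
    q_t = np.exp(np.log1p(-P) / E + beta * (E - 1) / 2.0)
    i = 1.0 - q_t
    clamped = i < 0
    if clamp:
        i = np.where(clamped, 0.0, i)
    return i, clamped


class StybloIncidenceEstimator(BaseEstimator):
    """Annual incidence surface from serial prevalence surveys.

    A scikit-learn style estimator: ``fit`` consumes long-format prevalence
    cells (columns ``sex, age_group, survey_year, prevalence``), and the
    fitted surface is exposed both as attributes and via ``predict`` /
    ``annual_surface``.

    Parameters
    ----------
    onset_age : int
        Age at which disease risk is assumed to begin (exposure years
        ``E = midpoint age - onset_age``).  0 = from birth.
    midpoint_offset : int
        Representative age within a 5-year band (2 -> midpoints 27..62).
    clamp : bool
        Revise negative incidence estimates to zero (flagged).
    per : float
        Reporting scale; 1000 = per 1000 person-years.
    weight_by_n : bool
        Weight the trend OLS by each cell's sample size ``n`` if present.

    Attributes
    ----------
    trend_ : DataFrame
        Per (sex, age_group): beta, intercept, n_surveys, rss.
    surface_ : DataFrame
        Incidence per ``per`` person-years at the survey years, long format
        with a ``clamped`` flag.
    survey_years_ : ndarray
    """

    def __init__(self, onset_age: int = 0, midpoint_offset: int = 2,
                 clamp: bool = True, per: float = 1000.0,
                 weight_by_n: bool = False):
        self.onset_age = onset_age
        self.midpoint_offset = midpoint_offset
        self.clamp = clamp
        self.per = per
        self.weight_by_n = weight_by_n

    # -- fitting ------------------------------------------------------

    def fit(self, X: pd.DataFrame, y=None):
        matrix = (
            X
            if isinstance(X, AgePeriodMatrix)
            else build_age_period_matrix(X, midpoint_offset=self.midpoint_offset)
        )
        years = matrix.survey_years
        if len(years) < 2:
            raise ValueError(
                "incidence estimation requires prevalences from >= 2 survey years"
            )
        cells = matrix.cells.copy()
        cells["mid_age"] = cells["age_group"].map(
            lambda g: midpoint_age(g, self.midpoint_offset)
        )
        cells["exposure"] = cells["mid_age"] - self.onset_age
        if (cells["exposure"] < 1).any():
            raise ValueError("onset_age leaves an age group with exposure < 1 year")
        cells["q_bar"] = mean_annual_disease_free_prob(
            cells[matrix.value_col].fillna(np.nan), cells["exposure"]
        )

        trends = []
        for (sex, group), sub in cells.groupby(["sex", "age_group"], observed=False):
            w = sub["n"] if (self.weight_by_n and "n" in sub) else None
            beta, alpha, n_used, rss = fit_log_trend(
                sub["survey_year"], sub["q_bar"], weights=w
            )
            trends.append(
                {"sex": sex, "age_group": group, "beta": beta, "intercept": alpha,
                 "n_surveys": n_used, "rss": rss, "degenerate": n_used < 2}
            )
        self.trend_ = pd.DataFrame(trends)

        merged = cells.merge(self.trend_[["sex", "age_group", "beta"]],
                             on=["sex", "age_group"])
        inc, clamped = annual_incidence(
            merged[matrix.value_col], merged["exposure"], merged["beta"],
            clamp=self.clamp,
        )
        surface = merged[["sex", "age_group", "survey_year"]].copy()
        surface["incidence"] = inc * self.per
        surface["clamped"] = clamped
        self.surface_ = surface.sort_values(
            ["sex", "age_group", "survey_year"]
        ).reset_index(drop=True)
        self.survey_years_ = years
        self.value_col_ = matrix.value_col
        return self

    # -- prediction ---------------------------------------------------

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Incidence (per ``per`` person-years) for prevalence cells ``X``,
        using the trends learned in ``fit``."""
        self._check_fitted()
        df = X.copy()
        df["mid_age"] = df["age_group"].map(
            lambda g: midpoint_age(g, self.midpoint_offset)
        )
        df["exposure"] = df["mid_age"] - self.onset_age
        df = df.merge(self.trend_[["sex", "age_group", "beta"]],
                      on=["sex", "age_group"], how="left")
        if df["beta"].isna().any():
            raise ValueError("cells reference (sex, age group) strata unseen in fit")
        inc, _ = annual_incidence(df[self.value_col_], df["exposure"], df["beta"],
                                  clamp=self.clamp)
        return inc * self.per

    def annual_surface(self, years=None) -> pd.DataFrame:
        """Survey-year estimates plus linear interpolation for years between
        surveys (long format: sex, age_group, year, incidence)."""
        self._check_fitted()
        frames = []
        for (sex, group), sub in self.surface_.groupby(["sex", "age_group"],
                                                       observed=False):
            ok = sub["incidence"].notna()
            if ok.sum() < 2:
                continue
            series = interpolate_annual(
                sub.loc[ok, "survey_year"], sub.loc[ok, "incidence"], targets=years
            )
            frames.append(
                pd.DataFrame({"sex": sex, "age_group": group,
                              "year": series.index, "incidence": series.values})
            )
        return pd.concat(frames, ignore_index=True)

    def _check_fitted(self):
        if not hasattr(self, "surface_"):
            raise AttributeError("estimator is not fitted; call fit() first")


def incidence_surface(cells: pd.DataFrame, onset_age: int = 0, **params) -> pd.DataFrame:
    """Functional wrapper: prevalence cells -> incidence surface (long CSV
    shape), via :class:`StybloIncidenceEstimator`."""
    est = StybloIncidenceEstimator(onset_age=onset_age, **params)
    return est.fit(cells).surface_
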