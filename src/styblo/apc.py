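"""Age-period and age-cohort Poisson deviance analysis of incident counts.

Counts on a 5-year age x 5-year period (or birth-cohort) grid are modeled
log-linearly with a log person-years offset, all terms categorical.  The
analysis of interest is the sequence of deviance drops: null -> age ->
age + period, and separately null -> age -> age + cohort; period and
cohort are never entered together (the linear dependency age + cohort =
period makes the joint model unidentifiable).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm


@dataclass
class APCFit:
    terms: tuple[str, ...]
    deviance: float
    df_resid: int
    params: pd.Series
    aic: float
    data_id: int = field(repr=False, default=0)

    @property
    def label(self) -> str:
        return " + ".join(self.terms) if self.terms else "null"


_ALLOWED = {"age", "period", "cohort"}


def fit_poisson_apc(data: pd.DataFrame, terms=()) -> APCFit:
    """Poisson GLM of ``count`` with log ``population`` offset.

    ``data`` needs columns ``count``, ``population`` and a categorical
    column per requested term (``age``, ``period``, ``cohort``).
    Requesting period and cohort together is refused (identifiability).
    """
    terms = tuple(terms)
    bad = set(terms) - _ALLOWED
    if bad:
        raise ValueError(f"unknown model term(s): {sorted(bad)}")
    if "period" in terms and "cohort" in terms:
        raise ValueError("period and cohort cannot be entered jointly "
                         "(age + cohort = period: not identifiable)")
    for col in ("count", "population") + terms:
        if col not in data.columns:
            raise ValueError(f"data lacks column {col!r}")
    if (data["population"] <= 0).any():
        raise ValueError("populations must be positive for the offset")

    X = pd.DataFrame(index=data.index)
    X["const"] = 1.0
    for t in terms:
        dummies = pd.get_dummies(data[t].astype("category"), prefix=t,
                                 drop_first=True, dtype=float)
        X = pd.concat([X, dummies], axis=1)
    model = sm.GLM(
        data["count"].to_numpy(dtype=float),
        X,
        family=sm.families.Poisson(),
        offset=np.log(data["population"].to_numpy(dtype=float)),
    )
    res = model.fit()
    return APCFit(
        terms=terms,
        deviance=float(res.deviance),
        df_resid=int(res.df_resid),
        params=res.params,
        aic=float(res.aic),
        data_id=id(data),
    )


def deviance_table(fits: list[APCFit]) -> pd.DataFrame:
    """Ordered comparison of deviance drops between successive nested fits.

    Fits must share the same data.  Non-nested successive pairs are kept in
    the table but flagged with ``nested = False`` and no drop is reported
    for them.
    """
    if len({f.data_id for f in fits}) > 1:
        raise ValueError("fits were made on different data")
    rows = []
    prev = None
    for f in fits:
        nested = prev is not None and set(prev.terms) <= set(f.terms)
        rows.append(
            {
                "model": f.label,
                "deviance": f.deviance,
                "df_resid": f.df_resid,
                "aic": f.aic,
                "nested_in_previous": bool(nested),
                "deviance_drop": (prev.deviance - f.deviance) if nested else np.nan,
                "df_drop": (prev.df_resid - f.df_resid) if nested else np.nan,
            }
        )
        prev = f
    return pd.DataFrame(rows)


def apc_analysis(data: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """The standard ladder: null/age/age+period and null/age/age+cohort."""
    null = fit_poisson_apc(data, ())
    age = fit_poisson_apc(data, ("age",))
    out = {}
    if "period" in data.columns:
        ap = fit_poisson_apc(data, ("age", "period"))
        out["age_period"] = deviance_table([null, age, ap])
    if "cohort" in data.columns:
        ac = fit_poisson_apc(data, ("age", "cohort"))
        out["age_cohort"] = deviance_table([null, age, ac])
    return out
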