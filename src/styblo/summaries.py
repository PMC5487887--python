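"""Direct age standardization, cumulative risk, incident-count arithmetic."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .hazard import AGE_GROUP_LABELS
from .weighting import binomial_ci

_WEIGHT_TOL = 1e-9


def standard_population(census: pd.DataFrame, by_sex: bool = False):
    """Reference age distribution (proportions) from a census table.

    Returns a Series indexed by age group (proportions summing to 1), or,
    with ``by_sex``, a DataFrame indexed by (sex, age_group) whose
    proportions sum to 1 within each sex.
    """
    if by_sex:
        counts = census.groupby(["sex", "age_group"], observed=False)["count"].sum()
        return counts / counts.groupby(level="sex").transform("sum")
    counts = census.groupby("age_group", observed=False)["count"].sum()
    return counts / counts.sum()


def age_standardize(rates, standard, ns=None, level: float = 0.95, per: float = 1000.0):
    """Directly age-standardized rate: sum of w_a * r_a over the eight bands.

    ``rates`` and ``standard`` are aligned by age-group label (Series or
    arrays in band order).  Standard proportions must sum to 1 (tolerance
    1e-9).  With cell sample sizes ``ns`` a binomial normal-approximation
    CI is attached; otherwise only the rate is returned.
    """
    rates = pd.Series(rates) if not isinstance(rates, pd.Series) else rates
    standard = pd.Series(standard) if not isinstance(standard, pd.Series) else standard
    if isinstance(rates.index, pd.RangeIndex) and len(rates) == len(AGE_GROUP_LABELS):
        rates.index = list(AGE_GROUP_LABELS)
    if isinstance(standard.index, pd.RangeIndex) and len(standard) == len(AGE_GROUP_LABELS):
        standard.index = list(AGE_GROUP_LABELS)
    if abs(standard.sum() - 1.0) > _WEIGHT_TOL:
        raise ValueError(f"standard proportions sum to {standard.sum():.12f}, not 1")
    missing = standard.index.difference(rates.dropna().index)
    if len(missing):
        raise ValueError(f"rates missing for age group(s): {list(missing)}")
    aligned = rates.reindex(standard.index)
    rate = float((aligned * standard).sum())
    if ns is None:
        return rate
    ns = pd.Series(ns).reindex(standard.index)
    if ns.isna().any() or (ns <= 0).any():
        return rate, (float("nan"), float("nan"))
    p = aligned / per
    var = float((standard**2 * p * (1 - p) / ns).sum())
    from scipy import stats

    z = stats.norm.ppf(0.5 + level / 2)
    half = z * math.sqrt(var) * per
    return rate, (max(0.0, rate - half), rate + half)


def cumulative_risk(age_specific_rates, mode: str = "as_published",
                    ages_per_interval: float = 5.0, per: float = 1000.0) -> float:
    """Cumulative risk (%) over 25-64 from the eight age-specific rates.

    ``mode="as_published"`` accumulates each 5-year band's *annual* rate
    once, ``x = sum(r_a) / per``, which is the rule that reproduces the
    published summary rows; ``mode="formula"`` applies the textbook
    person-years form ``x = sum(r_a * n_a) / per`` with ``n_a`` ages per
    band.  Both return ``(1 - exp(-x)) * 100``.
    """
    rates = np.asarray(pd.Series(age_specific_rates), dtype=float)
    if len(rates) != len(AGE_GROUP_LABELS):
        raise ValueError(f"expected {len(AGE_GROUP_LABELS)} age-group rates")
    if np.any(np.isnan(rates)):
        raise ValueError("age-specific rates contain NaN")
    if np.any(rates < 0):
        raise ValueError("negative rate: clamp incidence before cumulative risk")
    if mode == "as_published":
        x = rates.sum() / per
    elif mode == "formula":
        x = (rates * ages_per_interval).sum() / per
    else:
        raise ValueError(f"unknown cumulative-risk mode {mode!r}")
    return float(-np.expm1(-x) * 100.0)


def incident_counts(rate: float, population: float, per: float = 1000.0):
    """Incident cases implied by a rate and a population.

    Returns ``(rounded, exact)``: the reporting value rounds half-up to an
    integer; the unrounded value is retained for chained computations.
    """
    if rate < 0 or population < 0:
        raise ValueError("rate and population must be non-negative")
    exact = rate / per * population
    return int(math.floor(exact + 0.5)), float(exact)


def combine_sexes(rates_by_sex: pd.DataFrame, census: pd.DataFrame) -> pd.Series:
    """Population-weighted both-sex age-specific rates.

    ``rates_by_sex``: DataFrame indexed by age group with one column per
    sex.  Weights are the census sex split within each age group.
    """
    counts = census.groupby(["sex", "age_group"], observed=False)["count"].sum().unstack(0)
    counts = counts.reindex(rates_by_sex.index)
    w = counts.div(counts.sum(axis=1), axis=0)
    return (rates_by_sex * w[rates_by_sex.columns]).sum(axis=1)


def summary_table(surface: pd.DataFrame, standard, census: pd.DataFrame | None = None,
                  per: float = 1000.0) -> pd.DataFrame:
    """Assemble the reporting table: age-specific rows per survey year, an
    age-standardized row and a cumulative-risk row, per sex (and pooled
    when a census provides the sex split)."""
    out = []
    for sex, sub in surface.groupby("sex", observed=False):
        mat = sub.pivot(index="age_group", columns="survey_year", values="incidence")
        mat = mat.reindex(list(AGE_GROUP_LABELS))
        if isinstance(standard, dict):
            std = standard[sex]
        elif isinstance(standard, pd.Series) and isinstance(standard.index, pd.MultiIndex):
            std = standard.xs(sex, level="sex")
        else:
            std = standard
        block = mat.copy()
        block.loc["age-standardized"] = [
            age_standardize(mat[c], std, per=per) for c in mat.columns
        ]
        block.loc["cumulative risk %"] = [
            cumulative_risk(mat[c], per=per) for c in mat.columns
        ]
        block.insert(0, "sex", sex)
        out.append(block.reset_index(names="row"))
    table = pd.concat(out, ignore_index=True)
    return table
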