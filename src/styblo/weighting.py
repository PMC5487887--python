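"""Census post-stratification weights and weighted prevalence.

Case weights make the survey's joint region x sex x 5-year age-group
distribution match the nearest previous census:

    w(stratum) = census proportion / survey proportion.

Weighted prevalence within each (sex, age group) cell is the
weight-weighted case proportion; confidence intervals use the unweighted
cell size with the textbook binomial normal approximation (Clopper-Pearson
exact bounds available behind ``method="exact"``).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .records import case_status, with_age_groups

STRATA = ["region", "sex", "age_group"]


def compute_case_weights(survey: pd.DataFrame, census: pd.DataFrame) -> pd.DataFrame:
    """Post-stratification weight table over region x sex x age group.

    Returns one row per census stratum with columns ``census_count``,
    ``survey_count``, ``weight`` and ``covered``.  Strata present in the
    census but unsampled get ``covered=False`` and no weight (they are
    surfaced, not silently reweighted).  Survey strata absent from the
    census are a hard error: the census must partition the survey.
    """
    survey = with_age_groups(survey) if "age_group" not in survey.columns else survey
    counts = survey.groupby(STRATA, observed=False).size().rename("survey_count")
    table = (
        census.groupby(STRATA, observed=False)["count"].sum().rename("census_count").reset_index()
    )
    table = table.merge(counts.reset_index(), how="outer", on=STRATA)
    orphans = table["census_count"].isna()
    if orphans.any():
        bad = table.loc[orphans, STRATA].to_records(index=False)
        raise ValueError(f"survey strata missing from census: {list(bad)[:5]}")
    table["survey_count"] = table["survey_count"].fillna(0).astype(int)

    n_census = table["census_count"].sum()
    n_survey = table["survey_count"].sum()
    cprop = table["census_count"] / n_census
    sprop = table["survey_count"] / n_survey
    with np.errstate(divide="ignore", invalid="ignore"):
        table["weight"] = np.where(table["survey_count"] > 0, cprop / sprop, np.nan)
    table["covered"] = (table["survey_count"] > 0) | (table["census_count"] == 0)
    return table


def attach_weights(survey: pd.DataFrame, weights: pd.DataFrame) -> pd.DataFrame:
    """Merge the stratum case weights onto unit records as ``case_weight``
    (distinct from the records' body-weight column)."""
    survey = with_age_groups(survey) if "age_group" not in survey.columns else survey.copy()
    wtab = weights[STRATA + ["weight"]].rename(columns={"weight": "case_weight"})
    merged = survey.merge(wtab, how="left", on=STRATA)
    if merged["case_weight"].isna().any():
        raise ValueError("record maps to a stratum without a weight")
    return merged


def binomial_ci(p: float, n: int, level: float = 0.95, method: str = "normal"):
    """Binomial CI for a proportion; ``(nan, nan)`` marker when n = 0."""
    if not 0 <= p <= 1:
        raise ValueError("p must lie in [0, 1]")
    if n <= 0:
        return (float("nan"), float("nan"))
    if method == "normal":
        z = stats.norm.ppf(0.5 + level / 2)
        half = z * np.sqrt(p * (1 - p) / n)
        return (max(0.0, p - half), min(1.0, p + half))
    if method == "exact":
        k = p * n
        lo = 0.0 if k <= 0 else stats.beta.ppf((1 - level) / 2, k, n - k + 1)
        hi = 1.0 if k >= n else stats.beta.ppf(0.5 + level / 2, k + 1, n - k)
        return (float(lo), float(hi))
    raise ValueError(f"unknown CI method {method!r}")


def adjusted_prevalence(
    survey: pd.DataFrame,
    weights: pd.DataFrame | None = None,
    by=("sex", "age_group"),
    level: float = 0.95,
    ci_method: str = "normal",
) -> pd.DataFrame:
    """Census-weighted prevalence cells by (sex, age group).

    Records with indeterminable case status (no FPG, not on medication) are
    excluded from numerator and denominator.  Cells with no informative
    records are emitted with NaN prevalence and n = 0, never dropped.
    Output columns: the grouping keys, ``survey_year``, ``prevalence``,
    ``n``, ``ci_low``, ``ci_high``.
    """
    df = with_age_groups(survey) if "age_group" not in survey.columns else survey.copy()
    if weights is not None and "case_weight" not in df.columns:
        df = attach_weights(df, weights)
    if "case_weight" not in df.columns:
        df["case_weight"] = 1.0
    status = case_status(df)
    df["case"] = status.astype("float")  # NA -> NaN
    known = df[status.notna()].copy()

    year = int(df["survey_year"].iloc[0]) if len(df) else -1
    from .hazard import AGE_GROUP_LABELS, SEXES

    full_index = pd.MultiIndex.from_product(
        [SEXES, AGE_GROUP_LABELS], names=list(by)
    ) if tuple(by) == ("sex", "age_group") else None

    known["wc"] = known["case_weight"] * known["case"]
    grouped = known.groupby(list(by), observed=False)
    num = grouped["wc"].sum()
    den = grouped["case_weight"].sum()
    n = grouped.size()
    out = pd.DataFrame({"num": num, "den": den, "n": n})
    if full_index is not None:
        out = out.reindex(full_index)
    out["n"] = out["n"].fillna(0).astype(int)
    with np.errstate(invalid="ignore", divide="ignore"):
        out["prevalence"] = out["num"] / out["den"]
    cis = [
        binomial_ci(p, nn, level, ci_method) if nn > 0 and np.isfinite(p) else (np.nan, np.nan)
        for p, nn in zip(out["prevalence"], out["n"])
    ]
    out["ci_low"] = [c[0] for c in cis]
    out["ci_high"] = [c[1] for c in cis]
    out = out.drop(columns=["num", "den"]).reset_index()
    out.insert(len(by), "survey_year", year)
    return out


def pooled_prevalence(surveys_with_census: list[tuple[pd.DataFrame, pd.DataFrame]],
                      **kwargs) -> pd.DataFrame:
    """Pool same-year surveys: concatenate records, weight each survey to its
    own census, then compute one prevalence cell set from the stacked
    weighted records (each survey's weights already integrate to its census
    distribution, so stacking preserves representativeness)."""
    frames = []
    for survey, census in surveys_with_census:
        w = compute_case_weights(survey, census)
        frames.append(attach_weights(survey, w))
    stacked = pd.concat(frames, ignore_index=True)
    return adjusted_prevalence(stacked, weights=None, **kwargs)
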