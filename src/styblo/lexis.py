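"""Age-period (Lexis) matrices, birth-cohort tracing, annual interpolation.

Prevalence cells are arranged on a grid of 5-year age groups by survey
years, one matrix per sex.  Birth cohorts run along the diagonals: a cell
at age-group midpoint ``a_mid`` observed in year ``t`` belongs to cohort
``b = t - a_mid``.  Values for years between irregularly spaced surveys are
obtained by linear interpolation on the rate scale between adjacent
surveys; extrapolation beyond the survey span is deliberately refused here
(projection is a modelling step, not an interpolation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hazard import AGE_GROUP_LABELS

#: Representative (midpoint) age offset within a 5-year band: 25-29 -> 27.
MIDPOINT_OFFSET = 2


def midpoint_age(age_group: str, offset: int = MIDPOINT_OFFSET) -> int:
    return int(age_group.split("-")[0]) + offset


@dataclass
class AgePeriodMatrix:
    """Prevalence (or rate) cells on an age-group x survey-year grid, per sex.

    ``cells`` is long format with columns sex, age_group, survey_year and a
    value column; the class guarantees at most one cell per (sex, age group,
    year) and exposes pivoting and cohort tracing.
    """

    cells: pd.DataFrame
    value_col: str = "prevalence"
    midpoint_offset: int = MIDPOINT_OFFSET

    def __post_init__(self):
        keys = ["sex", "age_group", "survey_year"]
        if self.cells.duplicated(keys).any():
            dupes = self.cells[self.cells.duplicated(keys, keep=False)]
            raise ValueError(
                f"duplicate (sex, age group, year) cells:\n{dupes[keys].head()}"
            )
        self.cells = self.cells.sort_values(keys).reset_index(drop=True)

    @property
    def survey_years(self) -> np.ndarray:
        return np.unique(self.cells["survey_year"])

    @property
    def sexes(self) -> list[str]:
        return sorted(self.cells["sex"].unique())

    def pivot(self, sex: str) -> pd.DataFrame:
        sub = self.cells[self.cells["sex"] == sex]
        mat = sub.pivot(index="age_group", columns="survey_year", values=self.value_col)
        return mat.reindex([g for g in AGE_GROUP_LABELS if g in mat.index])

    def midpoints(self) -> pd.Series:
        groups = self.cells["age_group"].unique()
        return pd.Series({g: midpoint_age(g, self.midpoint_offset) for g in sorted(groups)})

    def birth_cohorts(self) -> pd.Series:
        """Cohort index b = survey year - midpoint age, one per cell."""
        mids = self.cells["age_group"].map(lambda g: midpoint_age(g, self.midpoint_offset))
        return self.cells["survey_year"] - mids

    def cohort_series(self, sex: str, birth_cohort: int) -> pd.DataFrame:
        """Ordered (age, year, value) triples sharing a birth-cohort index."""
        cells = self.cells[self.cells["sex"] == sex].copy()
        cells["mid_age"] = cells["age_group"].map(
            lambda g: midpoint_age(g, self.midpoint_offset)
        )
        cells["cohort"] = cells["survey_year"] - cells["mid_age"]
        out = cells[cells["cohort"] == birth_cohort].sort_values("survey_year")
        return out[["mid_age", "survey_year", self.value_col]].reset_index(drop=True)

    def missing_cells(self) -> pd.DataFrame:
        """Grid gaps (flagged, not an error: surveys may miss strata)."""
        full = pd.MultiIndex.from_product(
            [self.sexes, sorted(self.cells["age_group"].unique()), self.survey_years],
            names=["sex", "age_group", "survey_year"],
        )
        have = pd.MultiIndex.from_frame(self.cells[["sex", "age_group", "survey_year"]])
        gaps = full.difference(have).to_frame(index=False)
        nan_cells = self.cells[self.cells[self.value_col].isna()]
        return pd.concat([gaps, nan_cells[["sex", "age_group", "survey_year"]]],
                         ignore_index=True)


def build_age_period_matrix(
    cells: pd.DataFrame, value_col: str = "prevalence",
    midpoint_offset: int = MIDPOINT_OFFSET,
) -> AgePeriodMatrix:
    """Validate and wrap long-format prevalence cells into a Lexis matrix."""
    required = {"sex", "age_group", "survey_year", value_col}
    missing = required - set(cells.columns)
    if missing:
        raise ValueError(f"cells missing column(s): {sorted(missing)}")
    return AgePeriodMatrix(cells=cells.copy(), value_col=value_col,
                           midpoint_offset=midpoint_offset)


def interpolate_annual(years, values, targets=None):
    """Linear interpolation between adjacent survey years, exact at knots.

    Returns a Series indexed by year covering every integer year from the
    first to the last survey (or the requested ``targets``).  Requests
    outside the survey span raise: extrapolation belongs to the projection
    module, not here.
    """
    years = np.asarray(years, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(years) < 2:
        raise ValueError("interpolation requires at least two survey years")
    order = np.argsort(years)
    years, values = years[order], values[order]
    if np.any(np.diff(years) == 0):
        raise ValueError("duplicate survey years; pool them before interpolation")
    if targets is None:
        targets = np.arange(int(years[0]), int(years[-1]) + 1)
    targets = np.atleast_1d(np.asarray(targets, dtype=float))
    if targets.min() < years[0] or targets.max() > years[-1]:
        raise ValueError(
            f"interpolation request outside [{years[0]:.0f}, {years[-1]:.0f}]"
        )
    out = np.interp(targets, years, values)
    return pd.Series(out, index=targets.astype(int), name="value")
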