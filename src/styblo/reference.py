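"""Published Samoan T2DM incidence estimates, 1978-2013, as reference inputs.

These are the printed summary numbers of the Samoan serial-survey incidence
analysis: age-specific and age-standardized annual incidence per 1000
person-years by sex and survey year, cumulative-risk rows, census
populations, and the 2020 BMI-scenario projections.  The underlying survey
microdata were never deposited, so these tables serve two roles here:

* inputs to arithmetic that is closed over printed values (cumulative risk
  from the age-specific rows, interpolation of the 1993 rates, incident
  case counts from census populations, scenario rate differences), used to
  validate the corresponding package operations;
* reference magnitudes for the synthetic study configuration.
"""

from __future__ import annotations

import pandas as pd

from .hazard import AGE_GROUP_LABELS

SURVEY_YEARS = (1978, 1991, 1995, 2002, 2003, 2010, 2013)

#: Age-specific annual T2DM incidence per 1000 person-years (printed values).
_AGE_SPECIFIC = {
    "male": [
        [3.15, 2.41, 2.19, 1.80, 1.74, 1.36, 1.19],
        [0.00, 0.97, 2.52, 5.32, 5.73, 8.67, 9.97],
        [1.30, 2.74, 3.19, 4.00, 4.11, 4.94, 5.30],
        [0.37, 2.85, 3.65, 5.09, 5.30, 6.81, 7.47],
        [1.24, 5.65, 7.11, 9.80, 10.20, 13.12, 14.44],
        [2.09, 5.45, 6.56, 8.61, 8.91, 11.12, 12.12],
        [3.84, 6.45, 7.32, 8.90, 9.13, 10.84, 11.60],
        [4.36, 7.46, 8.50, 10.41, 10.70, 12.79, 13.74],
    ],
    "female": [
        [3.48, 2.74, 2.52, 2.13, 2.07, 1.69, 1.52],
        [0.98, 2.18, 2.56, 3.23, 3.33, 4.01, 4.31],
        [1.01, 2.08, 2.42, 3.02, 3.11, 3.72, 3.99],
        [2.76, 4.80, 5.46, 6.63, 6.80, 8.01, 8.54],
        [2.02, 4.44, 5.23, 6.65, 6.86, 8.36, 9.03],
        [2.39, 5.58, 6.63, 8.56, 8.84, 10.92, 11.85],
        [3.95, 6.80, 7.74, 9.47, 9.73, 11.61, 12.45],
        [7.01, 9.52, 10.34, 11.87, 12.10, 13.75, 14.50],
    ],
    "national": [
        [2.92, 2.27, 2.07, 1.72, 1.67, 1.33, 1.19],
        [1.52, 3.08, 3.57, 4.44, 4.56, 5.45, 5.83],
        [0.66, 1.94, 2.34, 3.06, 3.16, 3.89, 4.21],
        [0.28, 2.85, 3.67, 5.16, 5.38, 6.93, 7.61],
        [1.56, 4.59, 5.58, 7.39, 7.65, 9.58, 10.45],
        [2.00, 5.31, 6.40, 8.41, 8.71, 10.88, 11.86],
        [2.77, 5.89, 6.93, 8.84, 9.13, 11.21, 12.15],
        [3.71, 7.40, 8.64, 10.97, 11.31, 13.89, 15.08],
    ],
}

#: Age-standardized 25-64 annual incidence per 1000 person-years.
STANDARDIZED = pd.DataFrame(
    {
        "male": [1.12, 3.61, 4.43, 5.92, 6.14, 7.73, 8.44],
        "female": [2.55, 4.08, 4.58, 5.48, 5.61, 6.57, 7.00],
        "national": [1.74, 3.62, 4.24, 5.36, 5.52, 6.72, 7.25],
    },
    index=pd.Index(SURVEY_YEARS, name="survey_year"),
)

#: Printed cumulative-risk rows (%), for comparison with recomputation.
CUMULATIVE_RISK = pd.DataFrame(
    {
        "male": [1.24, 3.34, 4.02, 5.25, 5.43, 6.73, 7.30],
        "female": [2.33, 3.74, 4.20, 5.03, 5.15, 6.02, 6.41],
        "national": [1.53, 3.28, 3.84, 4.88, 5.03, 6.12, 6.61],
    },
    index=pd.Index(SURVEY_YEARS, name="survey_year"),
)

#: Census 25-64 populations: 1976 and 2011 censuses, 2020 projection.
CENSUS_POPULATION = {1976: 42_639, 2011: 71_968, 2020: 75_045}

#: 2020 scenario projections, age-standardized per 1000 person-years.
SCENARIO_2020 = pd.DataFrame(
    {
        "male": [10.18, 13.87, 13.16, 12.75, 12.34, 11.95, 11.58,
                 13.59, 14.03, 14.49, 14.96],
        "female": [8.04, 11.60, 10.61, 10.23, 9.87, 9.51, 9.17,
                   11.01, 11.42, 11.84, 12.28],
        "national": [8.56, 12.74, 11.89, 11.50, 11.11, 10.74, 10.38,
                     12.30, 12.73, 13.17, 13.63],
    },
    index=pd.Index(
        ["period_trend", "bmi_trend", "frozen_2013",
         "minus_1kg", "minus_2kg", "minus_3kg", "minus_4kg",
         "plus_1kg", "plus_2kg", "plus_3kg", "plus_4kg"],
        name="scenario",
    ),
)

#: Mean measured body weight (kg) in the 2013 survey, by sex.
MEAN_WEIGHT_2013 = {"male": 93.6, "female": 90.7}

#: External-validation cohort: annualized 1991-1995 incidence, both sexes.
COHORT_1991_1995_RATE = 5.3


def age_specific_rates(sex: str) -> pd.DataFrame:
    """Printed age-specific rates as an age-group x survey-year frame."""
    return pd.DataFrame(
        _AGE_SPECIFIC[sex], index=list(AGE_GROUP_LABELS), columns=list(SURVEY_YEARS)
    )
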