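import numpy as np
import pandas as pd
import pytest

import styblo as st
from styblo.lexis import midpoint_age


@pytest.fixture(scope="session")
def constant_surface():
    return st.HazardSurface.constant(0.005)


@pytest.fixture(scope="session")
def trend_surface():
    """Log-linear period trend, age-constant: the estimator's exact regime."""
    return st.HazardSurface.loglinear(0.012, -1.0e-4, 2013)


SURVEY_YEARS = (1978, 1991, 1995, 2002, 2003, 2010, 2013)


def noise_free_cells(surface, years=SURVEY_YEARS, onset_age=0):
    """Exact prevalence cells at the age-group midpoints (no sampling)."""
    rows = []
    for sex in st.SEXES:
        for g in st.AGE_GROUP_LABELS:
            mid = midpoint_age(g)
            for t in years:
                rows.append(
                    dict(sex=sex, age_group=g, survey_year=t,
                         prevalence=st.closed_form_prevalence(
                             surface, sex, mid, t, onset_age=onset_age))
                )
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def small_population(constant_surface):
    return st.simulate_population(
        constant_surface, n_per_cohort=60, seed=11,
        birth_years=np.arange(1945, 1986), last_year=2010,
    )
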