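import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

import styblo as st
from styblo.weighting import (adjusted_prevalence, attach_weights, binomial_ci,
                              compute_case_weights)


def _survey(strata_counts, year=2002):
    """Minimal survey frame: strata_counts maps (region, sex, age_group) -> n."""
    rows = []
    for (region, sex, group), n in strata_counts.items():
        age = int(group.split("-")[0]) + 1
        for _ in range(n):
            rows.append(dict(survey_year=year, sex=sex, age=age, region=region,
                             fasting_confirmed=True, fpg=5.0, on_medication=False,
                             pregnant=False, weight=np.nan, height=np.nan,
                             age_group=group))
    return pd.DataFrame(rows)


def _census(strata_counts):
    return pd.DataFrame(
        [dict(region=r, sex=s, age_group=g, count=n)
         for (r, s, g), n in strata_counts.items()]
    )


def test_weight_ratio_simple():
    # census proportion 0.10 vs survey proportion 0.05 -> weight 2.0
    survey = _survey({("a", "male", "25-29"): 5, ("b", "male", "30-34"): 95})
    census = _census({("a", "male", "25-29"): 100, ("b", "male", "30-34"): 900})
    w = compute_case_weights(survey, census).set_index("region")["weight"]
    assert w["a"] == pytest.approx(2.0)


def test_identical_distribution_gives_unit_weights():
    survey = _survey({("a", "male", "25-29"): 30, ("a", "female", "25-29"): 70})
    census = _census({("a", "male", "25-29"): 300, ("a", "female", "25-29"): 700})
    w = compute_case_weights(survey, census)
    assert np.allclose(w["weight"], 1.0)


def test_two_stratum_toy_weights_and_shares():
    # census 60/40, survey 30/70 -> weights 2.0 and 0.5714...
    survey = _survey({("a", "male", "25-29"): 30, ("b", "male", "25-29"): 70})
    census = _census({("a", "male", "25-29"): 60, ("b", "male", "25-29"): 40})
    w = compute_case_weights(survey, census).set_index("region")["weight"]
    assert w["a"] == pytest.approx(2.0)
    assert w["b"] == pytest.approx(4 / 7)
    # weighted stratum shares reproduce the census exactly
    merged = attach_weights(survey, w.reset_index().assign(
        sex="male", age_group="25-29"))
    shares = merged.groupby("region")["case_weight"].sum() / merged["case_weight"].sum()
    assert shares["a"] == pytest.approx(0.6)
    assert shares["b"] == pytest.approx(0.4)


def test_uncovered_stratum_flagged_not_imputed():
    survey = _survey({("a", "male", "25-29"): 10})
    census = _census({("a", "male", "25-29"): 50, ("b", "male", "25-29"): 50})
    w = compute_case_weights(survey, census)
    row = w[w["region"] == "b"].iloc[0]
    assert not row["covered"] and np.isnan(row["weight"])


def test_survey_stratum_missing_from_census_is_error():
    survey = _survey({("zzz", "male", "25-29"): 10})
    census = _census({("a", "male", "25-29"): 50})
    with pytest.raises(ValueError, match="missing from census"):
        compute_case_weights(survey, census)


def test_weighted_prevalence_toy():
    # two regions: cases 1/10 and 5/10, weights 2 and 1 -> P = 7/30
    survey = _survey({("a", "female", "30-34"): 10, ("b", "female", "30-34"): 10})
    survey.loc[survey["region"] == "a", "fpg"] = [8.0] + [5.0] * 9
    survey.loc[survey["region"] == "b", "fpg"] = [8.0] * 5 + [5.0] * 5
    weights = pd.DataFrame(
        [dict(region="a", sex="female", age_group="30-34", weight=2.0),
         dict(region="b", sex="female", age_group="30-34", weight=1.0)]
    )
    cells = adjusted_prevalence(survey, weights)
    cell = cells[(cells["sex"] == "female") & (cells["age_group"] == "30-34")]
    assert cell["prevalence"].iloc[0] == pytest.approx(7 / 30)
    assert cell["n"].iloc[0] == 20


def test_unit_weights_give_crude_proportion():
    survey = _survey({("a", "male", "40-44"): 20})
    survey.loc[survey.index[:7], "fpg"] = 9.0
    cells = adjusted_prevalence(survey)
    cell = cells[(cells["sex"] == "male") & (cells["age_group"] == "40-44")]
    assert cell["prevalence"].iloc[0] == pytest.approx(7 / 20)


def test_empty_cell_emitted_with_nan():
    survey = _survey({("a", "male", "40-44"): 5})
    cells = adjusted_prevalence(survey)
    empty = cells[(cells["sex"] == "female") & (cells["age_group"] == "25-29")]
    assert len(empty) == 1
    assert np.isnan(empty["prevalence"].iloc[0]) and empty["n"].iloc[0] == 0


def test_binomial_ci_normal_approximation():
    lo, hi = binomial_ci(0.5, 100)
    assert hi - 0.5 == pytest.approx(1.959964 * np.sqrt(0.25 / 100), abs=1e-6)
    assert (lo, hi) == (pytest.approx(0.402, abs=1e-3), pytest.approx(0.598, abs=1e-3))


def test_binomial_ci_degenerate_and_truncation():
    assert binomial_ci(0.0, 50) == (0.0, 0.0)
    lo, hi = binomial_ci(0.99, 10)
    assert hi <= 1.0 and lo >= 0.0
    assert binomial_ci(0.3, 0) == (pytest.approx(np.nan, nan_ok=True),) * 2


def test_wider_level_wider_interval():
    lo95, hi95 = binomial_ci(0.3, 200, level=0.95)
    lo99, hi99 = binomial_ci(0.3, 200, level=0.99)
    assert lo99 < lo95 and hi99 > hi95


def test_exact_ci_contains_point_estimate():
    lo, hi = binomial_ci(0.2, 50, method="exact")
    assert lo < 0.2 < hi


@settings(max_examples=30, deadline=None, derandomize=True)
@given(scale=hst.floats(min_value=0.1, max_value=10.0))
def test_prevalence_invariant_to_weight_rescaling(scale):
    survey = _survey({("a", "male", "40-44"): 10, ("b", "male", "40-44"): 10})
    survey.loc[survey["region"] == "a", "fpg"] = [9.0] * 3 + [5.0] * 7
    weights = pd.DataFrame(
        [dict(region="a", sex="male", age_group="40-44", weight=2.0 * scale),
         dict(region="b", sex="male", age_group="40-44", weight=1.0 * scale)]
    )
    base = pd.DataFrame(
        [dict(region="a", sex="male", age_group="40-44", weight=2.0),
         dict(region="b", sex="male", age_group="40-44", weight=1.0)]
    )
    a = adjusted_prevalence(survey, weights)["prevalence"]
    b = adjusted_prevalence(survey, base)["prevalence"]
    assert np.allclose(a.dropna(), b.dropna())


def test_weighted_beats_crude_under_biased_sampling():
    """Across seeds, census weighting moves prevalence toward the truth when
    older (higher-prevalence) strata are oversampled."""
    from styblo.records import case_status, with_age_groups
    from styblo.simulate import simulate_survey

    surface = st.HazardSurface.constant(0.008)
    pop = st.simulate_population(surface, n_per_cohort=400, seed=21,
                                 birth_years=np.arange(1941, 1981),
                                 last_year=2005)
    truth = pop.true_prevalence(2005)
    fractions = {"60-64": 0.8, "55-59": 0.8, "default": 0.08}
    crude_err, weighted_err = [], []
    for seed in range(20):
        sv = simulate_survey(pop, 2005, sampling_fractions=fractions, seed=seed)
        recs = with_age_groups(sv.records)
        crude = case_status(recs).astype(float).mean()
        w = compute_case_weights(recs, sv.census)
        merged = attach_weights(recs, w)
        status = case_status(merged).astype(float)
        weighted = (merged["case_weight"] * status).sum() / merged["case_weight"].sum()
        crude_err.append(abs(crude - truth))
        weighted_err.append(abs(weighted - truth))
    assert np.mean(weighted_err) < np.mean(crude_err)
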