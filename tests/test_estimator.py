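import numpy as np
import pandas as pd
import pytest

import styblo as st
from styblo.estimator import (StybloIncidenceEstimator, annual_incidence,
                              fit_log_trend, mean_annual_disease_free_prob)
from styblo.lexis import midpoint_age

from conftest import SURVEY_YEARS, noise_free_cells


class TestMeanAnnualDiseaseFreeProb:
    def test_zero_prevalence(self):
        assert mean_annual_disease_free_prob(0.0, 40) == 1.0

    def test_inverts_constant_hazard_product(self):
        p = 1 - 0.995**40
        assert mean_annual_disease_free_prob(p, 40) == pytest.approx(0.995, abs=1e-12)

    def test_monotone_in_prevalence(self):
        q = mean_annual_disease_free_prob(np.linspace(0, 0.9, 20), 30)
        assert (np.diff(q) < 0).all()

    def test_degenerate_full_prevalence(self):
        assert mean_annual_disease_free_prob(1.0, 10) == 0.0


class TestFitLogTrend:
    def test_constant_q_gives_zero_slope(self):
        beta, _, n, _ = fit_log_trend([1978, 1991, 2002], [0.995] * 3)
        assert beta == pytest.approx(0.0, abs=1e-15)
        assert n == 3

    def test_two_point_fit_is_exact(self):
        beta, _, _, rss = fit_log_trend([2000, 2004], [0.996, 0.994])
        assert beta == pytest.approx(np.log(0.994 / 0.996) / 4, rel=1e-12)
        assert beta == pytest.approx(-5.02e-4, rel=1e-2)
        assert rss == pytest.approx(0.0, abs=1e-20)

    def test_single_point_falls_back_to_zero_slope(self):
        beta, _, n, _ = fit_log_trend([2000], [0.99])
        assert beta == 0.0 and n == 1

    def test_recovers_generator_slope_per_age_group(self, trend_surface):
        cells = noise_free_cells(trend_surface)
        est = StybloIncidenceEstimator().fit(cells)
        # every age group's fitted slope equals the surface's period slope
        assert np.allclose(est.trend_["beta"], -1.0e-4, atol=1e-10)


class TestAnnualIncidence:
    def test_zero_trend_inverts_exposure_power(self):
        p = 1 - 0.995**40
        i, clamped = annual_incidence(p, 40, 0.0)
        assert i == pytest.approx(0.005, abs=1e-15)
        assert not clamped

    def test_zero_prevalence_zero_incidence(self):
        i, _ = annual_incidence(0.0, 30, 0.0)
        assert i == 0.0

    def test_negative_estimate_clamped_and_flagged(self):
        # strong positive beta (falling risk) pushes the estimate negative
        i, clamped = annual_incidence(0.01, 40, 0.05)
        assert i == 0.0 and clamped
        raw, _ = annual_incidence(0.01, 40, 0.05, clamp=False)
        assert raw < 0


class TestSurfaceRecovery:
    def test_constant_hazard_recovered_to_machine_precision(self, constant_surface):
        cells = noise_free_cells(constant_surface)
        est = StybloIncidenceEstimator(onset_age=0).fit(cells)
        assert np.abs(est.surface_["incidence"] - 5.0).max() < 1e-9

    def test_loglinear_hazard_recovered(self, trend_surface):
        cells = noise_free_cells(trend_surface)
        est = StybloIncidenceEstimator(onset_age=0).fit(cells)
        truth = np.array([
            float(trend_surface.rate(r.sex, midpoint_age(r.age_group), r.survey_year))
            for r in est.surface_.itertuples()
        ]) * 1000
        rel = np.abs(est.surface_["incidence"].to_numpy() - truth) / truth
        assert rel.max() < 0.01  # in fact machine precision in this regime

    def test_rising_hazard_gives_rising_estimates(self, trend_surface):
        cells = noise_free_cells(trend_surface)
        est = StybloIncidenceEstimator().fit(cells)
        for (_, _), sub in est.surface_.groupby(["sex", "age_group"], observed=False):
            vals = sub.sort_values("survey_year")["incidence"].to_numpy()
            assert (np.diff(vals) > 0).all()

    def test_adult_onset_age_regime(self):
        surface = st.HazardSurface.loglinear(0.014, -1.8e-4, 2013)
        cells = noise_free_cells(surface, onset_age=20)
        est = StybloIncidenceEstimator(onset_age=20).fit(cells)
        truth = np.array([
            float(surface.rate(r.sex, midpoint_age(r.age_group), r.survey_year))
            for r in est.surface_.itertuples()
        ]) * 1000
        assert np.allclose(est.surface_["incidence"], truth, rtol=1e-9)

    def test_single_survey_year_is_hard_error(self, trend_surface):
        cells = noise_free_cells(trend_surface, years=(2002,))
        with pytest.raises(ValueError, match="2 survey years"):
            StybloIncidenceEstimator().fit(cells)

    def test_output_invariant_to_duplicated_qbar_surveys(self, constant_surface):
        # appending surveys with identical q_bar leaves the OLS slope, and
        # hence the surface, unchanged
        base = noise_free_cells(constant_surface, years=(1990, 2000))
        extra = noise_free_cells(constant_surface, years=(1990, 2000, 2010))
        a = StybloIncidenceEstimator().fit(base).surface_
        b = StybloIncidenceEstimator().fit(extra).surface_
        merged = a.merge(b, on=["sex", "age_group", "survey_year"],
                         suffixes=("_a", "_b"))
        assert np.allclose(merged["incidence_a"], merged["incidence_b"], atol=1e-9)

    def test_predict_matches_fitted_surface(self, trend_surface):
        cells = noise_free_cells(trend_surface)
        est = StybloIncidenceEstimator().fit(cells)
        pred = est.predict(cells)
        assert np.allclose(pred, est.surface_["incidence"], atol=1e-9)

    def test_annual_surface_interpolates_between_surveys(self, trend_surface):
        cells = noise_free_cells(trend_surface, years=(1991, 1995))
        est = StybloIncidenceEstimator().fit(cells)
        annual = est.annual_surface()
        years = sorted(annual["year"].unique())
        assert years == [1991, 1992, 1993, 1994, 1995]

    def test_sklearn_params_round_trip(self):
        est = StybloIncidenceEstimator(onset_age=20, clamp=False)
        params = est.get_params()
        assert params["onset_age"] == 20 and params["clamp"] is False
        est2 = StybloIncidenceEstimator().set_params(**params)
        assert est2.onset_age == 20


def test_sampling_noise_envelope_small():
    """Smoke-scale version of the noise envelope: binomial prevalences at
    n = 1000 per stratum leave the standardized estimate near truth."""
    surface = st.HazardSurface.loglinear(0.014, -1.8e-4, 2013)
    cells = noise_free_cells(surface, onset_age=20)
    rng = np.random.default_rng(0)
    noisy = cells.copy()
    noisy["prevalence"] = rng.binomial(1000, cells["prevalence"]) / 1000
    est = StybloIncidenceEstimator(onset_age=20).fit(noisy)
    std = est.surface_.groupby("survey_year", observed=False)["incidence"].mean()
    truth = pd.Series({
        t: float(surface.rate("male", 45, t) + surface.rate("female", 45, t)) / 2 * 1000
        for t in SURVEY_YEARS
    })
    rel = (std - truth).abs() / truth
    assert rel.median() < 0.15
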