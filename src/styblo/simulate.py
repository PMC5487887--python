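"""Synthetic cohorts and cross-sectional surveys with known incidence.

The generator builds an individual-level population whose disease onsets
follow a :class:`~styblo.hazard.HazardSurface` exactly (annual Bernoulli
trials, absorbing status, disease-free at birth), then draws cross-sectional
surveys from it with configurable per-stratum sampling fractions.  Because
the truth is known in closed form, every downstream stage — weighting,
prevalence, the birth-cohort incidence estimator, projections — can be
tested against an oracle instead of an unavailable data deposit.

The default study configuration emulates a Pacific-island type 2 diabetes
setting: eight surveys over 1978-2013 (two fielded in 1991), ages 25-64,
prevalence rising from a few percent to beyond 20%, and a secular rise in
mean BMI.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hazard import AGE_GROUP_LABELS, SEXES, HazardSurface, age_group_label

#: Survey fielding years of the default study (1991 appears twice: two
#: independent surveys were run that year and are pooled downstream).
DEFAULT_SURVEY_YEARS: tuple[int, ...] = (1978, 1991, 1991, 1995, 2002, 2003, 2010, 2013)

DEFAULT_REGIONS: tuple[str, ...] = ("urban", "northwest", "rest-upolu", "savaii")
DEFAULT_REGION_WEIGHTS: tuple[float, ...] = (0.20, 0.25, 0.30, 0.25)


@dataclass(frozen=True)
class BMIModel:
    """Mean BMI by sex and calendar year, with individual noise.

    Linear secular trend: ``mean(sex, year) = intercept[sex] + slope * (year
    - ref_year)``, plus a mild age gradient around age 45.  Defaults give a
    rise of roughly 27->31 kg/m2 (men) and 29.5->34.5 (women) over
    1978-2013, with mean heights 1.74 m / 1.62 m.
    """

    intercepts: dict[str, float] = field(
        default_factory=lambda: {"male": 30.9, "female": 34.4}
    )
    slope_per_year: float = 0.11
    age_slope: float = 0.03
    ref_year: int = 2013
    sd: float = 4.0
    heights: dict[str, float] = field(
        default_factory=lambda: {"male": 1.74, "female": 1.62}
    )
    height_sd: float = 0.06

    def mean(self, sex: str, year, age=45):
        return (
            self.intercepts[sex]
            + self.slope_per_year * (np.asarray(year) - self.ref_year)
            + self.age_slope * (np.asarray(age) - 45)
        )


@dataclass
class SyntheticPopulation:
    """Individual-level population with fully known disease histories.

    ``individuals`` has one row per person: sex, birth_year, region,
    onset_year (``inf`` if never diseased within the simulated horizon) and
    death_year (``inf`` unless the excess-mortality knob is on).  Status is
    absorbing and determined only by hazards up to the query year.
    """

    individuals: pd.DataFrame
    surface: HazardSurface
    onset_age: int
    first_year: int
    last_year: int
    seed: int

    def alive_at(self, year: int) -> pd.DataFrame:
        df = self.individuals
        return df[df["death_year"] > year]

    def status_at(self, year: int) -> pd.Series:
        """Boolean diseased-by-``year`` flag for every individual."""
        return self.individuals["onset_year"] <= year

    def true_prevalence(self, year: int, sex: str | None = None,
                        age_lo: int = 25, age_hi: int = 64) -> float:
        df = self.alive_at(year).copy()
        age = year - df["birth_year"]
        df = df[(age >= age_lo) & (age <= age_hi)]
        if sex is not None:
            df = df[df["sex"] == sex]
        if len(df) == 0:
            return float("nan")
        return float((df["onset_year"] <= year).mean())


def simulate_population(
    surface: HazardSurface,
    n_per_cohort: int,
    regions=DEFAULT_REGIONS,
    seed: int = 0,
    *,
    region_weights=DEFAULT_REGION_WEIGHTS,
    birth_years=None,
    first_year: int | None = None,
    last_year: int = 2013,
    onset_age: int = 0,
    excess_mortality: float = 0.0,
) -> SyntheticPopulation:
    """Simulate individuals whose onsets follow ``surface`` exactly.

    Each person in birth cohort ``b`` undergoes one Bernoulli trial per year
    of life from ``onset_age + 1`` to the age attained at ``last_year``, with
    probability ``h(sex, a, b + a)``.  ``excess_mortality`` is an optional
    annual death probability applied after onset only (off by default: the
    estimator under test ignores differential survival).

    Reproducible: identical seeds give bit-identical populations.
    """
    if n_per_cohort < 1:
        raise ValueError("n_per_cohort must be >= 1")
    if birth_years is None:
        lo = (first_year if first_year is not None else 1978) - 64
        birth_years = np.arange(lo, last_year - 25 + 1)
    birth_years = np.asarray(birth_years)
    region_weights = np.asarray(region_weights, float)
    region_weights = region_weights / region_weights.sum()

    # eager domain validation: reject invalid hazards before any draw
    max_age = int(last_year - birth_years.min())
    ages = np.arange(onset_age + 1, max_age + 1)
    surface.validate(
        years=np.arange(birth_years.min() + onset_age + 1, last_year + 1), ages=ages
    )

    rng = np.random.default_rng(seed)
    frames = []
    for sex in surface.sexes:
        for b in birth_years:
            amax = int(last_year - b)
            if amax <= onset_age:
                trial_ages = np.array([], dtype=int)
            else:
                trial_ages = np.arange(onset_age + 1, amax + 1)
            if len(trial_ages):
                h = surface.rate(sex, trial_ages, b + trial_ages)
                surv = np.cumprod(1.0 - h)
            else:
                surv = np.array([])
            u = rng.random(n_per_cohort)
            if len(surv):
                # first trial k with surv[k] < u -> onset at age onset_age+k+1
                k = np.searchsorted(-surv, -u, side="right")
            else:
                k = np.full(n_per_cohort, 0)
            onset = np.where(
                (len(surv) > 0) & (k < len(surv)),
                b + onset_age + 1 + k,
                np.inf,
            )
            death = np.full(n_per_cohort, np.inf)
            if excess_mortality > 0:
                diseased = np.isfinite(onset)
                nd = int(diseased.sum())
                if nd:
                    extra = rng.geometric(excess_mortality, nd)
                    death[diseased] = onset[diseased] + extra
            frames.append(
                pd.DataFrame(
                    {
                        "sex": sex,
                        "birth_year": int(b),
                        "region": rng.choice(regions, n_per_cohort, p=region_weights),
                        "onset_year": onset,
                        "death_year": death,
                    }
                )
            )
    individuals = pd.concat(frames, ignore_index=True)
    return SyntheticPopulation(
        individuals=individuals,
        surface=surface,
        onset_age=onset_age,
        first_year=int(birth_years.min() + 25),
        last_year=int(last_year),
        seed=seed,
    )


@dataclass
class SimulatedSurvey:
    """One cross-sectional survey plus the census truth it should weight to."""

    records: pd.DataFrame
    census: pd.DataFrame
    empty_strata: pd.DataFrame  # strata with census count > 0 but no sample


def simulate_survey(
    pop: SyntheticPopulation,
    year: int,
    sampling_fractions=None,
    seed: int = 0,
    *,
    bmi_model: BMIModel | None = None,
    pregnancy_rate: float = 0.0,
    unconfirmed_fasting_rate: float = 0.0,
    medication_fraction: float = 0.3,
) -> SimulatedSurvey:
    """Draw a cross-sectional survey of 25-64 year olds at ``year``.

    ``sampling_fractions`` is either a scalar in (0, 1], or a mapping from
    stratum keys to fractions; keys may be any subset of
    ``(region, sex, age_group)`` tuples, a ``(sex, age_group)`` tuple, a
    bare age-group label, or a bare sex.  Fraction 1.0 everywhere returns
    the full census as the sample, so weighted prevalence is exactly the
    population prevalence.

    Fasting plasma glucose values are generated so the standard case
    definition (FPG >= 7.0 mmol/L and/or on medication) recovers true
    status without ambiguity: non-cases draw FPG in [4.0, 6.9], cases on
    medication may sit below threshold but carry the flag.
    """
    if not (pop.first_year - 39 <= year <= pop.last_year):
        raise ValueError(f"survey year {year} outside simulated span")
    rng = np.random.default_rng(seed)
    bmi_model = bmi_model or BMIModel()

    df = pop.alive_at(year).copy()
    df["age"] = year - df["birth_year"]
    df = df[(df["age"] >= 25) & (df["age"] <= 64)].reset_index(drop=True)
    df["age_group"] = age_group_label(df["age"].to_numpy())
    df["diseased"] = df["onset_year"] <= year

    census = (
        df.groupby(["region", "sex", "age_group"], observed=False)
        .size()
        .rename("count")
        .reset_index()
    )
    census["census_year"] = year

    frac = _resolve_fractions(df, sampling_fractions)
    take = rng.random(len(df)) < frac
    # exactness contract: fraction 1.0 takes everyone deterministically
    take[frac >= 1.0] = True
    sample = df[take].copy()

    sampled_counts = (
        sample.groupby(["region", "sex", "age_group"], observed=False).size().rename("sampled")
    )
    merged = census.merge(sampled_counts.reset_index(), how="left",
                          on=["region", "sex", "age_group"])
    merged["sampled"] = merged["sampled"].fillna(0).astype(int)
    empty = merged[(merged["count"] > 0) & (merged["sampled"] == 0)].copy()

    n = len(sample)
    bmi = np.empty(n)
    height = np.empty(n)
    for sex in SEXES:
        m = (sample["sex"] == sex).to_numpy()
        if m.any():
            bmi[m] = bmi_model.mean(sex, year, sample.loc[m, "age"].to_numpy()) + rng.normal(
                0, bmi_model.sd, m.sum()
            )
            height[m] = rng.normal(bmi_model.heights[sex], bmi_model.height_sd, m.sum())
    bmi = np.clip(bmi, 15, 60)
    weight = bmi * height**2

    diseased = sample["diseased"].to_numpy()
    on_med = diseased & (rng.random(n) < medication_fraction)
    fpg = np.where(
        diseased,
        7.0 + rng.gamma(2.0, 1.2, n),  # cases: >= 7.0
        4.0 + 2.9 * rng.random(n),  # non-cases: [4.0, 6.9]
    )
    # treated cases may be controlled below threshold; the flag classifies them
    treated_controlled = on_med & (rng.random(n) < 0.5)
    fpg = np.where(treated_controlled, 5.0 + 1.9 * rng.random(n), fpg)

    pregnant = np.zeros(n, dtype=bool)
    if pregnancy_rate > 0:
        pregnant = (
            (sample["sex"] == "female").to_numpy()
            & (sample["age"].to_numpy() <= 44)
            & (rng.random(n) < pregnancy_rate)
        )
    fasting = rng.random(n) >= unconfirmed_fasting_rate

    records = pd.DataFrame(
        {
            "survey_year": year,
            "sex": sample["sex"].to_numpy(),
            "age": sample["age"].to_numpy(),
            "region": sample["region"].to_numpy(),
            "fasting_confirmed": fasting,
            "fpg": np.round(fpg, 2),
            "on_medication": on_med,
            "pregnant": pregnant,
            "weight": np.round(weight, 1),
            "height": np.round(height, 3),
        }
    )
    return SimulatedSurvey(records=records, census=census, empty_strata=empty)


def _resolve_fractions(df: pd.DataFrame, fractions) -> np.ndarray:
    if fractions is None:
        fractions = 1.0
    if np.isscalar(fractions):
        f = float(fractions)
        if not 0 < f <= 1:
            raise ValueError("sampling fraction must lie in (0, 1]")
        return np.full(len(df), f)
    out = np.full(len(df), np.nan)
    keys_full = list(zip(df["region"], df["sex"], df["age_group"]))
    for i, (reg, sex, ag) in enumerate(keys_full):
        for key in ((reg, sex, ag), (sex, ag), ag, sex):
            if key in fractions:
                out[i] = fractions[key]
                break
    if np.isnan(out).any():
        default = fractions.get("default")
        if default is None:
            raise ValueError("sampling_fractions missing strata and no 'default' key")
        out = np.where(np.isnan(out), default, out)
    if np.any((out <= 0) | (out > 1)):
        raise ValueError("sampling fractions must lie in (0, 1]")
    return out


def default_surface(age_multipliers=None) -> HazardSurface:
    """The default study hazard: log-linear rise, roughly doubling 1978-2013.

    Base annual hazards at 2013 are 14.5 (men) / 13.5 (women) per 1000 with a
    common survival-scale slope of -1.7e-4 per year, valid back to the 1930s
    exposure years of the oldest 1978 cohorts.  Age-constant by default (the
    estimator's own model); pass multipliers to impose an age gradient.
    """
    return HazardSurface.loglinear(
        base_rate={"male": 0.0145, "female": 0.0135},
        slope=-1.7e-4,
        ref_year=2013,
        age_multipliers=age_multipliers,
    )


#: Risk-onset age of the default study: onset trials start in adulthood,
#: which keeps early-period prevalence at a few percent while late-period
#: prevalence exceeds 20%, matching the secular pattern being emulated.
DEFAULT_ONSET_AGE = 20


def default_study(n_per_cohort: int = 120, seed: int = 0,
                  survey_years=DEFAULT_SURVEY_YEARS,
                  sampling_fractions=None,
                  **survey_kwargs):
    """Simulate the full default study: population plus one survey per year.

    Returns ``(population, surveys)`` where ``surveys`` is a list of
    :class:`SimulatedSurvey` in fielding order (duplicate years allowed and
    drawn independently, as with the two 1991 surveys).
    """
    ss = np.random.SeedSequence(seed)
    pop_seed, *survey_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in
                               ss.spawn(1 + len(survey_years))]
    pop = simulate_population(
        default_surface(),
        n_per_cohort=n_per_cohort,
        seed=pop_seed,
        first_year=min(survey_years),
        last_year=max(survey_years),
        onset_age=DEFAULT_ONSET_AGE,
    )
    surveys = [
        simulate_survey(pop, y, sampling_fractions, seed=s, **survey_kwargs)
        for y, s in zip(survey_years, survey_seeds)
    ]
    return pop, surveys
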