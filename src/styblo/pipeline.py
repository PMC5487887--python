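"""End-to-end pipeline: simulate -> weight -> estimate -> summarize -> project.

The pipeline wires the library stages together in the order a serial
prevalence-survey incidence study runs them, writing every intermediate
table as CSV so each stage can be re-run from its serialized inputs.  All
randomness flows from one root seed through per-stage spawned streams, so
a config plus seed reproduces the whole bundle byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import records as rec
from . import simulate as sim
from .apc import apc_analysis
from .cmp import CMPRegression, ScenarioSpec, project_scenario
from .estimator import StybloIncidenceEstimator
from .hazard import AGE_GROUP_LABELS, SEXES
from .lexis import midpoint_age
from .summaries import (age_standardize, cumulative_risk, incident_counts,
                        standard_population, summary_table)
from .weighting import adjusted_prevalence, attach_weights, compute_case_weights

log = logging.getLogger("styblo")


@dataclass
class PipelineConfig:
    """Declarative configuration of a full synthetic-study run."""

    seed: int = 0
    n_per_cohort: int = 120
    survey_years: tuple = sim.DEFAULT_SURVEY_YEARS
    onset_age: int = sim.DEFAULT_ONSET_AGE
    #: per-individual sampling probability; 0.15 of the ~10k simulated
    #: adults gives surveys of ~1500 records, the size of the real ones
    sampling_fraction: float = 0.15
    pool_same_year: bool = True
    cumulative_risk_mode: str = "as_published"
    ci_method: str = "normal"
    horizon_year: int = 2020
    #: total 25-64 population at the horizon; None = carry the last
    #: simulated census total forward (keeps synthetic rates on scale)
    horizon_population: int | None = None
    target_bmi_2020: dict = field(default_factory=dict)  # sex -> BMI; default: trend
    weight_deltas: tuple = (-1, -2, -3, -4, 1, 2, 3, 4)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**raw)
        for key in ("survey_years", "weight_deltas"):
            if key in raw:
                setattr(cfg, key, tuple(raw[key]))
        return cfg

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["survey_years"] = list(self.survey_years)
        d["weight_deltas"] = list(self.weight_deltas)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


def _derived_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def make_design(df: pd.DataFrame, bmi_center: float = 30.0):
    """Shared CMP design builder: intercept, sex, age-group dummies, BMI.

    The dispersion design is intercept plus centred BMI, the "dispersion
    regressor" structure.  Category orders are fixed so that fitted and
    projection designs always align column for column.
    """
    X = [np.ones(len(df))]
    X.append((df["sex"] == "male").to_numpy(float))
    for g in AGE_GROUP_LABELS[1:]:
        X.append((df["age_group"] == g).to_numpy(float))
    bmi = df["bmi"].to_numpy(float) - bmi_center
    X.append(bmi)
    X = np.column_stack(X)
    Z = np.column_stack([np.ones(len(df)), bmi])
    return X, Z


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run every stage on a synthetic study; return the output bundle.

    Writes, under ``outdir``: the unit-record and census CSVs, the
    prevalence table, the incidence surface and trend report, the
    age-standardized summary table, the APC deviance tables, the scenario
    projection table, and the resolved config.
    """
    outdir = Path(outdir)
    (outdir / "data").mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO, format="%(name)s: %(message)s")
    config.to_yaml(outdir / "config.resolved.yaml")

    # -- stage 1: simulate and serialize ------------------------------
    pop, surveys = sim.default_study(
        n_per_cohort=config.n_per_cohort,
        seed=config.seed,
        survey_years=config.survey_years,
        sampling_fractions=config.sampling_fraction,
    )
    survey_paths = []
    for i, (year, sv) in enumerate(zip(config.survey_years, surveys)):
        spath = outdir / "data" / f"survey_{year}_{i}.csv"
        cpath = outdir / "data" / f"census_{year}_{i}.csv"
        rec.write_survey_records(sv.records, spath)
        sv.census.to_csv(cpath, index=False)
        survey_paths.append((year, spath, cpath))
    log.info("simulated %d surveys from %d individuals", len(surveys),
             len(pop.individuals))

    # -- stage 2: read back, validate, filter, weight, prevalence ------
    cells = []
    by_year: dict[int, list] = {}
    for year, spath, cpath in survey_paths:
        loaded = rec.read_survey_records(spath)
        census = rec.read_census_table(cpath)
        eligible = rec.filter_eligible(loaded)
        log.info("%d: %d records, %d parse errors, removed %s", year,
                 len(loaded), len(loaded.errors), eligible.removed)
        by_year.setdefault(year, []).append((eligible.records, census))

    for year, parts in sorted(by_year.items()):
        if config.pool_same_year and len(parts) > 1:
            frames = []
            for survey, census in parts:
                w = compute_case_weights(survey, census)
                frames.append(attach_weights(survey, w))
            stacked = pd.concat(frames, ignore_index=True)
            cell = adjusted_prevalence(stacked, ci_method=config.ci_method)
        else:
            survey, census = parts[0]
            w = compute_case_weights(survey, census)
            cell = adjusted_prevalence(survey, weights=w, ci_method=config.ci_method)
        cell["survey_year"] = year
        cells.append(cell)
    prevalence = pd.concat(cells, ignore_index=True)
    prevalence.to_csv(outdir / "prevalence.csv", index=False)

    # -- stage 3: birth-cohort incidence estimation --------------------
    est = StybloIncidenceEstimator(onset_age=config.onset_age)
    est.fit(prevalence)
    est.surface_.to_csv(outdir / "incidence_surface.csv", index=False)
    est.trend_.to_csv(outdir / "trend_fits.csv", index=False)
    annual = est.annual_surface()
    annual.to_csv(outdir / "incidence_annual.csv", index=False)

    # -- stage 4: standardization and summaries ------------------------
    last_census = by_year[max(by_year)][0][1]
    standard = {
        s: standard_population(last_census[last_census["sex"] == s]) for s in SEXES
    }
    table = summary_table(est.surface_, standard)
    table.to_csv(outdir / "summary_table.csv", index=False)

    census_pop = last_census["count"].sum()
    last_year = int(max(config.survey_years))
    std_rates = {
        s: age_standardize(
            est.surface_[
                (est.surface_["sex"] == s) & (est.surface_["survey_year"] == last_year)
            ].set_index("age_group")["incidence"],
            standard[s],
        )
        for s in SEXES
    }
    pops = {s: last_census.loc[last_census["sex"] == s, "count"].sum() for s in SEXES}
    national_rate = sum(std_rates[s] * pops[s] for s in SEXES) / sum(pops.values())
    cases_last, _ = incident_counts(national_rate, census_pop)

    # -- stage 5: APC deviance analysis --------------------------------
    strata = _incidence_strata(est.surface_, by_year)
    apc_data = strata.rename(columns={"age_group": "age", "survey_year": "period"})
    apc_data["cohort"] = (
        (apc_data["period"] - apc_data["age"].map(midpoint_age)) // 5 * 5
    )
    apc_tables = apc_analysis(apc_data)
    for name, tab in apc_tables.items():
        tab.to_csv(outdir / f"apc_{name}.csv", index=False)

    # -- stage 6: CMP regression and scenario projection ----------------
    bmi_strata = _bmi_strata(by_year)
    strata = strata.merge(bmi_strata, on=["sex", "age_group", "survey_year"], how="left")
    strata["bmi"] = strata["bmi"].fillna(strata["bmi"].mean())
    X, Z = make_design(strata)
    model = CMPRegression(on_failure="warn").fit(X, strata["count"].to_numpy(), Z)

    baseline = strata[strata["survey_year"] == last_year][
        ["sex", "age_group", "bmi"]
    ].rename(columns={"bmi": "baseline_bmi"})
    horizon_total = config.horizon_population or int(last_census["count"].sum())
    horizon_pop = _horizon_populations(last_census, horizon_total)
    proj_strata = baseline.merge(horizon_pop, on=["sex", "age_group"])

    bmi_model = sim.BMIModel()
    target = dict(config.target_bmi_2020) or {
        s: float(bmi_model.mean(s, config.horizon_year)) for s in SEXES
    }
    heights = bmi_model.heights
    scenarios = [
        ScenarioSpec("bmi_trend", config.horizon_year, last_year,
                     "period_trend_to_target", target_bmi=target),
        ScenarioSpec("frozen_baseline", config.horizon_year, last_year,
                     "frozen_at_baseline"),
    ] + [
        ScenarioSpec(f"{'plus' if d > 0 else 'minus'}_{abs(d)}kg",
                     config.horizon_year, last_year, "weight_delta_kg",
                     delta_kg=d, mean_heights=heights)
        for d in config.weight_deltas
    ]
    rows = []
    for sc in scenarios:
        res = project_scenario(model, sc, proj_strata, make_design, standard)
        row = {"scenario": sc.name}
        for key in (*SEXES, "national"):
            row[f"{key}_rate"] = res[key]["rate"]
            row[f"{key}_ci_low"], row[f"{key}_ci_high"] = res[key]["ci"]
        rows.append(row)
    projections = pd.DataFrame(rows)
    projections.to_csv(outdir / "projections.csv", index=False)

    bundle = {
        "prevalence": prevalence,
        "incidence": est.surface_,
        "annual": annual,
        "summary_table": table,
        "standardized_last": std_rates | {"national": national_rate},
        "incident_cases_last": cases_last,
        "apc": apc_tables,
        "cmp_model": model,
        "projections": projections,
    }
    with open(outdir / "headline.json", "w") as fh:
        json.dump(
            {
                "standardized_incidence_last_year": {
                    k: round(float(v), 3) for k, v in bundle["standardized_last"].items()
                },
                "incident_cases_last_year": cases_last,
            },
            fh, indent=2,
        )
    return bundle


def _incidence_strata(surface: pd.DataFrame, by_year) -> pd.DataFrame:
    """Per (sex, age group, survey year): incident count and population."""
    rows = []
    for year, parts in sorted(by_year.items()):
        census = pd.concat([c for _, c in parts]).groupby(
            ["sex", "age_group"], observed=False)["count"].sum() / len(parts)
        sub = surface[surface["survey_year"] == year]
        for _, r in sub.iterrows():
            popn = float(census.get((r["sex"], r["age_group"]), np.nan))
            if not np.isfinite(popn) or not np.isfinite(r["incidence"]):
                continue
            cases, _ = incident_counts(r["incidence"], popn)
            rows.append({"sex": r["sex"], "age_group": r["age_group"],
                         "survey_year": year, "count": cases,
                         "population": popn})
    return pd.DataFrame(rows)


def _bmi_strata(by_year) -> pd.DataFrame:
    """Mean measured BMI per (sex, age group, survey year) from unit records."""
    rows = []
    for year, parts in sorted(by_year.items()):
        records = pd.concat([s for s, _ in parts], ignore_index=True)
        records = rec.with_age_groups(records)
        bmi = records["weight"] / records["height"] ** 2
        g = records.assign(bmi=bmi).groupby(["sex", "age_group"], observed=False)["bmi"].mean()
        for (sex, ag), v in g.items():
            rows.append({"sex": sex, "age_group": ag, "survey_year": year, "bmi": v})
    return pd.DataFrame(rows)


def _horizon_populations(last_census: pd.DataFrame, total: int) -> pd.DataFrame:
    """Scale the last census's stratum shares to the projected total."""
    counts = last_census.groupby(["sex", "age_group"], observed=False)["count"].sum()
    share = counts / counts.sum()
    out = (share * total).rename("population").reset_index()
    return out
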