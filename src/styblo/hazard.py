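"""True incidence-hazard surfaces for synthetic cohorts.

A :class:`HazardSurface` stores the annual probability ``h(sex, age, year)``
of disease onset for a disease-free individual.  Surfaces are piecewise
constant over 5-year age groups and log-linear in calendar time on the
survival scale: ``log(1 - h)`` changes by a fixed slope per calendar year
within each age group.  This is exactly the structure the birth-cohort
incidence estimator assumes, which makes the surface the natural oracle
for recovery tests; age-varying multipliers let one probe the estimator
outside its comfort zone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

#: Closed 5-year age bands partitioning 25-64, as used throughout.
AGE_GROUPS: tuple[tuple[int, int], ...] = tuple(
    (lo, lo + 4) for lo in range(25, 65, 5)
)
AGE_GROUP_LABELS: tuple[str, ...] = tuple(f"{lo}-{hi}" for lo, hi in AGE_GROUPS)
SEXES: tuple[str, str] = ("male", "female")


class HazardValidationError(ValueError):
    """Raised when a surface yields an annual hazard outside [0, 1)."""


def age_group_label(age) -> np.ndarray:
    """Map integer attained age(s) to the 5-year band label (25-29 ... 60-64).

    Ages outside 25-64 raise; use :func:`age_group_index` with ``clip=True``
    for hazard lookups below 25.
    """
    age = np.asarray(age)
    if np.any((age < 25) | (age > 64)):
        raise ValueError("age outside the 25-64 range has no age-group label")
    idx = (age - 25) // 5
    return np.asarray(AGE_GROUP_LABELS, dtype=object)[idx]


def age_group_index(age, clip: bool = False) -> np.ndarray:
    age = np.asarray(age)
    idx = (age - 25) // 5
    if clip:
        return np.clip(idx, 0, len(AGE_GROUPS) - 1).astype(int)
    if np.any((idx < 0) | (idx >= len(AGE_GROUPS))):
        raise ValueError("age outside 25-64")
    return idx.astype(int)


@dataclass(frozen=True)
class HazardSurface:
    """Annual onset hazard by sex, 5-year age group and calendar year.

    Parameters
    ----------
    base_rates
        Mapping sex -> array of eight annual hazards at ``ref_year``.
    period_slopes
        Mapping sex -> array of eight slopes ``d_a`` of ``log(1 - h)`` per
        calendar year (negative slope = rising hazard).
    ref_year
        Calendar year at which ``base_rates`` apply.

    Ages below 25 take the 25-29 group's hazard; ages above 64 the 60-64
    group's.  Every lookup validates ``0 <= h < 1`` and raises
    :class:`HazardValidationError` otherwise, so a slope that would imply a
    negative hazard in any year actually touched is rejected rather than
    silently clipped.
    """

    base_rates: Mapping[str, np.ndarray]
    period_slopes: Mapping[str, np.ndarray]
    ref_year: int
    age_groups: tuple[tuple[int, int], ...] = field(default=AGE_GROUPS)

    def __post_init__(self):
        n = len(self.age_groups)
        base = {s: np.asarray(v, dtype=float) for s, v in self.base_rates.items()}
        slope = {s: np.asarray(v, dtype=float) for s, v in self.period_slopes.items()}
        for s, v in base.items():
            if v.shape != (n,):
                raise ValueError(f"base_rates[{s!r}] must have length {n}")
            if np.any((v < 0) | (v >= 1)):
                raise HazardValidationError("base rates must lie in [0, 1)")
        for s, v in slope.items():
            if v.shape != (n,):
                raise ValueError(f"period_slopes[{s!r}] must have length {n}")
        object.__setattr__(self, "base_rates", base)
        object.__setattr__(self, "period_slopes", slope)

    # -- constructors -------------------------------------------------

    @classmethod
    def constant(cls, h: float, sexes: Sequence[str] = SEXES) -> "HazardSurface":
        """Hazard ``h`` everywhere: all ages, sexes and years."""
        n = len(AGE_GROUPS)
        return cls(
            base_rates={s: np.full(n, h) for s in sexes},
            period_slopes={s: np.zeros(n) for s in sexes},
            ref_year=2000,
        )

    @classmethod
    def loglinear(
        cls,
        base_rate: float | Mapping[str, float],
        slope: float,
        ref_year: int,
        age_multipliers: Sequence[float] | None = None,
        sexes: Sequence[str] = SEXES,
    ) -> "HazardSurface":
        """Log-linear period trend, optionally scaled across age groups.

        ``log(1 - h(a, t)) = log(1 - m_a * base) + slope * (t - ref_year)``.
        With ``age_multipliers`` omitted the hazard is age-constant, the
        regime in which the birth-cohort estimator is exact.
        """
        n = len(AGE_GROUPS)
        mult = np.ones(n) if age_multipliers is None else np.asarray(age_multipliers, float)
        if mult.shape != (n,):
            raise ValueError(f"age_multipliers must have length {n}")
        if not isinstance(base_rate, Mapping):
            base_rate = {s: float(base_rate) for s in sexes}
        return cls(
            base_rates={s: mult * b for s, b in base_rate.items()},
            period_slopes={s: np.full(n, slope) for s in base_rate},
            ref_year=ref_year,
        )

    # -- evaluation ---------------------------------------------------

    @property
    def sexes(self) -> tuple[str, ...]:
        return tuple(self.base_rates)

    def rate(self, sex: str, age, year) -> np.ndarray:
        """Annual hazard for (vectors of) age and calendar year."""
        age = np.asarray(age)
        year = np.asarray(year)
        gi = age_group_index(age, clip=True)
        log_surv = np.log1p(-self.base_rates[sex][gi]) + self.period_slopes[sex][gi] * (
            year - self.ref_year
        )
        if np.any(log_surv > 0):
            ls, yr = np.broadcast_arrays(np.atleast_1d(log_surv), np.atleast_1d(year))
            bad = np.unique(yr[ls > 0])
            raise HazardValidationError(
                f"hazard below 0 for sex={sex} at year(s) {bad[:5]}"
            )
        h = -np.expm1(log_surv)
        if np.any(h >= 1):
            raise HazardValidationError("hazard reached 1; surface invalid")
        return h

    def validate(self, years: Sequence[int], ages: Sequence[int]) -> None:
        """Eagerly check ``0 <= h < 1`` on the (age x year) domain needed."""
        ages = np.asarray(ages)
        for sex in self.sexes:
            for a in ages:
                self.rate(sex, a, np.asarray(years))


def closed_form_prevalence(
    surface: HazardSurface, sex: str, age: int, year: int, onset_age: int = 0
) -> float:
    """Exact prevalence of a cohort observed at ``age`` in ``year``.

    The cohort accrues one Bernoulli onset trial per year of life from
    ``onset_age + 1`` up to ``age``; prevalence is one minus the product of
    the annual disease-free probabilities along the cohort's Lexis path:

        P = 1 - prod_{a = onset_age+1..age} (1 - h(sex, a, year - age + a))
    """
    if onset_age > age:
        raise ValueError("onset_age must not exceed age")
    if onset_age == age:
        return 0.0
    ages = np.arange(onset_age + 1, age + 1)
    years = year - age + ages
    h = surface.rate(sex, ages, years)
    return float(-np.expm1(np.sum(np.log1p(-h))))
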