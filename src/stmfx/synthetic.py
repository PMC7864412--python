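"""Synthetic STMF-format weekly mortality with known ground truth.

The generator emulates the structural features the estimators assume —
a slow annual trend in the weekly level, 52-week cosine seasonality with
winter elevation, an optional epidemic shock confined to one year, and
optional Poisson count noise — so that every baseline and the excess
pipeline can be exercised end-to-end with an exactly known answer.

Expected weekly deaths (both sexes) follow

    μ_ij = (α + β·(j − j0)) · (1 + γ·cos(2π(i − φ)/52))

with baseline level α, additive annual trend β, seasonal amplitude
γ ∈ [0, 1), and phase φ (the peak week; the default, week 2, puts the
peak in the Northern winter).  Week 53, generated only for 53-week ISO
years, reuses the week-52 seasonal factor.  An epidemic shock adds a
known total K of extra deaths over a week window of one year, spread
flat or triangularly.  Age groups are filled by fixed proportions of the
total; female and male series each carry half of the both-sex
expectation.  Rates are deaths per person-week of the configured
population.  All randomness is owned by a seeded generator, so equal
configs produce identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import cos, pi, tau

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io import (CANONICAL_COLUMNS, DEATH_COLUMNS, RATE_COLUMNS,
                 WeeklyMortalityTable, iso_weeks_in_year)

#: fixed age-group split of total deaths (0-14, 15-64, 65-74, 75-84, 85+);
#: a plausible elderly-heavy pattern, arbitrary by design and documented as
#: such — ground truths never depend on it.
AGE_SPLIT = (0.005, 0.105, 0.15, 0.27, 0.47)

_SEX_SCALE = {"b": 1.0, "f": 0.5, "m": 0.5}


@dataclass(frozen=True)
class Shock:
    """An epidemic shock: K extra expected deaths over one week window."""

    year: int
    week_from: int
    week_to: int
    total: float  # K ≥ 0, extra expected deaths (both sexes)
    shape: str = "flat"  # "flat" | "triangular"

    def __post_init__(self) -> None:
        if self.total < 0:
            raise ConfigError("shock total must be ≥ 0")
        if self.shape not in ("flat", "triangular"):
            raise ConfigError(f"unknown shock shape {self.shape!r}")
        if not 1 <= self.week_from <= self.week_to:
            raise ConfigError("shock window must satisfy 1 ≤ week_from ≤ week_to")

    def allocation(self) -> dict[int, float]:
        """Expected extra deaths per week of the window, summing to K."""
        weeks = list(range(self.week_from, self.week_to + 1))
        n = len(weeks)
        if self.shape == "flat":
            w = np.full(n, 1.0 / n)
        else:
            tri = np.minimum(np.arange(1, n + 1), np.arange(n, 0, -1)).astype(float)
            w = tri / tri.sum()
        return {wk: float(self.total * wi) for wk, wi in zip(weeks, w)}


@dataclass(frozen=True)
class SyntheticConfig:
    """Generative parameters for a synthetic STMF table.

    ``years`` is an inclusive (first, last) range.  ``population`` is the
    person-week exposure used for the rate columns.  Validation rejects
    configurations whose expected weekly deaths are not strictly positive,
    and shock windows that leave their year's ISO weeks.
    """

    years: tuple[int, int] = (2015, 2020)
    baseline: float = 1000.0          # α: expected weekly deaths, both sexes
    annual_trend: float = 0.0         # β: additive change per calendar year
    seasonal_amplitude: float = 0.15  # γ ∈ [0, 1)
    seasonal_phase: int = 2           # φ: peak week (Northern winter default)
    shock: Shock | None = None
    noise: str = "none"               # "none" | "poisson"
    population: float = 5_000_000.0   # person-weeks, for rate columns
    seed: int = 0
    country_code: str = "SYN"
    sexes: tuple[str, ...] = ("f", "m", "b")

    def __post_init__(self) -> None:
        first, last = self.years
        if last < first:
            raise ConfigError(f"invalid year range {self.years}")
        if not 0.0 <= self.seasonal_amplitude < 1.0:
            raise ConfigError("seasonal_amplitude must be in [0, 1)")
        if self.noise not in ("none", "poisson"):
            raise ConfigError(f"unknown noise model {self.noise!r}")
        if self.population <= 0:
            raise ConfigError("population must be positive")
        if not set(self.sexes) <= {"f", "m", "b"}:
            raise ConfigError(f"invalid sex codes {self.sexes}")
        for j in range(first, last + 1):
            for i in range(1, iso_weeks_in_year(j) + 1):
                if self.expected_deaths(j, i) <= 0:
                    raise ConfigError(
                        f"expected weekly deaths non-positive at year {j} "
                        f"week {i}; adjust baseline/trend/amplitude"
                    )
        if self.shock is not None:
            if not first <= self.shock.year <= last:
                raise ConfigError("shock year outside the generated range")
            if self.shock.week_to > iso_weeks_in_year(self.shock.year):
                raise ConfigError("shock window exceeds the year's ISO weeks")

    def expected_deaths(self, year: int, week: int) -> float:
        """Noise-free, shock-free expected both-sex deaths μ_ij."""
        i = min(week, 52)  # week 53 reuses the week-52 seasonal factor
        seasonal = 1.0 + self.seasonal_amplitude * cos(
            tau * (i - self.seasonal_phase) / 52.0
        )
        return (self.baseline + self.annual_trend * (year - self.years[0])) * seasonal


def generate(config: SyntheticConfig) -> WeeklyMortalityTable:
    """Generate a validated STMF-format table from *config*.

    Deterministic given the seed.  Under ``noise="none"`` the death counts
    equal their expectations exactly (fractional counts are legitimate
    table values); under ``"poisson"`` each age-group count is an
    independent Poisson draw around its expected share, and the total is
    their sum, so the total is Poisson with the intended mean.
    """
    rng = np.random.default_rng(config.seed)
    shock_alloc = config.shock.allocation() if config.shock else {}
    rows = []
    for sex in config.sexes:
        scale = _SEX_SCALE[sex]
        for year in range(config.years[0], config.years[1] + 1):
            for week in range(1, iso_weeks_in_year(year) + 1):
                mu = config.expected_deaths(year, week) * scale
                if config.shock and year == config.shock.year:
                    mu += shock_alloc.get(week, 0.0) * scale
                shares = np.array(AGE_SPLIT) * mu
                if config.noise == "poisson":
                    groups = rng.poisson(shares).astype(float)
                else:
                    groups = shares
                total = float(groups.sum())
                row = {"CountryCode": config.country_code, "Year": year,
                       "Week": week, "Sex": sex}
                row.update({c: float(v) for c, v in zip(DEATH_COLUMNS[:-1], groups)})
                row["DTotal"] = total
                for dc, rc in zip(DEATH_COLUMNS, RATE_COLUMNS):
                    row[rc] = row[dc] / config.population
                rows.append(row)
    df = pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))
    return WeeklyMortalityTable(df)


def ground_truth_excess(config: SyntheticConfig, week_from: int,
                        week_to: int) -> float:
    """Shock deaths allocated to [week_from, week_to] (exact, noise-free).

    This is the both-sex ground truth against which estimated excess over
    the same window is compared; female and male series each carry half.
    """
    if config.shock is None:
        raise ConfigError("config has no shock; ground-truth excess undefined")
    alloc = config.shock.allocation()
    return float(sum(v for w, v in alloc.items() if week_from <= w <= week_to))
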