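"""Shared fixtures and builders for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from stmfx import (ReferencePeriod, Shock, SyntheticConfig, WeeklySeries,
                   generate)


def make_series(values: dict[tuple[int, int], float], measure: str = "dtotal",
                country: str = "SYN", sex: str = "b") -> WeeklySeries:
    return WeeklySeries(country_code=country, sex=sex, measure=measure,
                        values=dict(values))


def rect_series(week_values: dict[int, list[float]], first_year: int = 2015
                ) -> tuple[WeeklySeries, ReferencePeriod]:
    """Series from per-week value lists, one entry per consecutive year."""
    values = {}
    n_years = max(len(v) for v in week_values.values())
    for week, vals in week_values.items():
        for k, v in enumerate(vals):
            values[(first_year + k, week)] = float(v)
    period = ReferencePeriod(tuple(range(first_year, first_year + n_years)))
    return make_series(values), period


def random_ragged_instance(rng: np.random.Generator):
    """A random ragged weekly series plus a reference period and target.

    Returns (data dict, series, period, target_year, weeks) where every
    returned week has at least two reference observations, so all six
    estimators are applicable.
    """
    first = int(rng.integers(2005, 2014))
    n_years = int(rng.integers(4, 11))
    years = list(range(first, first + n_years))
    data: dict[tuple[int, int], float] = {}
    for j in years:
        n_weeks = 53 if rng.random() < 0.2 else 52
        for i in range(1, n_weeks + 1):
            if rng.random() < 0.12:  # ragged: ~12% of cells missing
                continue
            data[(j, i)] = float(np.round(rng.gamma(20.0, 50.0), 3))
    # target year: last year; reference period: a random earlier subset, |P|>=2
    target = years[-1]
    n_ref = int(rng.integers(2, n_years))
    ref_years = tuple(sorted(rng.choice(years[:-1], size=min(n_ref, n_years - 1),
                                        replace=False).tolist()))
    if len(ref_years) < 2:
        ref_years = tuple(years[:2])
    period = ReferencePeriod(ref_years)
    weeks = tuple(
        w for w in range(1, 53)
        if (target, w) in data
        and sum((j, w) in data for j in ref_years) >= 2
    )
    series = make_series(data)
    return data, series, period, target, weeks


@pytest.fixture
def shock_config() -> SyntheticConfig:
    """Noise-free study conditions: flat 1300-death shock over 13 weeks."""
    return SyntheticConfig(
        years=(2015, 2020),
        shock=Shock(year=2020, week_from=10, week_to=22, total=1300.0),
        noise="none",
        seed=20,
    )


@pytest.fixture
def small_table():
    """A small valid table: 1 country, 3 years, 52 weeks, 3 sexes."""
    return generate(SyntheticConfig(years=(2017, 2019), seed=7))
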