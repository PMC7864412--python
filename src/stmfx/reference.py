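"""The six reference-level baselines for weekly excess mortality.

Let :math:`x_{ij}` be the selected measure on week *i* of year *j*, *P* the
reference period (a set of years, which may or may not include the target
year *T*), and *W* the set of weeks available in the target year.  Two
families of baselines are provided.

Week-varying (compare the target year with previous years):

* week-specific average      x̄_i   = mean_{j∈P} x_ij
* week-specific trend        x̂_i   = â_i + b̂_i·T, per-week OLS over j∈P
* week-specific lower quartile
                             x_i^Q1 = mean{ x_ij : x_ij ≤ Q1_i },
                             Q1_i the type-7 lower quartile of week i over P

Week-constant ("seasonality" within the year):

* yearly average-week        x̄     = mean_{i∈W} x̄_i
* summer average-week        x̄*    = mean over W* = W minus winter weeks
                             (Northern winter: weeks 1–12 and 48–52;
                              Southern winter: weeks 22–38)
* yearly lower-quartile-week x̄^Q1  = mean of all pooled x_ij (j∈P, all
                             weeks) at or below the pooled lower quartile

Quartiles use type-7 linear interpolation of order statistics, the default
of R's ``quantile`` and numpy's ``"linear"`` method.  Quartile-boundary
ties are included (membership uses ≤).  No confidence intervals are
computed: these are transparent point baselines, not model fits.

Missing cells inside *P* are tolerated: per-week statistics are taken over
the years that actually have the week, and the shortfall is logged.  Week
53 is special-cased: when no reference year contains week 53, the week-52
reference value is carried forward and flagged in diagnostics, so 53-week
target years (e.g. 2020) are not silently truncated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .errors import EstimatorError
from .io import WeeklySeries

log = logging.getLogger("stmfx")

#: short method codes, as accepted by the CLI, mapped to canonical names
METHODS = {
    "wsa": "week_specific_average",
    "wst": "week_specific_trend",
    "wsq": "week_specific_lower_quartile",
    "yaw": "yearly_average_week",
    "saw": "summer_average_week",
    "ylq": "yearly_lower_quartile_week",
}

#: STMF country/region codes located in the Southern Hemisphere; everything
#: else defaults to north.  Overridable via explicit hemisphere selection.
SOUTHERN_CODES = frozenset({"AUS", "AUS2", "NZL_NP", "NZL_MA", "NZL_NM", "CHL", "ZAF"})


def quantile_linear(values: Iterable[float], p: float) -> float:
    """Type-7 quantile: linear interpolation of order statistics.

    With sorted values x_(1..n) and h = 1 + (n-1)p, returns
    x_(⌊h⌋) + (h-⌊h⌋)(x_(⌈h⌉) - x_(⌊h⌋)) — the default estimator of R's
    ``quantile`` and of ``numpy.quantile(..., method="linear")``.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("quantile of empty value set")
    if not np.isfinite(arr).all():
        raise ValueError("quantile requires finite values")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0, 1], got {p}")
    return float(np.quantile(arr, p, method="linear"))


@dataclass(frozen=True)
class ReferencePeriod:
    """The set *P* of reference years; may include the target year."""

    years: tuple[int, ...]

    def __post_init__(self) -> None:
        ys = tuple(sorted(set(int(y) for y in self.years)))
        if not ys:
            raise EstimatorError("reference period is empty")
        object.__setattr__(self, "years", ys)

    def __len__(self) -> int:
        return len(self.years)

    def __iter__(self):
        return iter(self.years)

    @classmethod
    def preceding(cls, series: WeeklySeries, target_year: int,
                  max_years: int = 7) -> "ReferencePeriod":
        """Default period: up to *max_years* available years before *T*.

        Mirrors the common surveillance practice of using the 4–7 years
        preceding the target year.
        """
        prior = [y for y in series.years if y < target_year]
        if not prior:
            raise EstimatorError(
                f"no years precede target year {target_year} in the series"
            )
        return cls(tuple(prior[-max_years:]))

    def validate_against(self, series: WeeklySeries) -> None:
        missing = [y for y in self.years if y not in series.years]
        if missing:
            raise EstimatorError(
                f"reference years {missing} not present in the series "
                f"(available: {list(series.years)})"
            )


NORTH_WINTER = frozenset(range(1, 13)) | frozenset(range(48, 53))
SOUTH_WINTER = frozenset(range(22, 39))
_ALL_WEEKS = frozenset(range(1, 53))


@dataclass(frozen=True)
class HemisphereSeason:
    """Winter/non-winter partition of weeks 1–52 for a hemisphere.

    Winter weeks carry seasonally elevated mortality and are excluded by
    the summer average-week baseline.
    """

    hemisphere: str
    winter_weeks: frozenset[int]
    nonwinter_weeks: frozenset[int]

    def __post_init__(self) -> None:
        if self.winter_weeks | self.nonwinter_weeks != _ALL_WEEKS or (
            self.winter_weeks & self.nonwinter_weeks
        ):
            raise ValueError("winter and non-winter must partition weeks 1..52")

    @classmethod
    def north(cls) -> "HemisphereSeason":
        return cls("north", NORTH_WINTER, _ALL_WEEKS - NORTH_WINTER)

    @classmethod
    def south(cls) -> "HemisphereSeason":
        return cls("south", SOUTH_WINTER, _ALL_WEEKS - SOUTH_WINTER)

    @classmethod
    def from_name(cls, name: str) -> "HemisphereSeason":
        try:
            return {"north": cls.north, "south": cls.south}[name.lower()]()
        except KeyError:
            raise ValueError(f"unknown hemisphere {name!r}; use 'north' or 'south'")

    @classmethod
    def for_country(cls, country_code: str) -> "HemisphereSeason":
        """Bundled hemisphere lookup by STMF country code (default north)."""
        return cls.south() if country_code.upper() in SOUTHERN_CODES else cls.north()


@dataclass
class ReferenceLevel:
    """Per-week baseline values for a target year's available weeks.

    For the three week-specific methods ``level`` varies by week; for the
    three yearly methods it is one constant replicated across ``weeks``.
    ``diagnostics`` carries per-week fit metadata (OLS coefficients for the
    trend method, week-53 fallback flags, per-week observation counts).
    """

    method: str
    weeks: tuple[int, ...]
    level: dict[int, float]
    period: ReferencePeriod
    target_year: int | None = None
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weeks = tuple(sorted(int(w) for w in self.weeks))
        if set(self.level) != set(self.weeks):
            raise ValueError("level must be defined for exactly the listed weeks")

    @property
    def is_constant(self) -> bool:
        vals = list(self.level.values())
        return all(v == vals[0] for v in vals)

    def as_array(self) -> np.ndarray:
        return np.array([self.level[w] for w in self.weeks])


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _mean(vs: Sequence[float]) -> float:
    """Mean that returns identical inputs exactly.

    A pairwise floating-point mean of n equal values can be off by an ulp;
    short-circuiting guarantees that degenerate (constant) inputs pass
    through every baseline unchanged.
    """
    if all(v == vs[0] for v in vs):
        return float(vs[0])
    return float(np.mean(vs))


def _week_obs(series: WeeklySeries, period: ReferencePeriod, week: int
              ) -> tuple[list[int], list[float]]:
    """Years in P that observe *week*, with their values, in year order."""
    ys, vs = [], []
    for j in period:
        v = series.values.get((j, week))
        if v is not None:
            ys.append(j)
            vs.append(v)
    return ys, vs


def _normalize_weeks(weeks: Iterable[int]) -> tuple[int, ...]:
    ws = tuple(sorted(set(int(w) for w in weeks)))
    if not ws:
        raise EstimatorError("empty week set")
    if not all(1 <= w <= 53 for w in ws):
        raise EstimatorError(f"weeks outside 1..53 in {ws}")
    return ws


def _per_week(
    series: WeeklySeries,
    period: ReferencePeriod,
    weeks: Iterable[int],
    stat: Callable[[list[int], list[float]], float],
    method: str,
    min_obs: int,
) -> ReferenceLevel:
    """Apply a per-week statistic with week-53 carry-forward fallback."""
    period.validate_against(series)
    ws = _normalize_weeks(weeks)
    level: dict[int, float] = {}
    diag: dict = {"n_obs": {}, "week53_fallback": False}
    failures: list[str] = []
    for w in ws:
        ys, vs = _week_obs(series, period, w)
        if len(vs) >= min_obs:
            if len(vs) < len(period):
                log.debug("week %d: only %d of %d reference years observed",
                          w, len(vs), len(period))
            level[w] = stat(ys, vs)
            diag["n_obs"][w] = len(vs)
        elif w == 53 and 52 in level:
            # no reference year contains week 53: carry week 52 forward
            level[53] = level[52]
            diag["n_obs"][53] = len(vs)
            diag["week53_fallback"] = True
            log.info("week 53 absent from reference years; carrying week 52 forward")
        else:
            failures.append(
                f"week {w}: {len(vs)} observation(s) in reference period, "
                f"need ≥ {min_obs}"
            )
    if failures:
        raise EstimatorError(f"{method}: " + "; ".join(failures))
    return ReferenceLevel(method=method, weeks=ws, level=level, period=period,
                          diagnostics=diag)


# ---------------------------------------------------------------------------
# week-varying baselines
# ---------------------------------------------------------------------------


def week_specific_average(
    series: WeeklySeries, period: ReferencePeriod, weeks: Iterable[int]
) -> ReferenceLevel:
    """x̄_i: arithmetic mean of week *i* over the reference years.

    Ragged periods are tolerated: the denominator is the number of
    reference years that actually observe the week.
    """
    return _per_week(series, period, weeks, lambda ys, vs: _mean(vs),
                     "week_specific_average", min_obs=1)


def week_specific_trend(
    series: WeeklySeries,
    period: ReferencePeriod,
    target_year: int,
    weeks: Iterable[int],
) -> ReferenceLevel:
    """x̂_i = â_i + b̂_i·T: one independent OLS line per week.

    Each week's (â_i, b̂_i) minimise Σ_{j∈P}(x_ij − a − b·j)² with calendar
    year as the covariate, then the line is evaluated at the target year
    (extrapolation when T ∉ P).  Requires at least two reference
    observations per week.
    """
    if len(period) < 2:
        raise EstimatorError(
            "week_specific_trend needs at least 2 reference years, got "
            f"{list(period.years)}"
        )
    def ols(ys: list[int], vs: list[float]) -> tuple[float, float, float]:
        """Centered OLS; returns (fit at T, â, b̂) in calendar-year terms.

        Centering the year covariate keeps the normal equations well
        conditioned at calendar-year magnitudes, so exactly linear input
        is reproduced to machine precision.
        """
        y = np.asarray(ys, dtype=float)
        x = np.asarray(vs, dtype=float)
        ybar, xbar = y.mean(), x.mean()
        b = float(((y - ybar) * (x - xbar)).sum() / ((y - ybar) ** 2).sum())
        return float(xbar + b * (target_year - ybar)), float(xbar - b * ybar), b

    def fit(ys: list[int], vs: list[float]) -> float:
        if all(v == vs[0] for v in vs):
            return float(vs[0])  # exact fit; avoids least-squares round-off
        return ols(ys, vs)[0]

    ref = _per_week(series, period, weeks, fit, "week_specific_trend", min_obs=2)
    # per-week (â_i, b̂_i), for diagnostics
    ab: dict[int, tuple[float, float]] = {}
    for w in ref.weeks:
        ys, vs = _week_obs(series, period, w)
        if len(vs) >= 2:
            if all(v == vs[0] for v in vs):
                ab[w] = (float(vs[0]), 0.0)
            else:
                _, a, b = ols(ys, vs)
                ab[w] = (a, b)
    ref.diagnostics["coefficients"] = ab
    ref.target_year = target_year
    return ref


def week_specific_lower_quartile(
    series: WeeklySeries, period: ReferencePeriod, weeks: Iterable[int]
) -> ReferenceLevel:
    """x_i^Q1: mean of week *i*'s values at or below its lower quartile.

    One type-7 lower quartile per week; values tied with Q1 are included.
    Represents "low mortality" conditions for that week of the year.
    """

    def stat(ys: list[int], vs: list[float]) -> float:
        q1 = quantile_linear(vs, 0.25)
        low = [v for v in vs if v <= q1]
        return _mean(low)

    return _per_week(series, period, weeks, stat,
                     "week_specific_lower_quartile", min_obs=1)


# ---------------------------------------------------------------------------
# week-constant ("seasonality") baselines
# ---------------------------------------------------------------------------


def _constant_level(method: str, const: float, weeks: tuple[int, ...],
                    period: ReferencePeriod, diag: dict) -> ReferenceLevel:
    return ReferenceLevel(method=method, weeks=weeks,
                          level={w: const for w in weeks},
                          period=period, diagnostics=diag)


def yearly_average_week(
    series: WeeklySeries, period: ReferencePeriod, weeks: Iterable[int]
) -> ReferenceLevel:
    """x̄: mean of the week-specific averages x̄_i over the available weeks.

    A week-independent constant — the expected level if every week of the
    year had the same average mortality.
    """
    base = week_specific_average(series, period, weeks)
    const = _mean(base.as_array())
    return _constant_level("yearly_average_week", const, base.weeks, period,
                           {"constant": const, "n_weeks": len(base.weeks)})


def summer_average_week(
    series: WeeklySeries,
    period: ReferencePeriod,
    weeks: Iterable[int],
    season: HemisphereSeason,
) -> ReferenceLevel:
    """x̄*: mean of x̄_i over the non-winter weeks W* only.

    Excludes the seasonally elevated winter weeks, so x̄* is generally
    below x̄.  The constant is replicated across all requested weeks so it
    can be differenced against the full target year.
    """
    ws = _normalize_weeks(weeks)
    summer = tuple(w for w in ws if w in season.nonwinter_weeks)
    if not summer:
        raise EstimatorError(
            "no non-winter weeks among the available weeks; the summer "
            "average-week baseline is undefined — use yearly_average_week "
            "or a week-specific method instead"
        )
    base = week_specific_average(series, period, summer)
    const = _mean(base.as_array())
    return _constant_level("summer_average_week", const, ws, period,
                           {"constant": const, "summer_weeks": summer,
                            "hemisphere": season.hemisphere})


def yearly_lower_quartile_week(
    series: WeeklySeries,
    period: ReferencePeriod,
    weeks: Iterable[int] | None = None,
) -> ReferenceLevel:
    """x̄^Q1: mean of pooled values at or below the pooled lower quartile.

    Pools the measure over *all* weeks of *all* reference years, computes
    one type-7 lower quartile, and averages the values not exceeding it —
    a flexible "low-mortality season" constant.  ``weeks`` only controls
    over which weeks the constant is replicated (default: every week
    present within the reference period).
    """
    period.validate_against(series)
    pool = sorted(v for (j, i), v in series.values.items() if j in set(period))
    if not pool:
        raise EstimatorError("no observations in the reference period")
    q1 = quantile_linear(pool, 0.25)
    low = [v for v in pool if v <= q1]
    const = _mean(low)
    if weeks is None:
        weeks = {i for (j, i) in series.values if j in set(period)}
    ws = _normalize_weeks(weeks)
    return _constant_level("yearly_lower_quartile_week", const, ws, period,
                           {"constant": const, "q1": q1, "n_pooled": len(pool),
                            "n_low": len(low)})


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------


def compute_reference(
    series: WeeklySeries,
    method: str,
    period: ReferencePeriod | Sequence[int],
    weeks: Iterable[int] | None = None,
    target_year: int | None = None,
    season: HemisphereSeason | None = None,
) -> ReferenceLevel:
    """Compute a reference level by method code or canonical name.

    ``weeks`` defaults to the weeks available in ``target_year``; the
    trend method requires ``target_year``; the summer method uses
    ``season`` (default: bundled hemisphere lookup for the series'
    country).  The returned level carries ``target_year`` when given, so
    downstream differencing can check consistency.
    """
    name = METHODS.get(method.lower(), method.lower())
    if name not in METHODS.values():
        raise EstimatorError(
            f"unknown method {method!r}; valid: {sorted(METHODS)} or "
            f"{sorted(METHODS.values())}"
        )
    if not isinstance(period, ReferencePeriod):
        period = ReferencePeriod(tuple(period))
    if weeks is None:
        if target_year is None:
            raise EstimatorError("either weeks or target_year must be given")
        weeks = series.weeks_in_year(target_year)
        if not weeks:
            raise EstimatorError(f"target year {target_year} has no data")

    if name == "week_specific_average":
        ref = week_specific_average(series, period, weeks)
    elif name == "week_specific_trend":
        if target_year is None:
            raise EstimatorError("week_specific_trend requires target_year")
        ref = week_specific_trend(series, period, target_year, weeks)
    elif name == "week_specific_lower_quartile":
        ref = week_specific_lower_quartile(series, period, weeks)
    elif name == "yearly_average_week":
        ref = yearly_average_week(series, period, weeks)
    elif name == "summer_average_week":
        if season is None:
            season = HemisphereSeason.for_country(series.country_code)
        ref = summer_average_week(series, period, weeks, season)
    else:
        ref = yearly_lower_quartile_week(series, period, weeks)
    if target_year is not None:
        ref.target_year = target_year
    return ref
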