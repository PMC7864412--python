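"""Excess-mortality computation: differences, polygons, summaries.

Excess mortality on week *i* is the exact difference between the observed
value of the selected measure in the target year and the reference level
for that week.  Maximal runs of consecutive weeks in which the target year
lies strictly above (excess) or strictly below (deficit) the reference
level are reported as "polygons" — the shaded intervals of the standard
excess-mortality figure — with start week, end week and length in whole
weeks.  Selections of weeks are summarised as sums for death counts and as
unweighted means for death rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

import pandas as pd

from .errors import EstimatorError, SelectionError
from .io import WeeklySeries
from .reference import ReferenceLevel


class WeekExcess(NamedTuple):
    observed: float
    reference: float
    difference: float


@dataclass(frozen=True)
class Polygon:
    """A maximal run of consecutive weeks with one sign of difference."""

    sign: str  # "excess" | "deficit"
    start_week: int
    end_week: int

    def __post_init__(self) -> None:
        if self.sign not in ("excess", "deficit"):
            raise ValueError(f"invalid polygon sign {self.sign!r}")
        if self.end_week < self.start_week:
            raise ValueError("end_week before start_week")

    @property
    def length(self) -> int:
        """Duration in whole weeks (end − start + 1)."""
        return self.end_week - self.start_week + 1


def detect_polygons(differences: Mapping[int, float] | Iterable[tuple[int, float]]
                    ) -> list[Polygon]:
    """Find maximal constant-sign runs of consecutive available weeks.

    Zero-difference weeks terminate runs and belong to no polygon; a gap
    in the available weeks also terminates a run.  Weeks must be strictly
    increasing.
    """
    if isinstance(differences, Mapping):
        items = list(differences.items())
    else:
        items = list(differences)
    weeks = [int(w) for w, _ in items]
    if weeks != sorted(set(weeks)):
        raise ValueError("weeks must be strictly increasing")

    polygons: list[Polygon] = []
    run_sign: str | None = None
    run_start = run_end = 0
    prev_week: int | None = None

    def close() -> None:
        nonlocal run_sign
        if run_sign is not None:
            polygons.append(Polygon(run_sign, run_start, run_end))
            run_sign = None

    for w, d in items:
        sign = "excess" if d > 0 else "deficit" if d < 0 else None
        gap = prev_week is not None and w != prev_week + 1
        if sign is None or gap or sign != run_sign:
            close()
        if sign is not None and run_sign is None:
            run_sign, run_start = sign, w
        if sign is not None:
            run_end = w
        prev_week = w
    close()
    return polygons


@dataclass
class ExcessResult:
    """Per-week observed/reference/difference plus detected polygons."""

    target_year: int
    method: str
    measure_kind: str  # "count" | "rate"
    per_week: dict[int, WeekExcess]
    polygons: list[Polygon] = field(default_factory=list)
    period_years: tuple[int, ...] = ()

    @property
    def weeks(self) -> tuple[int, ...]:
        return tuple(sorted(self.per_week))

    def differences(self) -> dict[int, float]:
        return {w: self.per_week[w].difference for w in self.weeks}

    def polygon_of_week(self, week: int) -> int | None:
        """1-based index of the polygon covering *week*, or None."""
        for k, p in enumerate(self.polygons, start=1):
            if p.start_week <= week <= p.end_week:
                return k
        return None

    def to_frame(self) -> pd.DataFrame:
        """Tidy frame: week, observed, reference, difference, polygon_id, polygon_sign."""
        rows = []
        for w in self.weeks:
            rec = self.per_week[w]
            pid = self.polygon_of_week(w)
            rows.append({
                "week": w,
                "observed": rec.observed,
                "reference": rec.reference,
                "difference": rec.difference,
                "polygon_id": "" if pid is None else pid,
                "polygon_sign": "" if pid is None else self.polygons[pid - 1].sign,
            })
        return pd.DataFrame(rows, columns=["week", "observed", "reference",
                                           "difference", "polygon_id",
                                           "polygon_sign"])

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, index=False, lineterminator="\n")
        return path


def compute_excess(series: WeeklySeries, target_year: int,
                   level: ReferenceLevel) -> ExcessResult:
    """Difference the target year against a reference level.

    ``level.weeks`` must all be available in the target year of *series*;
    the per-week difference is the exact subtraction observed − reference.
    """
    if level.target_year is not None and level.target_year != target_year:
        raise EstimatorError(
            f"reference level was computed for target year {level.target_year}, "
            f"not {target_year}"
        )
    available = set(series.weeks_in_year(target_year))
    missing = [w for w in level.weeks if w not in available]
    if missing:
        raise EstimatorError(
            f"reference weeks {missing} are not available in target year "
            f"{target_year}"
        )
    per_week = {}
    for w in level.weeks:
        obs = series.values[(target_year, w)]
        ref = level.level[w]
        per_week[w] = WeekExcess(observed=obs, reference=ref,
                                 difference=obs - ref)
    result = ExcessResult(target_year=target_year, method=level.method,
                          measure_kind=series.kind, per_week=per_week,
                          period_years=level.period.years)
    result.polygons = detect_polygons(result.differences())
    return result


@dataclass(frozen=True)
class SelectionSummary:
    """Totals over a selected week range.

    For death counts the totals are sums over the selected available
    weeks; for rates they are unweighted means (exposures are not part of
    the data model).  ``weeks_excluded`` lists requested weeks that have
    no data — selections are week-dependent.
    """

    measure_kind: str
    week_from: int
    week_to: int
    weeks_used: tuple[int, ...]
    weeks_excluded: tuple[int, ...]
    observed_total: float
    reference_total: float
    excess_total: float


def summarize_selection(result: ExcessResult, week_from: int,
                        week_to: int) -> SelectionSummary:
    """Summarise the selection [week_from, week_to] of an excess result."""
    if week_to < week_from:
        raise SelectionError(f"empty week range {week_from}:{week_to}")
    requested = range(week_from, week_to + 1)
    used = tuple(w for w in requested if w in result.per_week)
    if not used:
        raise SelectionError(
            f"selection {week_from}:{week_to} does not intersect the result "
            f"weeks {result.weeks[0]}..{result.weeks[-1]}"
        )
    excluded = tuple(w for w in requested if w not in result.per_week)
    obs = [result.per_week[w].observed for w in used]
    ref = [result.per_week[w].reference for w in used]
    dif = [result.per_week[w].difference for w in used]
    if result.measure_kind == "count":
        agg = sum
    else:
        agg = lambda xs: sum(xs) / len(xs)
    return SelectionSummary(
        measure_kind=result.measure_kind,
        week_from=week_from, week_to=week_to,
        weeks_used=used, weeks_excluded=excluded,
        observed_total=float(agg(obs)),
        reference_total=float(agg(ref)),
        excess_total=float(agg(dif)),
    )


@dataclass(frozen=True)
class AxisScale:
    """Per-axis normalisation for nearest-point queries.

    Distances are Euclidean after dividing week offsets by ``week`` and
    value offsets by ``value`` — mirroring how a plot's aspect maps screen
    distance to data distance.
    """

    week: float = 1.0
    value: float = 1.0

    def __post_init__(self) -> None:
        if self.week <= 0 or self.value <= 0:
            raise ValueError("axis scales must be positive")


class NearestPoint(NamedTuple):
    year: int
    week: int
    value: float


def nearest_point(series: WeeklySeries, query_week: float, query_value: float,
                  scale: AxisScale = AxisScale()) -> NearestPoint:
    """Data point nearest to (query_week, query_value) under *scale*.

    Ties are broken toward the earlier year, then the earlier week —
    useful for spotting outliers such as heat-wave weeks in overlay plots.
    """
    if not series.values:
        raise SelectionError("series is empty")
    best: tuple[float, int, int] | None = None
    for (year, week), value in series.values.items():
        d = (((week - query_week) / scale.week) ** 2
             + ((value - query_value) / scale.value) ** 2)
        key = (d, year, week)
        if best is None or key < best:
            best = key
    _, year, week = best
    return NearestPoint(year=year, week=week, value=series.values[(year, week)])
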