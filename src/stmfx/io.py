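"""Reading, validating and writing STMF-style weekly mortality tables.

The Short-term Mortality Fluctuations (STMF) series of the Human Mortality
Database distributes, per country or region, weekly death counts and weekly
death rates (deaths per person-week) by sex and broad age group: 0-14,
15-64, 65-74, 75-84, 85+ and all ages combined.  This module reads and
writes CSV files in that shape, validates them, and extracts single weekly
series — one measure for one (country, sex) — which is the unit the
reference-level estimators consume.

Canonical column dialect::

    CountryCode,Year,Week,Sex,D0_14,D15_64,D65_74,D75_84,D85p,DTotal,
                              R0_14,R15_64,R65_74,R75_84,R85p,RTotal

Weeks are ISO-8601 week numbers taken as given (no date arithmetic); sex
codes are ``f``/``m``/``b``, case-insensitive on read and lower-case on
write.  Extra columns are ignored with a warning.  Lenient reading drops
offending rows and logs how many were dropped; it never imputes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import SchemaError, SelectionError, ValidationError

log = logging.getLogger("stmfx")

SEX_CODES = ("f", "m", "b")

AGE_GROUPS = ("0_14", "15_64", "65_74", "75_84", "85p", "total")

KEY_COLUMNS = ("CountryCode", "Year", "Week", "Sex")
DEATH_COLUMNS = ("D0_14", "D15_64", "D65_74", "D75_84", "D85p", "DTotal")
RATE_COLUMNS = ("R0_14", "R15_64", "R65_74", "R75_84", "R85p", "RTotal")
VALUE_COLUMNS = DEATH_COLUMNS + RATE_COLUMNS
CANONICAL_COLUMNS = KEY_COLUMNS + VALUE_COLUMNS

#: measure name (lower-case) -> canonical column.  ``d*`` are death counts,
#: ``r*`` are weekly death rates (deaths per person-week).
MEASURES: Mapping[str, str] = {
    **{f"d{g}".lower(): c for g, c in zip(AGE_GROUPS, DEATH_COLUMNS)},
    **{f"r{g}".lower(): c for g, c in zip(AGE_GROUPS, RATE_COLUMNS)},
}

MIN_YEAR = 1990


def iso_weeks_in_year(year: int) -> int:
    """Number of ISO-8601 weeks in *year* (52 or 53).

    A year has 53 ISO weeks exactly when 28 December falls in week 53.
    """
    return date(year, 12, 28).isocalendar()[1]


def measure_kind(measure: str) -> str:
    """``"count"`` for death-count measures, ``"rate"`` for rate measures."""
    m = measure.lower()
    if m not in MEASURES:
        raise SelectionError(
            f"unknown measure {measure!r}; valid measures: {sorted(MEASURES)}"
        )
    return "count" if m.startswith("d") else "rate"


# ---------------------------------------------------------------------------
# Table container
# ---------------------------------------------------------------------------


@dataclass
class WeeklyMortalityTable:
    """A validated long-format weekly mortality table.

    One row per (country, year, week, sex), carrying death counts and
    weekly rates for every age group.  Construction validates all
    invariants strictly; use :func:`read_stmf_csv` with ``strict=False``
    for the drop-and-log path.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = _validate_strict(self.data)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def countries(self) -> tuple[str, ...]:
        return tuple(sorted(self.data["CountryCode"].unique()))

    @property
    def years(self) -> tuple[int, ...]:
        return tuple(sorted(self.data["Year"].unique()))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WeeklyMortalityTable):
            return NotImplemented
        return self.data.reset_index(drop=True).equals(
            other.data.reset_index(drop=True)
        )


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def _check_rows(df: pd.DataFrame) -> pd.Series:
    """Return a Series of per-row error messages (empty string = valid).

    Operates on a frame with canonical columns and numeric value columns
    (NaN where coercion failed).
    """
    msg = pd.Series("", index=df.index, dtype=object)

    bad_sex = ~df["Sex"].isin(SEX_CODES)
    msg[bad_sex & (msg == "")] = "invalid sex code"

    year = df["Year"]
    bad_year = year.isna() | (year % 1 != 0) | (year < MIN_YEAR)
    msg[bad_year & (msg == "")] = f"year missing, non-integer or < {MIN_YEAR}"

    week = df["Week"]
    bad_week = week.isna() | (week % 1 != 0) | (week < 1) | (week > 53)
    msg[bad_week & (msg == "")] = "week outside 1..53"

    # week 53 only in years that actually have 53 ISO weeks
    ok_rows = ~(bad_year | bad_week)
    w53 = ok_rows & (df["Week"] == 53)
    if w53.any():
        years53 = df.loc[w53, "Year"].astype(int)
        bad_idx = years53.index[[iso_weeks_in_year(int(y)) != 53 for y in years53]]
        bad53 = pd.Series(df.index.isin(bad_idx), index=df.index)
        msg[bad53 & (msg == "")] = "week 53 in a 52-week ISO year"

    vals = df[list(VALUE_COLUMNS)]
    bad_val = vals.isna().any(axis=1) | ~np.isfinite(vals.fillna(0.0)).all(axis=1)
    msg[bad_val & (msg == "")] = "missing or non-finite value"
    neg = (vals < 0).any(axis=1)
    msg[neg & (msg == "")] = "negative value"

    # total deaths must dominate every age-group count
    age_max = df[list(DEATH_COLUMNS[:-1])].max(axis=1)
    bad_tot = (df["DTotal"] < age_max) & ~bad_val & ~neg
    msg[bad_tot & (msg == "")] = "DTotal below an age-group death count"

    return msg


def _coerce(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    out["CountryCode"] = out["CountryCode"].astype(str)
    out["Sex"] = out["Sex"].astype(str).str.strip().str.lower()
    for c in ("Year", "Week"):
        out[c] = pd.to_numeric(out[c], errors="coerce")
    for c in VALUE_COLUMNS:
        out[c] = pd.to_numeric(out[c], errors="coerce")
    return out


def _validate_strict(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    df = _coerce(df[list(CANONICAL_COLUMNS)])
    msg = _check_rows(df)
    bad = msg[msg != ""]
    if len(bad):
        i = bad.index[0]
        raise ValidationError(f"row {i}: {bad.iloc[0]}")
    dup = df.duplicated(subset=list(KEY_COLUMNS), keep=False)
    if dup.any():
        i = df.index[dup][0]
        key = tuple(df.loc[i, list(KEY_COLUMNS)])
        raise ValidationError(f"duplicate (country, year, week, sex) key {key} at row {i}")
    df["Year"] = df["Year"].astype(np.int64)
    df["Week"] = df["Week"].astype(np.int64)
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Read / write
# ---------------------------------------------------------------------------


def read_stmf_csv(path: str | Path, strict: bool = True) -> WeeklyMortalityTable:
    """Read an STMF-style CSV into a validated :class:`WeeklyMortalityTable`.

    Parameters
    ----------
    path
        CSV file with the canonical header (extra columns are ignored with
        a logged warning).
    strict
        If True (default) any invariant violation raises
        :class:`~stmfx.errors.ValidationError` naming the offending row.
        If False, offending rows (and later duplicates) are dropped and
        counted in the log; nothing is imputed.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    # round_trip float parsing keeps write∘read∘write byte-identical
    df = pd.read_csv(path, dtype={"CountryCode": str, "Sex": str},
                     float_precision="round_trip")
    missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path.name}: missing required column(s): {', '.join(missing)}"
        )
    extra = [c for c in df.columns if c not in CANONICAL_COLUMNS]
    if extra:
        log.warning("%s: ignoring %d extra column(s): %s", path.name, len(extra), extra)
    df = df[list(CANONICAL_COLUMNS)]
    if strict:
        return WeeklyMortalityTable(df)

    coerced = _coerce(df)
    msg = _check_rows(coerced)
    bad = msg != ""
    if bad.any():
        log.warning("%s: dropped %d invalid row(s)", path.name, int(bad.sum()))
        coerced = coerced[~bad]
    dup = coerced.duplicated(subset=list(KEY_COLUMNS), keep="first")
    if dup.any():
        log.warning("%s: dropped %d duplicate-key row(s)", path.name, int(dup.sum()))
        coerced = coerced[~dup]
    return WeeklyMortalityTable(coerced.reset_index(drop=True))


def write_stmf_csv(table: WeeklyMortalityTable, path: str | Path) -> Path:
    """Write *table* to *path* in the canonical CSV dialect.

    Writing is deterministic: reading the file back and writing again
    produces a byte-identical file.
    """
    path = Path(path)
    df = table.data[list(CANONICAL_COLUMNS)]
    df.to_csv(path, index=False, lineterminator="\n")
    return path


# ---------------------------------------------------------------------------
# Series extraction
# ---------------------------------------------------------------------------


@dataclass
class WeeklySeries:
    """One measure for one (country, sex): mapping (year, week) -> value.

    This is the object the reference-level estimators operate on; entries
    exist only for (year, week) cells actually present in the source table.
    """

    country_code: str
    sex: str
    measure: str
    values: dict[tuple[int, int], float] = field(default_factory=dict)

    @property
    def years(self) -> tuple[int, ...]:
        return tuple(sorted({y for y, _ in self.values}))

    @property
    def kind(self) -> str:
        return measure_kind(self.measure)

    def weeks_in_year(self, year: int) -> tuple[int, ...]:
        return tuple(sorted(w for y, w in self.values if y == year))

    def __len__(self) -> int:
        return len(self.values)

    def to_pandas(self) -> pd.Series:
        idx = pd.MultiIndex.from_tuples(sorted(self.values), names=["Year", "Week"])
        return pd.Series([self.values[k] for k in sorted(self.values)], index=idx,
                         name=self.measure)


def select_series(
    table: WeeklyMortalityTable, country: str, sex: str, measure: str
) -> WeeklySeries:
    """Extract a single :class:`WeeklySeries` from a table.

    The series contains exactly the (year, week) cells present for the
    (country, sex) key — no imputation.  Unknown country, sex or measure
    raises :class:`~stmfx.errors.SelectionError` listing the valid options.
    """
    sex = sex.lower()
    measure = measure.lower()
    if country not in table.countries:
        raise SelectionError(
            f"unknown country {country!r}; available: {list(table.countries)}"
        )
    if sex not in SEX_CODES:
        raise SelectionError(f"unknown sex {sex!r}; valid codes: {list(SEX_CODES)}")
    if measure not in MEASURES:
        raise SelectionError(
            f"unknown measure {measure!r}; valid measures: {sorted(MEASURES)}"
        )
    col = MEASURES[measure]
    df = table.data
    sub = df[(df["CountryCode"] == country) & (df["Sex"] == sex)]
    values = {
        (int(r.Year), int(r.Week)): float(getattr(r, col))
        for r in sub.itertuples(index=False)
    }
    return WeeklySeries(country_code=country, sex=sex, measure=measure, values=values)
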