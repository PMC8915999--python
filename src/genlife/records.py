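"""Shared record schema and date handling for genealogy microdata.

A record collection is a pandas DataFrame with one row per person and the
columns in :data:`RECORD_COLUMNS`.  Vital dates are stored as fractional
calendar years (e.g. 1700.5 is mid-1700); the companion ``*_precision``
column says how much of the date is actually known:

``day``
    the fractional year encodes an exact date;
``year``
    only the calendar year is known — the stored value is the integer year
    and downstream computations impute mid-year (July 1);
``missing``
    no date at all (stored as NaN).

On disk (delimited text) exact dates are ISO-8601 ``YYYY-MM-DD`` and
year-precision dates are bare years, mirroring the mixed precision of
crowdsourced genealogy exports.
"""

from __future__ import annotations

import datetime as _dt

import numpy as np
import pandas as pd

RECORD_COLUMNS = [
    "person_id",
    "sex",
    "birth",
    "birth_precision",
    "death",
    "death_precision",
    "birth_place",
    "death_place",
    "elite",
    "entry_age",
]

#: days per year used for the fractional-year <-> calendar-date conversion.
DAYS_PER_YEAR = 365.0


def frac_year_to_iso(y: float) -> str:
    """Convert a fractional year to an ISO-8601 date string (day precision)."""
    year = int(np.floor(y))
    # round (not floor) so day/365 -> date -> day/365 is a fixed point
    day = int(np.round((y - year) * DAYS_PER_YEAR))
    day = min(day, 364)
    date = _dt.date(year, 1, 1) + _dt.timedelta(days=day)
    return date.isoformat()


def iso_to_frac_year(s: str) -> float:
    """Convert an ISO-8601 date string to a fractional year."""
    date = _dt.date.fromisoformat(s)
    doy = (date - _dt.date(date.year, 1, 1)).days
    return date.year + doy / DAYS_PER_YEAR


def month_of(frac_year: float, precision: str) -> float:
    """1-based calendar month of a fractional-year date; NaN if not known."""
    if precision != "day" or not np.isfinite(frac_year):
        return np.nan
    frac = frac_year - np.floor(frac_year)
    return float(min(int(frac * 12) + 1, 12))


def effective_time(value: np.ndarray | pd.Series, precision: pd.Series) -> np.ndarray:
    """Date usable for Lexis arithmetic: mid-year imputed for year precision."""
    v = np.asarray(value, dtype=float).copy()
    year_only = np.asarray(precision) == "year"
    v[year_only] = np.floor(v[year_only]) + 0.5
    return v


def death_age(df: pd.DataFrame) -> np.ndarray:
    """Age at death in years.

    For year-precision pairs this reduces to death_year - birth_year, the
    standard convention when only years are recorded.
    """
    b = effective_time(df["birth"], df["birth_precision"])
    d = effective_time(df["death"], df["death_precision"])
    return d - b


def _date_to_text(value: float, precision: str) -> str:
    if precision == "missing" or not np.isfinite(value):
        return ""
    if precision == "year":
        return str(int(np.floor(value)))
    return frac_year_to_iso(value)


def _text_to_date(s: str) -> tuple[float, str]:
    s = s.strip()
    if not s:
        return np.nan, "missing"
    if "-" in s:
        return iso_to_frac_year(s), "day"
    return float(int(s)), "year"


def write_records(df: pd.DataFrame, path) -> None:
    """Write a record collection as delimited text (ISO dates / bare years)."""
    out = pd.DataFrame(
        {
            "person_id": df["person_id"],
            "sex": df["sex"],
            "birth_date": [
                _date_to_text(v, p) for v, p in zip(df["birth"], df["birth_precision"])
            ],
            "death_date": [
                _date_to_text(v, p) for v, p in zip(df["death"], df["death_precision"])
            ],
            "birth_place": df["birth_place"].fillna(""),
            "death_place": df["death_place"].fillna(""),
            "is_elite": df["elite"].map({True: "1", False: "0"}).fillna(""),
            "entry_age": df["entry_age"].map(
                lambda a: f"{a:.6f}" if np.isfinite(a) else ""
            ),
        }
    )
    out.to_csv(path, index=False)


def empty_records(n: int = 0) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "person_id": pd.Series([""] * n, dtype=object),
            "sex": pd.Series(["male"] * n, dtype=object),
            "birth": np.full(n, np.nan),
            "birth_precision": pd.Series(["missing"] * n, dtype=object),
            "death": np.full(n, np.nan),
            "death_precision": pd.Series(["missing"] * n, dtype=object),
            "birth_place": pd.Series([np.nan] * n, dtype=object),
            "death_place": pd.Series([np.nan] * n, dtype=object),
            "elite": np.zeros(n, dtype=bool),
            "entry_age": np.full(n, np.nan),
        }
    )
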