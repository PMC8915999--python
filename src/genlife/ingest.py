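"""Reading, territory assignment and cleaning of genealogy records.

The cleaning pipeline mirrors standard practice for crowdsourced
genealogy exports: restrict to one territory (a person belongs if born
and/or died there), drop exact duplicates, drop transcription errors
(death ages above 100 y), drop deaths after the last reliable year
(default 1910), keep males, and optionally drop records without exact
dates.  Every removal is counted in a report whose arithmetic must
reconcile.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .records import RECORD_COLUMNS, _text_to_date, death_age, empty_records

_PUNCT_RE = re.compile(r"[^\w\s]")
_WS_RE = re.compile(r"\s+")


def normalize_place(s) -> str:
    """Case-fold, strip accents and punctuation, collapse whitespace."""
    if s is None or (isinstance(s, float) and np.isnan(s)):
        return ""
    s = unicodedata.normalize("NFKD", str(s))
    s = "".join(c for c in s if not unicodedata.combining(c))
    s = _PUNCT_RE.sub("", s.casefold())
    return _WS_RE.sub(" ", s).strip()


@dataclass
class CleaningReport:
    """Per-stage removal counts for the cleaning pipeline."""

    n_input: int = 0
    n_after_territory: int | None = None
    n_non_male_removed: int = 0
    n_missing_date_removed: int = 0
    n_duplicates_removed: int = 0
    n_age_gt_max_removed: int = 0
    n_after_period_removed: int = 0
    n_missing_exact_date_removed: int = 0
    n_output: int = 0

    def reconciles(self) -> bool:
        removed = (
            self.n_non_male_removed
            + self.n_missing_date_removed
            + self.n_duplicates_removed
            + self.n_age_gt_max_removed
            + self.n_after_period_removed
            + self.n_missing_exact_date_removed
        )
        return self.n_input - removed == self.n_output

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(self)])


def packaged_cleaning_fixture_path():
    """Path of the packaged 10-record cleaning demonstration fixture."""
    from importlib.resources import files

    return files("genlife") / "data" / "cleaning_fixture.csv"


def read_records(path, schema: dict | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a delimited-text genealogy export.

    Parameters
    ----------
    path : path-like
        CSV file with a header row.  Dates are ISO-8601 or bare years.
    schema : dict, optional
        Maps the canonical column names (``person_id``, ``birth_date``,
        ``death_date``, ``sex``, ``birth_place``, ``death_place``,
        ``is_elite``, ``entry_age``) to the file's column names.

    Returns
    -------
    (records, rejects)
        Parsed records, and a rejects table with a ``reject_reason``
        column — malformed rows are collected, never silently dropped.
    """
    schema = schema or {}
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    if raw.empty:
        raise ValueError(f"empty input file: {path}")

    def col(name, default=None):
        actual = schema.get(name, name)
        if actual in raw.columns:
            return raw[actual]
        return pd.Series([default] * len(raw), index=raw.index)

    for mandatory in ("person_id", "birth_date", "death_date"):
        if schema.get(mandatory, mandatory) not in raw.columns:
            raise ValueError(f"missing mandatory column: {mandatory}")

    n = len(raw)
    out = empty_records(n)
    out["person_id"] = col("person_id").to_numpy()
    sex = col("sex", "male").replace("", "unknown")
    out["sex"] = sex.to_numpy()
    reject_reason = np.array([""] * n, dtype=object)

    for src, vcol, pcol in (
        ("birth_date", "birth", "birth_precision"),
        ("death_date", "death", "death_precision"),
    ):
        vals, precs = [], []
        for i, s in enumerate(col(src, "")):
            try:
                v, p = _text_to_date(s)
            except (ValueError, OverflowError):
                v, p = np.nan, "missing"
                if not reject_reason[i]:
                    reject_reason[i] = f"unparseable {src}: {s!r}"
            vals.append(v)
            precs.append(p)
        out[vcol] = vals
        out[pcol] = precs

    out["birth_place"] = col("birth_place", "").map(lambda s: s if s else np.nan).to_numpy()
    out["death_place"] = col("death_place", "").map(lambda s: s if s else np.nan).to_numpy()
    elite_raw = col("is_elite", "")
    out["elite"] = elite_raw.isin(["1", "true", "True"]).to_numpy()
    out["entry_age"] = pd.to_numeric(col("entry_age", ""), errors="coerce").to_numpy()

    both = out["birth"].notna() & out["death"].notna()
    bad_order = both & (out["death"].to_numpy() < out["birth"].to_numpy())
    reject_reason[bad_order.to_numpy() & (reject_reason == "")] = "death before birth"

    rejected = reject_reason != ""
    rejects = out.loc[rejected].copy()
    rejects["reject_reason"] = reject_reason[rejected]
    return out.loc[~rejected].reset_index(drop=True), rejects.reset_index(drop=True)


def assign_territory(
    records: pd.DataFrame, territory_rule: Callable[[str], bool]
) -> np.ndarray:
    """Boolean mask: person linked to the territory.

    A person belongs if the birth place OR the death place satisfies the
    predicate (evaluated on normalized place strings).  Records with both
    places missing are excluded.
    """
    bp = records["birth_place"].map(normalize_place)
    dp = records["death_place"].map(normalize_place)
    in_b = bp.map(lambda s: bool(s) and bool(territory_rule(s)))
    in_d = dp.map(lambda s: bool(s) and bool(territory_rule(s)))
    return (in_b | in_d).to_numpy()


def clean_records(
    records: pd.DataFrame,
    max_age: float = 100.0,
    last_year: float = 1910.0,
    sex: str | None = "male",
    drop_inexact_dates: bool = False,
) -> tuple[pd.DataFrame, CleaningReport]:
    """Apply the exclusion rules and return survivors plus a count report.

    Rules, in order: sex filter; records lacking a usable birth or death
    date; exact duplicates (same birth date, death date and normalized
    birth place — the lexicographically smallest person_id survives);
    death age above `max_age`; death year after `last_year` (deaths in
    `last_year` itself are retained); optionally any record whose dates
    are not day-precision.

    The pipeline is idempotent and order-invariant: permuting the input
    rows changes neither the survivor set nor the report.
    """
    report = CleaningReport(n_input=len(records))
    df = records.copy()

    if sex is not None:
        keep = df["sex"] == sex
        report.n_non_male_removed = int((~keep).sum())
        df = df.loc[keep]

    usable = df["birth"].notna() & df["death"].notna()
    report.n_missing_date_removed = int((~usable).sum())
    df = df.loc[usable]

    # deterministic duplicate tie-break: keep smallest person_id
    df = df.sort_values("person_id", kind="mergesort")
    key = pd.DataFrame(
        {
            "b": df["birth"].round(9),
            "d": df["death"].round(9),
            "p": df["birth_place"].map(normalize_place),
        },
        index=df.index,
    )
    dup = key.duplicated(keep="first")
    report.n_duplicates_removed = int(dup.sum())
    df = df.loc[~dup]

    age = death_age(df)
    over = age > max_age
    report.n_age_gt_max_removed = int(over.sum())
    df = df.loc[~over]

    late = np.floor(df["death"].to_numpy(float)) > last_year
    report.n_after_period_removed = int(late.sum())
    df = df.loc[~late]

    if drop_inexact_dates:
        exact = (df["birth_precision"] == "day") & (df["death_precision"] == "day")
        report.n_missing_exact_date_removed = int((~exact).sum())
        df = df.loc[exact]

    df = df.sort_values("person_id", kind="mergesort").reset_index(drop=True)
    report.n_output = len(df)
    assert report.reconciles()
    return df[RECORD_COLUMNS], report
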