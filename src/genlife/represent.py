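"""Coverage, elite oversampling and record-linkage diagnostics.

Three questions about a genealogy sample: how much of the real population
does it hold in any given year (coverage), how strongly are elites
overrepresented (the oversampling factor), and does either diagnostic
predict how closely the sample's mortality estimates track the elite
rather than the general population (the coverage/oversampling vs
resemblance correlations)?
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np
import pandas as pd

from .ingest import normalize_place
from .records import effective_time, month_of


@dataclass
class MatchResult:
    roster_id: str
    genealogy_id: str
    match_score: float
    matched_on: tuple


def interpolate_population(points: pd.DataFrame, years) -> pd.Series:
    """Log-linear interpolation of population size between point estimates.

    Exponential growth between consecutive anchors — the standard model
    for historical population series.  Extrapolation outside the anchor
    span is refused.
    """
    pts = points.sort_values("year")
    yrs = pts["year"].to_numpy(float)
    cnt = pts["count"].to_numpy(float)
    if len(yrs) < 2:
        raise ValueError("need at least two population anchor points")
    if np.any(cnt <= 0):
        raise ValueError("population anchors must be positive for log interpolation")
    years = np.asarray(years, dtype=float)
    if years.min() < yrs[0] or years.max() > yrs[-1]:
        raise ValueError("population interpolation requested outside anchor span")
    vals = np.exp(np.interp(years, yrs, np.log(cnt)))
    return pd.Series(vals, index=years, name="population")


def alive_counts(records: pd.DataFrame, years) -> np.ndarray:
    """Interval-stabbing alive counts (birth <= t < death) per queried year."""
    b = effective_time(records["birth"], records["birth_precision"])
    d = effective_time(records["death"], records["death_precision"])
    ok = np.isfinite(b) & np.isfinite(d)
    b, d = b[ok], d[ok]
    years = np.asarray(years, dtype=float)
    return np.array([int(((b <= y) & (y < d)).sum()) for y in years])


def coverage_series(records: pd.DataFrame, population: pd.Series) -> pd.DataFrame:
    """Yearly share of the real population present in the sample.

    `population` is an interpolated year -> size series.  Values above 1
    are kept but flagged as anomalies.
    """
    years = np.asarray(population.index, dtype=float)
    pop = population.to_numpy(float)
    if np.any(pop <= 0):
        raise ValueError("population size must be positive at every queried year")
    alive = alive_counts(records, years)
    cov = alive / pop
    return pd.DataFrame(
        {
            "year": years,
            "n_alive_sample": alive,
            "population_size": pop,
            "coverage": cov,
            "anomaly": cov > 1.0,
        }
    )


def _place_similarity(a: str, b: str) -> float:
    """1 - normalized Levenshtein distance on normalized place strings."""
    a, b = normalize_place(a), normalize_place(b)
    if not a or not b:
        return 0.0
    dist = edlib.align(a, b)["editDistance"]
    return 1.0 - dist / max(len(a), len(b))


def match_scholars(
    records: pd.DataFrame,
    roster: pd.DataFrame,
    year_tolerance: int = 1,
    require_month: bool = True,
    place_threshold: float = 0.85,
) -> tuple[list[MatchResult], list[str]]:
    """Link a scholar roster into the genealogy by vital-date pattern matching.

    Candidates are blocked on birth and death year within `year_tolerance`;
    a candidate is confirmed when months agree where both sides know them
    (if `require_month`) and the best of birth-place/death-place
    similarity reaches `place_threshold`.  Conflicts are resolved one-to-
    one by descending score with a deterministic identifier tie-break.

    Returns (matches, unmatched_roster_ids).
    """
    b = effective_time(records["birth"], records["birth_precision"])
    d = effective_time(records["death"], records["death_precision"])
    b_year = np.floor(b)
    d_year = np.floor(d)
    b_month = np.array(
        [month_of(v, p) for v, p in zip(records["birth"], records["birth_precision"])]
    )
    d_month = np.array(
        [month_of(v, p) for v, p in zip(records["death"], records["death_precision"])]
    )
    rec_ids = records["person_id"].to_numpy()
    rec_bp = records["birth_place"].to_numpy(object)
    rec_dp = records["death_place"].to_numpy(object)

    candidates: list[tuple[float, str, str, tuple]] = []
    for row in roster.itertuples(index=False):
        near = (
            (np.abs(b_year - row.birth_year) <= year_tolerance)
            & (np.abs(d_year - row.death_year) <= year_tolerance)
            & np.isfinite(b)
            & np.isfinite(d)
        )
        for idx in np.where(near)[0]:
            fields = ["birth_year", "death_year"]
            months_ok = True
            month_hits = 0
            for rec_m, ros_m, tag in (
                (b_month[idx], row.birth_month, "birth_month"),
                (d_month[idx], row.death_month, "death_month"),
            ):
                if np.isfinite(rec_m) and ros_m > 0:
                    if int(rec_m) == int(ros_m):
                        month_hits += 1
                        fields.append(tag)
                    else:
                        months_ok = False
            if require_month and not months_ok:
                continue
            sim = max(
                _place_similarity(rec_bp[idx], row.birth_place),
                _place_similarity(rec_dp[idx], row.death_place),
            )
            if sim < place_threshold:
                continue
            fields.append("place")
            year_slack = abs(b_year[idx] - row.birth_year) + abs(
                d_year[idx] - row.death_year
            )
            score = sim + 0.5 * month_hits - 0.1 * year_slack
            candidates.append((score, row.roster_id, rec_ids[idx], tuple(fields)))

    # greedy one-to-one resolution, highest score first, stable id tie-break
    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
    used_roster: set = set()
    used_record: set = set()
    matches: list[MatchResult] = []
    for score, rid, gid, fields in candidates:
        if rid in used_roster or gid in used_record:
            continue
        used_roster.add(rid)
        used_record.add(gid)
        matches.append(MatchResult(rid, gid, float(score), fields))
    unmatched = [r for r in roster["roster_id"] if r not in used_roster]
    return matches, unmatched


def oversampling_series(
    records: pd.DataFrame,
    matched_ids: set,
    scholar_population_counts: dict,
    population: pd.Series,
    periods: list[tuple[float, float]],
) -> pd.DataFrame:
    """Per-period elite oversampling factor.

    oversampling = (matched scholars alive / sample alive)
                 / (scholars in population / population size),
    with alive counts taken at the period midpoint.  Zero denominators
    yield NaN with an ``undefined`` flag, never a silent drop.
    """
    is_scholar = records["person_id"].isin(matched_ids).to_numpy()
    rows = []
    for lo, hi in periods:
        mid = 0.5 * (lo + hi)
        alive = alive_counts(records, [mid])[0]
        alive_sch = alive_counts(records.loc[is_scholar], [mid])[0]
        pop = float(np.exp(np.interp(mid, np.asarray(population.index, float),
                                     np.log(population.to_numpy(float)))))
        sch_pop = float(scholar_population_counts.get((lo, hi), np.nan))
        share_s = alive_sch / alive if alive > 0 else np.nan
        share_p = sch_pop / pop if pop > 0 and np.isfinite(sch_pop) else np.nan
        ratio = share_s / share_p if share_p and np.isfinite(share_p) and share_p > 0 else np.nan
        rows.append(
            {
                "period_lo": lo,
                "period_hi": hi,
                "share_scholars_sample": share_s,
                "share_scholars_population": share_p,
                "oversampling": ratio,
                "undefined": not np.isfinite(ratio),
            }
        )
    return pd.DataFrame(rows)


def resemblance_correlation(
    e30_sample: np.ndarray, e30_elite: np.ndarray, driver: np.ndarray
) -> float:
    """Pearson correlation between a driver series and sample-elite resemblance.

    Resemblance in period t is -|e30_sample(t) - e30_elite(t)|: larger
    means the sample's mortality looks more like the elite's.  A negative
    correlation with coverage says better-covered periods resemble the
    elite less; a positive correlation with oversampling says elite-heavy
    periods resemble it more.
    """
    e30_sample = np.asarray(e30_sample, float)
    e30_elite = np.asarray(e30_elite, float)
    driver = np.asarray(driver, float)
    if not (len(e30_sample) == len(e30_elite) == len(driver)):
        raise ValueError("series must be aligned on common periods")
    if len(driver) < 3:
        raise ValueError("need at least 3 periods")
    resemblance = -np.abs(e30_sample - e30_elite)
    if np.std(resemblance) == 0 or np.std(driver) == 0:
        raise ValueError("zero variance: correlation undefined")
    return float(np.corrcoef(driver, resemblance)[0, 1])
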