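"""Lexis tabulation: deaths and person-year exposures on an age x period grid.

Lifelines (birth to death, optionally entered late at an appointment age —
left truncation) are cut into half-open age intervals [a, a+w) crossed
with half-open calendar periods.  The grid also accumulates, per cell, the
summed age-within-interval at death, from which the observed average
person-years lived by those dying in an interval (Chiang's a_x) can be
recovered for life-table construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .records import effective_time


@dataclass
class LexisGrid:
    """Death counts and person-year exposures on an age x period lattice.

    All intervals are half-open [lo, hi); the last age interval is the
    open age group, closed at the configured maximum age.
    """

    age_edges: np.ndarray  # length n_age + 1
    period_edges: np.ndarray  # length n_period + 1
    deaths: np.ndarray  # (n_age, n_period) int
    exposures: np.ndarray  # (n_age, n_period) float
    death_offset_sum: np.ndarray  # (n_age, n_period): sum of (death age - age lo)
    truncated: bool = False
    n_excluded_no_death: int = 0

    def __post_init__(self) -> None:
        shape = (len(self.age_edges) - 1, len(self.period_edges) - 1)
        for name in ("deaths", "exposures", "death_offset_sum"):
            arr = getattr(self, name)
            if arr.shape != shape:
                raise ValueError(f"{name} has shape {arr.shape}, expected {shape}")
        if np.any(self.deaths < 0) or np.any(self.exposures < 0):
            raise ValueError("deaths and exposures must be non-negative")

    @property
    def n_age(self) -> int:
        return len(self.age_edges) - 1

    @property
    def n_period(self) -> int:
        return len(self.period_edges) - 1

    def age_mid(self) -> np.ndarray:
        return 0.5 * (self.age_edges[:-1] + self.age_edges[1:])

    def period_mid(self) -> np.ndarray:
        return 0.5 * (self.period_edges[:-1] + self.period_edges[1:])

    def period_slice(self, period: tuple[float, float]) -> "LexisGrid":
        """Sub-grid restricted to periods inside [lo, hi)."""
        lo, hi = period
        keep = (self.period_edges[:-1] >= lo) & (self.period_edges[1:] <= hi)
        idx = np.where(keep)[0]
        if len(idx) == 0:
            raise ValueError(f"no grid periods inside {period}")
        edges = np.append(self.period_edges[:-1][idx], self.period_edges[idx[-1] + 1])
        return LexisGrid(
            self.age_edges,
            edges,
            self.deaths[:, idx],
            self.exposures[:, idx],
            self.death_offset_sum[:, idx],
            self.truncated,
        )

    def marginal_by_age(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Deaths, exposures and observed a_x aggregated over all periods.

        a_x falls back to the interval midpoint where a group has no
        deaths.
        """
        d = self.deaths.sum(axis=1)
        e = self.exposures.sum(axis=1)
        widths = np.diff(self.age_edges)
        with np.errstate(invalid="ignore", divide="ignore"):
            ax = np.where(d > 0, self.death_offset_sum.sum(axis=1) / np.maximum(d, 1),
                          widths / 2.0)
        return d, e, ax

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i in range(self.n_age):
            for j in range(self.n_period):
                rows.append(
                    {
                        "age_lo": self.age_edges[i],
                        "age_hi": self.age_edges[i + 1],
                        "period_lo": self.period_edges[j],
                        "period_hi": self.period_edges[j + 1],
                        "deaths": int(self.deaths[i, j]),
                        "exposure": self.exposures[i, j],
                    }
                )
        return pd.DataFrame(rows)


def person_cell_exposure(
    birth: float,
    death: float,
    age_cell: tuple[float, float],
    period_cell: tuple[float, float],
    entry_age: float | None = None,
) -> float:
    """Person-years one lifeline spends in one age x period cell.

    The lifeline under observation is [birth + entry_age, death) (entry
    defaults to birth); its intersection with the band of ages
    [age_lo, age_hi) and the period window gives the exposure.
    """
    if entry_age is not None and np.isfinite(entry_age):
        if birth + entry_age > death:
            raise ValueError("entry_age exceeds age at death")
        start = birth + max(entry_age, 0.0)
    else:
        start = birth
    a_lo, a_hi = age_cell
    p_lo, p_hi = period_cell
    lo = max(start, birth + a_lo, p_lo)
    hi = min(death, birth + a_hi, p_hi)
    return max(0.0, hi - lo)


def tabulate(
    records: pd.DataFrame,
    age_edges,
    period_edges,
    use_entry_age: bool = False,
    right_censor_to: float | None = None,
) -> LexisGrid:
    """Tabulate records into a LexisGrid.

    Deaths are tallied by age at death and period of death (each death in
    exactly one cell); exposures accumulate person-years per cell.  With
    ``use_entry_age`` false, entry ages are ignored — the untruncated
    ("woLT") variant.  Records without a death date are excluded and
    counted, unless ``right_censor_to`` is set, in which case they
    contribute exposure up to that calendar time.

    Year-precision dates have already been imputed at mid-year by
    :func:`genlife.records.effective_time`.
    """
    if len(records) == 0:
        raise ValueError("no records to tabulate")
    age_edges = np.asarray(age_edges, dtype=float)
    period_edges = np.asarray(period_edges, dtype=float)

    birth = effective_time(records["birth"], records["birth_precision"])
    death = effective_time(records["death"], records["death_precision"])
    has_death = np.isfinite(death)

    entry = records["entry_age"].to_numpy(dtype=float)
    if not use_entry_age:
        entry = np.full(len(records), np.nan)
    start = birth + np.where(np.isfinite(entry), np.maximum(entry, 0.0), 0.0)
    if np.any(has_death & (start > death)):
        raise ValueError("entry_age exceeds age at death for some records")

    n_excluded = 0
    if right_censor_to is None:
        keep = has_death
        n_excluded = int((~has_death).sum())
        birth, death, start = birth[keep], death[keep], start[keep]
        has_death = has_death[keep]
        end = death
    else:
        end = np.where(has_death, death, right_censor_to)

    n_age, n_period = len(age_edges) - 1, len(period_edges) - 1
    deaths = np.zeros((n_age, n_period), dtype=int)
    exposures = np.zeros((n_age, n_period))
    offsets = np.zeros((n_age, n_period))

    # exposures: loop over cells, vectorized over persons
    for i in range(n_age):
        seg_lo = np.maximum(start, birth + age_edges[i])
        seg_hi = np.minimum(end, birth + age_edges[i + 1])
        for j in range(n_period):
            lo = np.maximum(seg_lo, period_edges[j])
            hi = np.minimum(seg_hi, period_edges[j + 1])
            exposures[i, j] = np.maximum(0.0, hi - lo).sum()

    # deaths: histogram over (age at death, time of death)
    da = (death - birth)[has_death]
    dt = death[has_death]
    in_grid = (
        (da >= age_edges[0]) & (da <= age_edges[-1])
        & (dt >= period_edges[0]) & (dt < period_edges[-1])
    )
    da, dt = da[in_grid], dt[in_grid]
    ai = np.minimum(np.searchsorted(age_edges, da, side="right") - 1, n_age - 1)
    pj = np.searchsorted(period_edges, dt, side="right") - 1
    np.add.at(deaths, (ai, pj), 1)
    np.add.at(offsets, (ai, pj), da - age_edges[ai])

    return LexisGrid(
        age_edges, period_edges, deaths, exposures, offsets,
        truncated=use_entry_age, n_excluded_no_death=n_excluded,
    )


def write_grid(grid: LexisGrid, path) -> None:
    grid.to_frame().to_csv(path, index=False)
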