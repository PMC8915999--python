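"""Synthetic genealogy worlds with known ground truth.

Generates a closed male population under a Gompertz–Makeham mortality
regime, an ascertainment-biased genealogy sample of it (emulating the
structure and failure modes of crowdsourced genealogy exports: duplicates,
transcription errors producing impossible ages, year-only dates,
time-varying inclusion and elite oversampling), a scholar roster for the
elite stratum, and sparse historical population-size point estimates.

The hazard at age x for a non-elite is

    mu(x) = c + a * exp(b * x)

(Makeham constant ``c``, Gompertz level ``a`` and slope ``b``); elites have
their entire hazard multiplied by ``elite_hazard_ratio`` (< 1 means an
elite survival advantage).  ``period_trend`` applies a multiplicative
annual drift to ``a`` by birth cohort, anchored at the midpoint of the
birth-year range.  Lifespans are drawn by inverting the survival function
(bisection on the cumulative hazard, tolerance 1e-8 y), so the generated
distribution is exact, not an approximation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate

from .records import empty_records

_MAX_AGE = 5000.0  # search bracket cap for hazard inversion


@dataclass
class MortalityModel:
    """Gompertz–Makeham mortality regime, optionally degenerate.

    Parameters
    ----------
    makeham_c : float
        Age-independent hazard per year (background mortality), >= 0.
    gompertz_a : float
        Senescent hazard per year at age 0, > 0.
    gompertz_b : float
        Log-hazard slope per year of age, >= 0.
    period_trend : float
        Multiplicative annual change applied to ``gompertz_a`` by birth
        cohort (1.0 = stationary regime).
    elite_hazard_ratio : float
        Multiplier on the whole hazard for the elite stratum; < 1 encodes
        an elite mortality advantage.
    point_mass_age : float or None
        If set, every lifespan equals this age exactly (degenerate mode
        used for analytic checks).
    """

    makeham_c: float = 0.005
    gompertz_a: float = 1e-4
    gompertz_b: float = 0.09
    period_trend: float = 1.0
    elite_hazard_ratio: float = 1.0
    point_mass_age: float | None = None

    def __post_init__(self) -> None:
        if self.makeham_c < 0:
            raise ValueError("makeham_c must be >= 0")
        if self.gompertz_a <= 0:
            raise ValueError("gompertz_a must be > 0")
        if self.gompertz_b < 0:
            raise ValueError("gompertz_b must be >= 0")
        if self.elite_hazard_ratio <= 0:
            raise ValueError("elite_hazard_ratio must be > 0")
        if self.period_trend <= 0:
            raise ValueError("period_trend must be > 0")

    def level_at(self, cohort_offset: float = 0.0) -> float:
        """Gompertz level ``a`` for a cohort born `cohort_offset` years after the anchor."""
        return self.gompertz_a * self.period_trend**cohort_offset

    def cumulative_hazard(
        self, x: np.ndarray, *, elite: bool = False, cohort_offset: float = 0.0
    ) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        a = self.level_at(cohort_offset)
        if self.gompertz_b > 0:
            # overflow at extreme ages is benign: inf hazard -> survival 0
            with np.errstate(over="ignore"):
                h = self.makeham_c * x + (a / self.gompertz_b) * np.expm1(
                    self.gompertz_b * x
                )
        else:
            h = (self.makeham_c + a) * x
        if elite:
            h = h * self.elite_hazard_ratio
        return h

    def survival(
        self, x: np.ndarray, *, elite: bool = False, cohort_offset: float = 0.0
    ) -> np.ndarray:
        return np.exp(-self.cumulative_hazard(x, elite=elite, cohort_offset=cohort_offset))


@dataclass
class AscertainmentModel:
    """How the genealogy sample is drawn from the population.

    Inclusion probability for a person born in year t is
    ``clamp(base_inclusion + inclusion_time_slope * (t - anchor))`` times
    ``elite_inclusion_multiplier`` if elite, clamped to [0, 1]; the anchor
    is the midpoint of the population's birth-year range.  Error processes
    (duplication, age inflation past 100 y, loss of date precision) act on
    the included records.
    """

    base_inclusion: float = 0.1
    inclusion_time_slope: float = 0.0
    elite_inclusion_multiplier: float = 1.0
    duplicate_rate: float = 0.0
    age_error_rate: float = 0.0
    missing_exact_date_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("base_inclusion", "duplicate_rate", "age_error_rate",
                     "missing_exact_date_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.elite_inclusion_multiplier < 1.0:
            raise ValueError("elite_inclusion_multiplier must be >= 1")


@dataclass
class SimulationTruth:
    """Ground truth recorded while generating / sampling a synthetic world."""

    true_e30_by_period: dict = field(default_factory=dict)
    true_gini30_by_period: dict = field(default_factory=dict)
    true_coverage_by_year: dict = field(default_factory=dict)
    true_oversampling_by_period: dict = field(default_factory=dict)
    scholar_ids: set = field(default_factory=set)
    elite_ids: set = field(default_factory=set)
    roster_to_person: dict = field(default_factory=dict)


def draw_lifespans(
    n: int,
    mortality: MortalityModel,
    rng: np.random.Generator,
    *,
    elite: bool = False,
    cohort_offset: float = 0.0,
) -> np.ndarray:
    """Draw lifespans by inverse-CDF on the survival function.

    Solves H(x) = -log(U) by bisection to 1e-8 y; exact for any valid
    parameter combination, including the pure-exponential limit b = 0.
    """
    if mortality.point_mass_age is not None:
        return np.full(n, float(mortality.point_mass_age))
    u = rng.uniform(size=n)
    target = -np.log(u)
    if elite:
        target = target / mortality.elite_hazard_ratio

    def cumhaz(x):
        return mortality.cumulative_hazard(x, cohort_offset=cohort_offset)

    hi = 120.0
    while cumhaz(np.array([hi]))[0] < target.max() and hi < _MAX_AGE:
        hi *= 2.0
    lo_v = np.zeros(n)
    hi_v = np.full(n, hi)
    # 64 bisection steps: bracket / 2^64 << 1e-8
    for _ in range(64):
        mid = 0.5 * (lo_v + hi_v)
        below = cumhaz(mid) < target
        lo_v = np.where(below, mid, lo_v)
        hi_v = np.where(below, hi_v, mid)
    return 0.5 * (lo_v + hi_v)


def _check_convergent(mortality: MortalityModel) -> None:
    if mortality.point_mass_age is not None:
        return
    if mortality.gompertz_b == 0 and mortality.makeham_c + mortality.gompertz_a <= 0:
        raise ValueError("remaining-lifespan integral does not converge: zero hazard")


def analytic_remaining_e30(
    mortality: MortalityModel, age: float = 30.0, *, elite: bool = False,
    cohort_offset: float = 0.0,
) -> float:
    """Remaining life expectancy at `age` by adaptive quadrature.

    Computes integral of S(age+u)/S(age) du over u >= 0 — the truth value
    for every e30 recovery test.
    """
    if mortality.point_mass_age is not None:
        if mortality.point_mass_age < age:
            raise ValueError("point mass below conditioning age")
        return float(mortality.point_mass_age - age)
    _check_convergent(mortality)
    h_age = mortality.cumulative_hazard(
        np.array([age]), elite=elite, cohort_offset=cohort_offset
    )[0]

    def integrand(u):
        h = mortality.cumulative_hazard(
            np.array([age + u]), elite=elite, cohort_offset=cohort_offset
        )[0]
        return np.exp(-(h - h_age))

    val, _ = integrate.quad(integrand, 0, np.inf, limit=500)
    return float(val)


def analytic_remaining_gini(
    mortality: MortalityModel, age: float = 30.0, *, elite: bool = False,
    cohort_offset: float = 0.0,
) -> float:
    """Gini of remaining lifespan at `age`: int S(1-S) du / int S du."""
    if mortality.point_mass_age is not None:
        return 0.0
    _check_convergent(mortality)
    h_age = mortality.cumulative_hazard(
        np.array([age]), elite=elite, cohort_offset=cohort_offset
    )[0]

    def surv(u):
        h = mortality.cumulative_hazard(
            np.array([age + u]), elite=elite, cohort_offset=cohort_offset
        )[0]
        return np.exp(-(h - h_age))

    num, _ = integrate.quad(lambda u: surv(u) * (1 - surv(u)), 0, np.inf, limit=500)
    den, _ = integrate.quad(surv, 0, np.inf, limit=500)
    return float(num / den)


def generate_population(
    n: int,
    mortality: MortalityModel,
    birth_year_range: tuple[float, float] = (1500.0, 1910.0),
    elite_fraction: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Generate a closed male population with exact vital dates.

    Birth times are uniform over `birth_year_range`; lifespans come from
    `draw_lifespans` with the elite hazard ratio applied to the elite
    stratum.  Deterministic under a fixed seed.
    """
    if n <= 0:
        raise ValueError("n must be > 0")
    if not 0.0 <= elite_fraction <= 1.0:
        raise ValueError("elite_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    lo, hi = birth_year_range
    anchor = 0.5 * (lo + hi)
    births = rng.uniform(lo, hi, size=n)
    elite = rng.uniform(size=n) < elite_fraction

    lifespans = np.empty(n)
    # cohort drift applied at decade resolution to keep inversion vectorized
    decades = np.floor((births - anchor) / 10.0) * 10.0 + 5.0
    for off in np.unique(decades):
        for is_el in (False, True):
            m = (decades == off) & (elite == is_el)
            if m.any():
                lifespans[m] = draw_lifespans(
                    int(m.sum()), mortality, rng, elite=is_el, cohort_offset=float(off)
                )

    df = empty_records(n)
    width = len(str(n))
    df["person_id"] = [f"P{i:0{width}d}" for i in range(n)]
    df["birth"] = births
    df["birth_precision"] = "day"
    df["death"] = births + lifespans
    df["death_precision"] = "day"
    df["birth_place"] = np.where(elite, "Altstadt", "Neudorf")
    df["death_place"] = np.where(elite, "Altstadt", "Neudorf")
    df["elite"] = elite

    truth = SimulationTruth(elite_ids=set(df.loc[elite, "person_id"]))
    for start in np.arange(np.floor(lo / 10) * 10, hi, 10.0):
        off = start + 5.0 - anchor
        key = (float(start), float(start + 10.0))
        truth.true_e30_by_period[key] = analytic_remaining_e30(
            mortality, cohort_offset=off
        )
        truth.true_gini30_by_period[key] = analytic_remaining_gini(
            mortality, cohort_offset=off
        )
    return df, truth


def sample_genealogy(
    population: pd.DataFrame,
    model: AscertainmentModel,
    seed: int = 0,
    truth: SimulationTruth | None = None,
) -> pd.DataFrame:
    """Draw an ascertainment-biased genealogy sample from a population.

    Each person is included independently with the clamped inclusion
    probability; included records then suffer the configured error
    processes.  Realized coverage (per year) and elite oversampling (per
    decade) are recorded into `truth` when given.
    """
    if len(population) == 0:
        raise ValueError("population is empty")
    rng = np.random.default_rng(seed)
    births = population["birth"].to_numpy(dtype=float)
    anchor = 0.5 * (births.min() + births.max())
    p = np.clip(
        model.base_inclusion + model.inclusion_time_slope * (births - anchor), 0.0, 1.0
    )
    elite = population["elite"].to_numpy(dtype=bool)
    p = np.clip(np.where(elite, p * model.elite_inclusion_multiplier, p), 0.0, 1.0)
    included = rng.uniform(size=len(population)) < p
    sample = population.loc[included].copy().reset_index(drop=True)

    if truth is not None:
        _record_sampling_truth(population, sample, truth)

    # error processes act on the included records
    n = len(sample)
    if n and model.age_error_rate > 0:
        bad = rng.uniform(size=n) < model.age_error_rate
        sample.loc[bad, "death"] = sample.loc[bad, "birth"] + rng.uniform(
            101.0, 110.0, size=int(bad.sum())
        )
    if n and model.missing_exact_date_rate > 0:
        yo = rng.uniform(size=n) < model.missing_exact_date_rate
        for col, prec in (("birth", "birth_precision"), ("death", "death_precision")):
            sample.loc[yo, col] = np.floor(sample.loc[yo, col])
            sample.loc[yo, prec] = "year"
    if n and model.duplicate_rate > 0:
        dup = rng.uniform(size=n) < model.duplicate_rate
        dups = sample.loc[dup].copy()
        # near-copies: same vital dates, perturbed place strings (case /
        # punctuation only, so place normalization collapses them)
        dups["person_id"] = dups["person_id"] + "_dup"
        dups["birth_place"] = dups["birth_place"].map(
            lambda s: s.upper() + "." if isinstance(s, str) else s
        )
        dups["death_place"] = dups["death_place"].map(
            lambda s: (" " + s.lower()) if isinstance(s, str) else s
        )
        sample = pd.concat([sample, dups], ignore_index=True)
    return sample


def _record_sampling_truth(
    population: pd.DataFrame, sample: pd.DataFrame, truth: SimulationTruth
) -> None:
    pb = population["birth"].to_numpy(float)
    pd_ = population["death"].to_numpy(float)
    sb = sample["birth"].to_numpy(float)
    sd = sample["death"].to_numpy(float)
    years = np.arange(np.floor(pb.min()), np.ceil(pd_.max()) + 1)
    for y in years:
        alive_pop = int(((pb <= y) & (y < pd_)).sum())
        alive_samp = int(((sb <= y) & (y < sd)).sum())
        if alive_pop > 0:
            truth.true_coverage_by_year[float(y)] = alive_samp / alive_pop
    pe = population["elite"].to_numpy(bool)
    se = sample["elite"].to_numpy(bool)
    for start in np.arange(np.floor(pb.min() / 10) * 10, pd_.max(), 10.0):
        mid = start + 5.0
        pop_alive = (pb <= mid) & (mid < pd_)
        samp_alive = (sb <= mid) & (mid < sd)
        if pop_alive.sum() and samp_alive.sum() and pe[pop_alive].mean() > 0:
            share_pop = pe[pop_alive].mean()
            share_samp = se[samp_alive].mean()
            truth.true_oversampling_by_period[(float(start), float(start + 10))] = (
                share_samp / share_pop
            )


def generate_scholar_roster(
    population: pd.DataFrame,
    appointment_age_distribution: tuple = ("uniform", 30.0, 45.0),
    seed: int = 0,
    truth: SimulationTruth | None = None,
    date_noise_rate: float = 0.0,
) -> pd.DataFrame:
    """Build a scholar roster from the elite stratum.

    Scholars are elites who survive to their independently drawn
    appointment age; elites dying before it never enter the roster.
    ``date_noise_rate`` perturbs recorded birth/death years by ±1 to
    exercise fuzzy matching.
    """
    kind = appointment_age_distribution[0]
    if kind == "fixed":
        lo = hi = float(appointment_age_distribution[1])
    elif kind == "uniform":
        lo, hi = map(float, appointment_age_distribution[1:3])
    else:
        raise ValueError(f"unknown appointment age distribution: {kind!r}")

    elites = population.loc[population["elite"]].copy()
    if len(elites) == 0:
        raise ValueError("population has no elite members")
    rng = np.random.default_rng(seed)

    # Appointment ages are drawn independently of lifespan; an elite who
    # dies before the drawn appointment never enters the scholar
    # population.  Keeping the draw independent of death is what makes
    # left-truncated estimation on the roster valid: conditioning the
    # draw on the death age (redraw-until-feasible) would concentrate
    # deaths just after entry and bias the truncated hazard upward.
    ages = (elites["death"] - elites["birth"]).to_numpy(float)
    n_all = len(elites)
    entry = rng.uniform(lo, hi, size=n_all) if kind == "uniform" else np.full(n_all, lo)
    feasible = entry < ages
    if not feasible.any():
        raise RuntimeError("no elite survives to any drawn appointment age")
    elites = elites.loc[feasible]
    entry = entry[feasible]
    n = len(elites)

    births = elites["birth"].to_numpy(float)
    deaths = elites["death"].to_numpy(float)
    b_year = np.floor(births).astype(int)
    d_year = np.floor(deaths).astype(int)
    if date_noise_rate > 0:
        for arr in (b_year, d_year):
            noisy = rng.uniform(size=n) < date_noise_rate
            arr[noisy] += rng.choice([-1, 1], size=int(noisy.sum()))
    b_month = (np.minimum((births - np.floor(births)) * 12, 11) + 1).astype(int)
    d_month = (np.minimum((deaths - np.floor(deaths)) * 12, 11) + 1).astype(int)

    roster = pd.DataFrame(
        {
            "roster_id": [f"S{i:05d}" for i in range(n)],
            "birth_year": b_year,
            "birth_month": b_month,
            "death_year": d_year,
            "death_month": d_month,
            "birth_place": elites["birth_place"].to_numpy(),
            "death_place": elites["death_place"].to_numpy(),
            "appointment_year": (np.floor(births + entry)).astype(int),
            "entry_age": entry,
        }
    )
    if truth is not None:
        truth.scholar_ids = set(elites["person_id"])
        truth.roster_to_person = dict(
            zip(roster["roster_id"], elites["person_id"])
        )
    return roster


def generate_population_size_series(
    records: pd.DataFrame, sample_years: list[float] | np.ndarray
) -> pd.DataFrame:
    """Exact head counts of persons alive at each sampled year.

    Sparse on purpose, to force interpolation downstream — this emulates
    scattered historical population-size point estimates.
    """
    b = records["birth"].to_numpy(float)
    d = records["death"].to_numpy(float)
    rows = []
    for y in sample_years:
        rows.append({"year": float(y), "count": int(((b <= y) & (y < d)).sum())})
    return pd.DataFrame(rows)
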