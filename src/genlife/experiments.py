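"""Reusable simulation experiments over the full estimation pipeline.

These encapsulate the package's own validation studies: calibration of
the binomial Monte Carlo intervals, left-truncation behaviour of the
scholar estimators, coverage/oversampling recovery, and the qualitative
reproduction of the ascertainment-bias phenomenon (a genealogy sample
whose mortality migrates from the elite's toward the general
population's as coverage improves).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import lexis, lifetable, represent, synth, uncertainty

AGE_EDGES = np.append(np.arange(30.0, 81.0, 5.0), 100.0)
_WIDE_PERIOD = np.array([0.0, 4000.0])


def cohort_e30(records: pd.DataFrame, use_entry_age: bool = False) -> float:
    """e30 of a cohort of records via Lexis tabulation + abridged table."""
    grid = lexis.tabulate(records, AGE_EDGES, _WIDE_PERIOD, use_entry_age=use_entry_age)
    return lifetable.remaining_e(lifetable.grid_to_lifetable(grid))


def scholar_records(
    population: pd.DataFrame, roster: pd.DataFrame, truth: synth.SimulationTruth
) -> pd.DataFrame:
    """Scholar record collection with entry ages attached from the roster."""
    p2r = {v: k for k, v in truth.roster_to_person.items()}
    scholars = population.loc[population["person_id"].isin(truth.scholar_ids)].copy()
    entry = roster.set_index("roster_id")["entry_age"]
    scholars["entry_age"] = [entry[p2r[p]] for p in scholars["person_id"]]
    return scholars


def ci_coverage_experiment(
    mortality: synth.MortalityModel,
    n_datasets: int = 500,
    n_individuals: int = 2000,
    n_sims: int = 200,
    seed: int = 0,
) -> float:
    """Fraction of 95% binomial Monte Carlo intervals covering the true e30.

    Each dataset is an independent cohort of `n_individuals` lifespans;
    the truth is the analytic remaining life expectancy under the
    generating regime.
    """
    truth = synth.analytic_remaining_e30(mortality)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_datasets):
        pop, _ = synth.generate_population(
            n_individuals, mortality, birth_year_range=(1700.0, 1710.0),
            seed=int(rng.integers(2**31)),
        )
        grid = lexis.tabulate(pop, AGE_EDGES, _WIDE_PERIOD)
        eci, _ = uncertainty.resample_lifetables(
            grid, n_sims=n_sims, seed=int(rng.integers(2**31))
        )
        hits += eci.lower95 <= truth <= eci.upper95
    return hits / n_datasets


def truncation_experiment(
    seed: int = 0,
    n: int = 60_000,
    elite_hazard_ratio: float = 0.6,
) -> dict:
    """wLT vs woLT scholar e30 against the analytic elite truth.

    Returns the truth, both estimates, and their errors.  The woLT
    variant counts pre-appointment person-years without the deaths that
    the appointment filter removed, so it understates early-adult
    mortality and overstates e30.
    """
    mortality = synth.MortalityModel(
        makeham_c=0.002, gompertz_a=1e-4, gompertz_b=0.09,
        elite_hazard_ratio=elite_hazard_ratio,
    )
    pop, truth = synth.generate_population(
        n, mortality, birth_year_range=(1700.0, 1750.0), elite_fraction=0.5, seed=seed
    )
    roster = synth.generate_scholar_roster(
        pop, ("uniform", 30.0, 45.0), seed=seed + 1, truth=truth
    )
    scholars = scholar_records(pop, roster, truth)
    true_e30 = synth.analytic_remaining_e30(mortality, elite=True)
    e_wlt = cohort_e30(scholars, use_entry_age=True)
    e_wolt = cohort_e30(scholars, use_entry_age=False)
    return {
        "true_elite_e30": true_e30,
        "e30_wLT": e_wlt,
        "e30_woLT": e_wolt,
        "wLT_error": e_wlt - true_e30,
        "woLT_bias": e_wolt - true_e30,
        "n_scholars": len(scholars),
    }


@dataclass
class BiasWorldResult:
    """One replicate of the two-stratum ascertainment-bias world."""

    coverage: np.ndarray  # per period
    oversampling: np.ndarray
    e30_sample: np.ndarray
    e30_elite: float
    e30_general: float
    corr_coverage: float
    corr_oversampling: float


def bias_phenomenon_replicate(
    seed: int,
    n_per_period: int = 10_000,
    n_periods: int = 6,
    elite_fraction: float = 0.1,
    elite_hazard_ratio: float = 0.55,
    elite_multiplier: float = 5.0,
    inclusion_by_period: np.ndarray | None = None,
) -> BiasWorldResult:
    """Simulate rising-coverage periods and measure the resemblance drift.

    Each period is an independent birth cohort sampled with a period-
    specific base inclusion probability (default rising 0.05 to 0.65)
    and a constant elite inclusion multiplier.  As coverage rises the
    elite share of the sample falls (the multiplier saturates at
    probability 1), so the sample's e30 migrates from the elite value
    toward the general value: coverage correlates negatively, and
    oversampling positively, with resemblance to the elite.
    """
    if inclusion_by_period is None:
        inclusion_by_period = np.linspace(0.05, 0.65, n_periods)
    mortality = synth.MortalityModel(
        makeham_c=0.002, gompertz_a=1e-4, gompertz_b=0.09,
        elite_hazard_ratio=elite_hazard_ratio,
    )
    rng = np.random.default_rng(seed)
    cov = np.empty(n_periods)
    overs = np.empty(n_periods)
    e30s = np.empty(n_periods)
    elite_frames = []
    for t, base in enumerate(inclusion_by_period):
        pop, _ = synth.generate_population(
            n_per_period, mortality,
            birth_year_range=(1700.0 + 10 * t, 1710.0 + 10 * t),
            elite_fraction=elite_fraction, seed=int(rng.integers(2**31)),
        )
        model = synth.AscertainmentModel(
            base_inclusion=float(base), elite_inclusion_multiplier=elite_multiplier
        )
        sample = synth.sample_genealogy(pop, model, seed=int(rng.integers(2**31)))
        cov[t] = len(sample) / len(pop)
        share_samp = sample["elite"].mean()
        share_pop = pop["elite"].mean()
        overs[t] = share_samp / share_pop
        e30s[t] = cohort_e30(sample)
        elite_frames.append(pop.loc[pop["elite"]])
    e30_elite = cohort_e30(pd.concat(elite_frames, ignore_index=True))
    corr_cov = represent.resemblance_correlation(e30s, np.full(n_periods, e30_elite), cov)
    corr_over = represent.resemblance_correlation(
        e30s, np.full(n_periods, e30_elite), overs
    )
    return BiasWorldResult(
        coverage=cov,
        oversampling=overs,
        e30_sample=e30s,
        e30_elite=e30_elite,
        e30_general=synth.analytic_remaining_e30(mortality),
        corr_coverage=corr_cov,
        corr_oversampling=corr_over,
    )


def representativeness_recovery(
    seed: int = 0,
    n: int = 100_000,
    base_inclusion: float = 0.10,
    elite_multiplier: float = 5.0,
    elite_fraction: float = 0.01,
) -> dict:
    """Estimate coverage and oversampling against their design values.

    The designed coverage is the population-average inclusion
    probability; the designed oversampling is the ratio of the elite
    share in the sample to the elite share in the population implied by
    the design.  Standard errors come from the binomial counts.
    """
    mortality = synth.MortalityModel(makeham_c=0.002, gompertz_a=1e-4, gompertz_b=0.09)
    pop, truth = synth.generate_population(
        n, mortality, birth_year_range=(1700.0, 1800.0),
        elite_fraction=elite_fraction, seed=seed,
    )
    model = synth.AscertainmentModel(
        base_inclusion=base_inclusion, elite_inclusion_multiplier=elite_multiplier
    )
    sample = synth.sample_genealogy(pop, model, seed=seed + 1, truth=truth)

    p_elite = min(base_inclusion * elite_multiplier, 1.0)
    p_bar = (1 - elite_fraction) * base_inclusion + elite_fraction * p_elite
    design_coverage = p_bar
    design_oversampling = p_elite / p_bar

    est_coverage = len(sample) / len(pop)
    se_coverage = np.sqrt(p_bar * (1 - p_bar) / n)

    share_samp = sample["elite"].mean()
    share_pop = pop["elite"].mean()
    est_oversampling = share_samp / share_pop
    exp_share = elite_fraction * p_elite / p_bar
    se_share = np.sqrt(exp_share * (1 - exp_share) / len(sample))
    se_oversampling = est_oversampling * np.sqrt(
        (se_share / max(share_samp, 1e-12)) ** 2
        + (1 - elite_fraction) / (n * elite_fraction)
    )
    return {
        "design_coverage": design_coverage,
        "est_coverage": est_coverage,
        "se_coverage": float(se_coverage),
        "design_oversampling": design_oversampling,
        "est_oversampling": float(est_oversampling),
        "se_oversampling": float(se_oversampling),
    }
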