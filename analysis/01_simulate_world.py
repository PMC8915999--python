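"""Generate the synthetic genealogy world used by the downstream analyses.

Creates, under results/data/: a biased genealogy sample (records.csv) of a
120k-person male population with a 2% elite stratum, the elite scholar
roster (roster.csv), and sparse historical population-size anchors
(population.csv).  The ascertainment model includes a rising inclusion
probability, five-fold elite oversampling, duplicates, age-inflation
errors and year-only dates — the failure modes of crowdsourced
genealogies.
"""

from pathlib import Path

import numpy as np

from genlife import synth
from genlife.records import write_records

OUT = Path("results/data")
SEED = 2022


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    mortality = synth.MortalityModel(
        makeham_c=0.003, gompertz_a=1e-4, gompertz_b=0.09,
        period_trend=0.999, elite_hazard_ratio=0.6,
    )
    pop, truth = synth.generate_population(
        120_000, mortality, birth_year_range=(1600.0, 1860.0),
        elite_fraction=0.02, seed=SEED,
    )
    model = synth.AscertainmentModel(
        base_inclusion=0.12, inclusion_time_slope=0.0008,
        elite_inclusion_multiplier=5.0, duplicate_rate=0.02,
        age_error_rate=0.005, missing_exact_date_rate=0.1,
    )
    sample = synth.sample_genealogy(pop, model, seed=SEED + 1, truth=truth)
    roster = synth.generate_scholar_roster(pop, seed=SEED + 2, truth=truth)
    pop_sizes = synth.generate_population_size_series(
        pop, np.arange(1600.0, 2001.0, 50.0)
    )
    pop_sizes = pop_sizes[pop_sizes["count"] > 0]

    write_records(sample, OUT / "records.csv")
    roster.to_csv(OUT / "roster.csv", index=False)
    pop_sizes.to_csv(OUT / "population.csv", index=False)
    write_records(pop, OUT / "population_records.csv")

    print(f"population: {len(pop)} persons, {int(pop['elite'].sum())} elites")
    print(f"sample:     {len(sample)} records "
          f"({len(sample) / len(pop):.1%} of the population)")
    print(f"roster:     {len(roster)} scholars")
    print(f"wrote records/roster/population tables to {OUT}/")


if __name__ == "__main__":
    main()
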