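import numpy as np
import pytest

from genlife import synth

AGE_EDGES = np.append(np.arange(30.0, 81.0, 5.0), 100.0)


@pytest.fixture(scope="session")
def gompertz_model():
    """Stationary adult mortality regime used across the suite."""
    return synth.MortalityModel(makeham_c=0.0, gompertz_a=1e-4, gompertz_b=0.09)


@pytest.fixture(scope="session")
def gompertz_population(gompertz_model):
    """50k-person cohort under the Gompertz regime (exact dates)."""
    pop, truth = synth.generate_population(
        50_000, gompertz_model, birth_year_range=(1700.0, 1800.0), seed=101
    )
    return pop, truth


@pytest.fixture(scope="session")
def elite_world():
    """Population with an elite stratum plus its scholar roster."""
    mortality = synth.MortalityModel(
        makeham_c=0.002, gompertz_a=1e-4, gompertz_b=0.09, elite_hazard_ratio=0.6
    )
    pop, truth = synth.generate_population(
        60_000, mortality, birth_year_range=(1700.0, 1750.0),
        elite_fraction=0.5, seed=21,
    )
    roster = synth.generate_scholar_roster(
        pop, ("uniform", 30.0, 45.0), seed=22, truth=truth
    )
    return mortality, pop, roster, truth
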