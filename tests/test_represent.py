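"""Coverage, oversampling, record linkage and the resemblance correlations."""

import numpy as np
import pandas as pd
import pytest

from genlife import represent, synth
from genlife.experiments import representativeness_recovery, scholar_records


class TestInterpolation:
    def test_anchor_years_exact(self):
        pts = pd.DataFrame({"year": [1700, 1800, 1900], "count": [1000, 4000, 9000]})
        out = represent.interpolate_population(pts, [1700, 1800, 1900])
        assert np.allclose(out.to_numpy(), [1000, 4000, 9000])

    def test_geometric_midpoint(self):
        pts = pd.DataFrame({"year": [1700, 1800], "count": [1000, 4000]})
        out = represent.interpolate_population(pts, [1750])
        assert out.iloc[0] == pytest.approx(2000.0)

    def test_matches_per_segment_exponential_formula(self):
        pts = pd.DataFrame({"year": [1700, 1760, 1820], "count": [500, 2000, 3000]})
        years = np.arange(1700, 1821)
        out = represent.interpolate_population(pts, years)
        for y, v in zip(years, out):
            if y <= 1760:
                expected = 500 * (2000 / 500) ** ((y - 1700) / 60)
            else:
                expected = 2000 * (3000 / 2000) ** ((y - 1760) / 60)
            assert v == pytest.approx(expected)

    def test_extrapolation_refused(self):
        pts = pd.DataFrame({"year": [1700, 1800], "count": [1000, 4000]})
        with pytest.raises(ValueError, match="outside"):
            represent.interpolate_population(pts, [1650])


class TestCoverage:
    def test_full_inclusion_coverage_one(self, gompertz_population):
        pop, _ = gompertz_population
        sub = pop.head(5000)
        years = np.arange(1740.0, 1781.0)
        counts = synth.generate_population_size_series(sub, years)
        series = pd.Series(
            counts["count"].to_numpy(float), index=years
        )
        series = series[series > 0]
        cov = represent.coverage_series(sub, series)
        assert np.allclose(cov["coverage"], 1.0)

    def test_alive_counts_match_brute_force(self, gompertz_population):
        pop, _ = gompertz_population
        sub = pop.head(3000)
        years = [1720.0, 1750.0, 1800.0]
        got = represent.alive_counts(sub, years)
        b, d = sub["birth"].to_numpy(), sub["death"].to_numpy()
        for y, g in zip(years, got):
            assert g == ((b <= y) & (y < d)).sum()

    def test_partial_inclusion_near_design(self):
        out = representativeness_recovery(seed=61, n=100_000)
        assert abs(out["est_coverage"] - out["design_coverage"]) < 3 * out["se_coverage"]

    def test_zero_population_rejected(self, gompertz_population):
        pop, _ = gompertz_population
        series = pd.Series([0.0], index=[1750.0])
        with pytest.raises(ValueError, match="positive"):
            represent.coverage_series(pop.head(100), series)


class TestMatching:
    def test_exact_twin_matched_and_absent_unmatched(self, elite_world):
        _, pop, roster, truth = elite_world
        some = roster.head(50).copy()
        ids = [truth.roster_to_person[r] for r in some["roster_id"]]
        recs = pop.loc[pop["person_id"].isin(ids[:40])]  # 10 roster rows absent
        matches, unmatched = represent.match_scholars(recs, some, year_tolerance=0)
        matched_ids = {m.roster_id for m in matches}
        for rid in some["roster_id"].head(40):
            assert rid in matched_ids
        assert len(unmatched) == 10

    def test_precision_recall_with_date_noise(self, elite_world):
        _, pop, _, truth = elite_world
        roster_n = synth.generate_scholar_roster(
            pop, ("uniform", 30.0, 45.0), seed=22, truth=truth, date_noise_rate=0.01
        )
        rng = np.random.default_rng(3)
        keep = set(rng.choice(pop["person_id"], size=6000, replace=False))
        ros = roster_n.loc[
            roster_n["roster_id"].map(lambda r: truth.roster_to_person[r] in keep)
        ].head(1000)
        keep |= {truth.roster_to_person[r] for r in ros["roster_id"]}
        recs = pop.loc[pop["person_id"].isin(keep)]
        matches, _ = represent.match_scholars(recs, ros, year_tolerance=1)
        tp = sum(
            1 for m in matches if truth.roster_to_person[m.roster_id] == m.genealogy_id
        )
        assert tp / len(matches) >= 0.95  # precision
        assert tp / len(ros) >= 0.95  # recall

    def test_one_to_one_resolution(self, elite_world):
        _, pop, roster, truth = elite_world
        recs = pop.loc[pop["elite"]].head(2000)
        matches, _ = represent.match_scholars(recs, roster.head(500))
        assert len({m.roster_id for m in matches}) == len(matches)
        assert len({m.genealogy_id for m in matches}) == len(matches)


class TestOversampling:
    def test_equal_shares_ratio_one(self, gompertz_population):
        pop, _ = gompertz_population
        sub = pop.head(10_000).copy()
        rng = np.random.default_rng(9)
        scholars = set(rng.choice(sub["person_id"], size=500, replace=False))
        # anchors at the period midpoints so interpolation is exact there
        years = np.arange(1700.0, 1901.0, 10.0)
        counts = synth.generate_population_size_series(sub, years)
        popser = pd.Series(counts["count"].to_numpy(float), index=years)
        popser = popser[popser > 0]
        periods = [(1740.0, 1760.0), (1760.0, 1780.0)]
        sch_counts = {
            p: represent.alive_counts(
                sub.loc[sub["person_id"].isin(scholars)], [0.5 * (p[0] + p[1])]
            )[0]
            for p in periods
        }
        out = represent.oversampling_series(sub, scholars, sch_counts, popser, periods)
        # sample IS the population here, so shares cancel exactly
        assert np.allclose(out["oversampling"], 1.0, atol=1e-9)

    def test_designed_multiplier_recovered(self):
        out = representativeness_recovery(seed=71, n=100_000)
        assert (
            abs(out["est_oversampling"] - out["design_oversampling"])
            < 3 * out["se_oversampling"]
        )

    def test_uniform_sampling_oversampling_one(self):
        out = representativeness_recovery(
            seed=81, n=100_000, elite_multiplier=1.0, elite_fraction=0.05
        )
        assert out["design_oversampling"] == 1.0
        assert abs(out["est_oversampling"] - 1.0) < 3 * out["se_oversampling"]

    def test_zero_denominator_flagged(self, gompertz_population):
        pop, _ = gompertz_population
        sub = pop.head(1000)
        years = np.arange(1700.0, 1901.0, 50.0)
        counts = synth.generate_population_size_series(sub, years)
        popser = pd.Series(
            np.maximum(counts["count"].to_numpy(float), 1.0), index=years
        )
        out = represent.oversampling_series(
            sub, set(), {(1750.0, 1760.0): 0.0}, popser, [(1750.0, 1760.0)]
        )
        assert out["undefined"].iloc[0]


class TestResemblance:
    def test_exact_antimonotone(self):
        # resemblance falls (-1, -2, -3) as the driver rises (1, 2, 3)
        c = represent.resemblance_correlation(
            np.array([12.0, 11, 10]), np.array([13.0, 13, 13]), np.array([1.0, 2, 3])
        )
        assert c == pytest.approx(-1.0)

    def test_driver_equal_resemblance(self):
        e30s = np.array([10.0, 11, 12])
        elite = np.array([13.0, 13, 13])
        driver = -np.abs(e30s - elite)
        assert represent.resemblance_correlation(e30s, elite, driver) == pytest.approx(1.0)

    def test_zero_variance_flagged(self):
        with pytest.raises(ValueError, match="variance"):
            represent.resemblance_correlation(
                np.array([10.0, 10, 10]), np.array([10.0, 10, 10]),
                np.array([1.0, 2, 3]),
            )

    def test_too_few_periods(self):
        with pytest.raises(ValueError, match="3"):
            represent.resemblance_correlation(
                np.array([1.0, 2]), np.array([1.0, 2]), np.array([1.0, 2])
            )
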