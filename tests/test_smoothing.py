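"""B-spline basis construction and penalized Poisson surface fitting."""

import numpy as np
import pytest

from genlife import smoothing
from genlife.lexis import LexisGrid


def _cox_de_boor(x, t, i, k):
    """Textbook recursive B-spline evaluation (independent oracle)."""
    if k == 0:
        return 1.0 if t[i] <= x < t[i + 1] else 0.0
    left = 0.0
    if t[i + k] > t[i]:
        left = (x - t[i]) / (t[i + k] - t[i]) * _cox_de_boor(x, t, i, k - 1)
    right = 0.0
    if t[i + k + 1] > t[i + 1]:
        right = (t[i + k + 1] - x) / (t[i + k + 1] - t[i + 1]) * _cox_de_boor(
            x, t, i + 1, k - 1
        )
    return left + right


def _make_grid(D, E, age_edges=None, period_edges=None):
    if age_edges is None:
        age_edges = np.append(np.arange(30.0, 81.0, 5.0), 100.0)
    if period_edges is None:
        period_edges = np.arange(1700.0, 1901.0, 10.0)
    return LexisGrid(age_edges, period_edges, D, E, np.zeros_like(E))


@pytest.fixture(scope="module")
def gompertz_surface_grid():
    """Poisson death counts from a drifting Gompertz surface, ~50k deaths."""
    rng = np.random.default_rng(5)
    age_edges = np.append(np.arange(30.0, 81.0, 5.0), 100.0)
    period_edges = np.arange(1700.0, 1901.0, 10.0)
    ages = 0.5 * (age_edges[:-1] + age_edges[1:])
    periods = 0.5 * (period_edges[:-1] + period_edges[1:])
    A, P = np.meshgrid(ages, periods, indexing="ij")
    true_lograte = np.log(1e-4) + 0.09 * A + 0.002 * (P - 1800.0)
    E = np.full(A.shape, 4000.0)
    D = rng.poisson(E * np.exp(true_lograte))
    return _make_grid(D, E, age_edges, period_edges), true_lograte


class TestBasis:
    def test_partition_of_unity(self):
        grid = np.linspace(30, 100, 40)
        B = smoothing.bspline_basis(grid, spacing=5.0, degree=3)
        assert np.allclose(B.sum(axis=1), 1.0, atol=1e-10)

    def test_degree_zero_indicator_basis(self):
        grid = np.arange(0.0, 10.0, 1.0)
        B = smoothing.bspline_basis(grid, spacing=1.0, degree=0)
        assert B.shape == (10, 10)
        assert np.allclose(B, np.eye(10))

    def test_matches_cox_de_boor_recursion(self):
        grid = np.linspace(32.5, 97.5, 14)
        spacing, degree = 5.0, 3
        B = smoothing.bspline_basis(grid, spacing, degree)
        lo = grid[0]
        nseg = int(np.floor((grid[-1] - lo) / spacing)) + 1
        inner = lo + spacing * np.arange(nseg + 1)
        knots = np.concatenate(
            [lo - spacing * np.arange(degree, 0, -1), inner,
             inner[-1] + spacing * np.arange(1, degree + 1)]
        )
        oracle = np.array(
            [[_cox_de_boor(x, knots, i, degree) for i in range(B.shape[1])]
             for x in grid]
        )
        assert np.allclose(B, oracle, atol=1e-12)

    def test_too_few_basis_functions_raises(self):
        with pytest.raises(ValueError):
            smoothing.difference_penalty(2, 2)


class TestFit:
    @pytest.mark.parametrize("lam", [0.1, 10.0, 1000.0])
    def test_constant_rate_recovered_within_two_percent(self, lam):
        # exposures large enough that even the max per-cell Poisson
        # deviation over all 220 cells stays well under 2%
        rng = np.random.default_rng(2)
        E = np.full((11, 20), 1e8)
        D = rng.poisson(E * 0.02)
        grid = _make_grid(D, E)
        fit = smoothing.fit_psplines_2d(
            grid, smoothing.PsplineSpec(lambda_age=lam, lambda_period=lam)
        )
        assert fit.converged
        rates = np.exp(fit.log_rate)
        assert np.all(np.abs(rates / 0.02 - 1.0) < 0.02)

    def test_infinite_lambda_limit_is_penalty_null_space(self, gompertz_surface_grid):
        # order-2 difference penalties leave surfaces affine in each
        # dimension (span 1, age, period, age*period) unpenalized
        grid, _ = gompertz_surface_grid
        fit = smoothing.fit_psplines_2d(
            grid, smoothing.PsplineSpec(lambda_age=1e10, lambda_period=1e10)
        )
        A, P = np.meshgrid(fit.age_grid, fit.period_grid, indexing="ij")
        X = np.column_stack(
            [np.ones(A.size), A.ravel(), P.ravel(), (A * P).ravel()]
        )
        coef, *_ = np.linalg.lstsq(X, fit.log_rate.ravel(), rcond=None)
        assert np.abs(X @ coef - fit.log_rate.ravel()).max() < 1e-4

    def test_gompertz_surface_rmse(self, gompertz_surface_grid):
        grid, true_lograte = gompertz_surface_grid
        spec = smoothing.select_lambdas(
            grid, smoothing.PsplineSpec(), [0.1, 1.0, 10.0, 100.0, 1000.0]
        )
        fit = smoothing.fit_psplines_2d(grid, spec)
        well = grid.exposures > 100
        rmse = np.sqrt(np.mean((fit.log_rate[well] - true_lograte[well]) ** 2))
        assert rmse < 0.05

    def test_saturated_limit_reproduces_raw_rates(self):
        # identity basis + no penalty: Poisson ML gives deaths/exposure
        rng = np.random.default_rng(4)
        age_edges = np.arange(30.0, 61.0, 5.0)
        period_edges = np.arange(1700.0, 1761.0, 10.0)
        E = rng.uniform(500, 2000, size=(6, 6))
        D = rng.poisson(E * 0.03)
        grid = _make_grid(D, E, age_edges, period_edges)
        spec = smoothing.PsplineSpec(
            spline_degree=0, knot_spacing_age=5.0, knot_spacing_period=10.0,
            penalty_order=1, lambda_age=0.0, lambda_period=0.0,
        )
        fit = smoothing.fit_psplines_2d(grid, spec)
        pos = D > 0
        assert np.allclose(np.exp(fit.log_rate)[pos], (D / E)[pos], rtol=1e-4)

    def test_effective_dimension_monotone_in_lambda(self, gompertz_surface_grid):
        grid, _ = gompertz_surface_grid
        eds = []
        for lam in [0.1, 10.0, 1000.0]:
            fit = smoothing.fit_psplines_2d(
                grid, smoothing.PsplineSpec(lambda_age=lam, lambda_period=1.0)
            )
            eds.append(fit.effective_dimension)
        assert eds[0] > eds[1] > eds[2]

    def test_zero_exposure_cells_are_interpolated(self):
        rng = np.random.default_rng(6)
        E = np.full((11, 20), 1000.0)
        E[5, 7] = 0.0
        D = rng.poisson(E * 0.02)
        grid = _make_grid(D, E)
        fit = smoothing.fit_psplines_2d(grid, smoothing.PsplineSpec())
        assert np.isfinite(fit.log_rate[5, 7])
        assert abs(np.exp(fit.log_rate[5, 7]) - 0.02) < 0.005


class TestSelection:
    def test_single_candidate_returned(self, gompertz_surface_grid):
        grid, _ = gompertz_surface_grid
        spec = smoothing.select_lambdas(grid, smoothing.PsplineSpec(), [7.0])
        assert spec.lambda_age == 7.0 and spec.lambda_period == 7.0

    def test_selected_bic_is_minimal(self, gompertz_surface_grid):
        grid, _ = gompertz_surface_grid
        lams = [1.0, 100.0]
        best = smoothing.select_lambdas(grid, smoothing.PsplineSpec(), lams)
        best_bic = smoothing.fit_psplines_2d(grid, best).bic
        for la in lams:
            for lp in lams:
                fit = smoothing.fit_psplines_2d(
                    grid, smoothing.PsplineSpec(lambda_age=la, lambda_period=lp)
                )
                assert best_bic <= fit.bic + 1e-6

    def test_planar_truth_selects_maximal_smoothing(self):
        # noiseless planar surface: BIC prefers the stiffest candidate
        age_edges = np.append(np.arange(30.0, 81.0, 5.0), 100.0)
        period_edges = np.arange(1700.0, 1901.0, 10.0)
        ages = 0.5 * (age_edges[:-1] + age_edges[1:])
        periods = 0.5 * (period_edges[:-1] + period_edges[1:])
        A, P = np.meshgrid(ages, periods, indexing="ij")
        E = np.full(A.shape, 10_000.0)
        D = np.rint(E * np.exp(np.log(2e-4) + 0.08 * A)).astype(int)
        grid = _make_grid(D, E, age_edges, period_edges)
        best = smoothing.select_lambdas(
            grid, smoothing.PsplineSpec(), [1.0, 100.0, 10_000.0]
        )
        assert best.lambda_age == 10_000.0 and best.lambda_period == 10_000.0


class TestAggregation:
    def test_constant_surface_aggregates_to_constant(self):
        edges = np.append(np.arange(30.0, 81.0, 5.0), 100.0)
        pedges = np.arange(1700.0, 1901.0, 10.0)
        E = np.full((11, 20), 1000.0)
        surf = smoothing.HazardSurface(
            age_grid=0.5 * (edges[:-1] + edges[1:]),
            period_grid=0.5 * (pedges[:-1] + pedges[1:]),
            log_rate=np.full((11, 20), np.log(0.02)),
            effective_dimension=1.0, converged=True, bic=0.0, deviance=0.0,
            exposures=E,
        )
        mx = smoothing.surface_to_mx(surf, edges, (1700.0, 1800.0))
        assert np.allclose(mx, 0.02)

    def test_zero_weight_group_raises(self):
        edges = np.append(np.arange(30.0, 81.0, 5.0), 100.0)
        mids = 0.5 * (edges[:-1] + edges[1:])
        pmids = 0.5 * (np.arange(1700.0, 1901.0, 10.0)[:-1]
                       + np.arange(1700.0, 1901.0, 10.0)[1:])
        E = np.full((11, 20), 1000.0)
        E[0, :] = 0.0
        surf = smoothing.HazardSurface(
            age_grid=mids, period_grid=pmids, log_rate=np.zeros((11, 20)),
            effective_dimension=1.0, converged=True, bic=0.0, deviance=0.0,
            exposures=E,
        )
        with pytest.raises(ValueError, match="zero exposure"):
            smoothing.surface_to_mx(surf, edges, (1700.0, 1800.0))

    def test_matches_brute_force_weighted_mean(self, gompertz_surface_grid):
        grid, _ = gompertz_surface_grid
        fit = smoothing.fit_psplines_2d(grid, smoothing.PsplineSpec())
        edges = grid.age_edges
        mx = smoothing.surface_to_mx(fit, edges, (1750.0, 1800.0))
        pj = (fit.period_grid >= 1750.0) & (fit.period_grid < 1800.0)
        for i in range(len(edges) - 1):
            ai = (fit.age_grid >= edges[i]) & (fit.age_grid < edges[i + 1])
            r = np.exp(fit.log_rate[np.ix_(ai, pj)])
            w = fit.exposures[np.ix_(ai, pj)]
            assert mx[i] == pytest.approx((r * w).sum() / w.sum())
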