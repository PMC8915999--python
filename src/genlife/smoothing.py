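"""Two-dimensional P-spline smoothing of mortality surfaces.

Death counts on a Lexis grid are modelled as

    D_ij ~ Poisson(E_ij * exp(eta_ij)),   eta = B_age Theta B_period'

with equally spaced cubic B-spline bases in age and calendar time and a
difference penalty of order 2 on the coefficients in each dimension
(penalized likelihood lambda_age * ||D_a Theta||^2 + lambda_period *
||Theta D_p'||^2).  The fit is by penalized iteratively reweighted least
squares with step-halving, so the penalized log-likelihood never
decreases.  Smoothing weights are selected by BIC on a grid, ties broken
toward the smoother fit.

Cells with zero exposure carry zero weight: their fitted values are pure
penalty interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import product

import numpy as np
from scipy.interpolate import BSpline

_RIDGE = 1e-6
_MAX_ITER = 200
_TOL = 1e-6


@dataclass
class PsplineSpec:
    """P-spline basis and penalty configuration."""

    spline_degree: int = 3
    knot_spacing_age: float = 5.0
    knot_spacing_period: float = 10.0
    penalty_order: int = 2
    lambda_age: float = 10.0
    lambda_period: float = 10.0

    def __post_init__(self) -> None:
        if self.lambda_age < 0 or self.lambda_period < 0:
            raise ValueError("smoothing weights must be >= 0")
        if self.penalty_order < 1:
            raise ValueError("penalty_order must be >= 1")


@dataclass
class HazardSurface:
    """Smoothed log death-rate over the grid's age x period midpoints."""

    age_grid: np.ndarray
    period_grid: np.ndarray
    log_rate: np.ndarray  # (n_age, n_period)
    effective_dimension: float
    converged: bool
    bic: float
    deviance: float
    exposures: np.ndarray  # carried along for exposure-weighted aggregation

    def to_frame(self):
        import pandas as pd

        rows = []
        for i, a in enumerate(self.age_grid):
            for j, p in enumerate(self.period_grid):
                rows.append({"age": a, "period": p, "log_rate": self.log_rate[i, j]})
        return pd.DataFrame(rows)


def bspline_basis(grid, spacing: float, degree: int = 3) -> np.ndarray:
    """Equally spaced B-spline basis evaluated at the grid points.

    Knots are laid every `spacing` units from the first grid point, with
    `degree` boundary-extension knots on each side, so the basis is a
    partition of unity on the whole grid (each row sums to 1).
    """
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    lo, hi = grid[0], grid[-1]
    # last inner knot strictly beyond the grid so every point lies in a
    # half-open knot span and the partition of unity covers the whole grid
    nseg = int(np.floor((hi - lo) / spacing)) + 1
    inner = lo + spacing * np.arange(nseg + 1)
    knots = np.concatenate(
        [lo - spacing * np.arange(degree, 0, -1), inner,
         inner[-1] + spacing * np.arange(1, degree + 1)]
    )
    B = BSpline.design_matrix(grid, knots, degree).toarray()
    return B


def difference_penalty(n_basis: int, order: int) -> np.ndarray:
    """D'D for the order-th difference matrix on n_basis coefficients."""
    if n_basis <= order:
        raise ValueError("need more basis functions than the penalty order")
    D = np.diff(np.eye(n_basis), n=order, axis=0)
    return D.T @ D


def _poisson_devloglik(y, mu, w):
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(y / mu) - (y - mu), mu - y)
    return 2.0 * float(np.sum(w * term))


def fit_psplines_2d(grid, spec: PsplineSpec) -> HazardSurface:
    """Fit the penalized Poisson death-rate surface to a Lexis grid.

    Returns the smoothed log rate at the grid cell midpoints, the
    effective dimension (trace of the hat matrix), a convergence flag and
    BIC = deviance + log(#positive-exposure cells) * effective dimension.
    """
    ages = grid.age_mid()
    periods = grid.period_mid()
    y = grid.deaths.astype(float)
    E = grid.exposures.astype(float)
    if not np.any(E > 0):
        raise ValueError("all exposures are zero")

    Ba = bspline_basis(ages, spec.knot_spacing_age, spec.spline_degree)
    Bp = bspline_basis(periods, spec.knot_spacing_period, spec.spline_degree)
    ka, kp = Ba.shape[1], Bp.shape[1]
    B = np.kron(Ba, Bp)  # row-major vec of the (age, period) matrix
    P = spec.lambda_age * np.kron(difference_penalty(ka, spec.penalty_order), np.eye(kp))
    P = P + spec.lambda_period * np.kron(
        np.eye(ka), difference_penalty(kp, spec.penalty_order)
    )
    P = P + _RIDGE * np.eye(ka * kp)

    yv = y.ravel()
    Ev = E.ravel()
    obs = Ev > 0
    log_off = np.where(obs, np.log(np.maximum(Ev, 1e-300)), 0.0)

    # initialize from the raw empirical log rate
    eta0 = np.log((yv + 0.5) / (Ev + 1.0))
    W0 = obs.astype(float)
    theta = np.linalg.solve(B.T @ (W0[:, None] * B) + P, B.T @ (W0 * eta0))

    def penloglik(th):
        eta = B @ th
        mu = np.exp(eta + log_off)
        ll = float(np.sum(np.where(obs, yv * (eta + log_off) - mu, 0.0)))
        return ll - 0.5 * float(th @ P @ th)

    converged = False
    pl_old = penloglik(theta)
    for _ in range(_MAX_ITER):
        eta = B @ theta
        mu = np.exp(eta + log_off)
        w = np.where(obs, mu, 0.0)
        z = eta + np.where(w > 0, (yv - mu) / np.maximum(mu, 1e-300), 0.0)
        BtWB = B.T @ (w[:, None] * B)
        theta_new = np.linalg.solve(BtWB + P, B.T @ (w * z))
        # step-halving: penalized log-likelihood must not decrease
        step = theta_new - theta
        t = 1.0
        for _ in range(30):
            cand = theta + t * step
            if penloglik(cand) >= pl_old - 1e-12:
                break
            t *= 0.5
        theta_new = theta + t * step
        delta = float(np.max(np.abs(theta_new - theta)))
        theta = theta_new
        pl_old = penloglik(theta)
        if delta < _TOL:
            converged = True
            break

    eta = B @ theta
    mu = np.exp(eta + log_off)
    w = np.where(obs, mu, 0.0)
    BtWB = B.T @ (w[:, None] * B)
    H = np.linalg.solve(BtWB + P, BtWB)
    ed = float(np.trace(H))
    dev = _poisson_devloglik(yv, np.maximum(mu, 1e-300), obs.astype(float))
    n_obs = int(obs.sum())
    bic = dev + np.log(max(n_obs, 1)) * ed

    return HazardSurface(
        age_grid=ages,
        period_grid=periods,
        log_rate=eta.reshape(y.shape),
        effective_dimension=ed,
        converged=converged,
        bic=bic,
        deviance=dev,
        exposures=E,
    )


def select_lambdas(grid, spec: PsplineSpec, lambda_grid) -> PsplineSpec:
    """Pick (lambda_age, lambda_period) minimizing BIC over a grid.

    `lambda_grid` is either a list of scalars (crossed with itself) or a
    list of (lambda_age, lambda_period) pairs.  Ties go to the larger
    (smoother) pair; non-converged candidates are excluded.
    """
    lambda_grid = list(lambda_grid)
    if not lambda_grid:
        raise ValueError("lambda_grid is empty")
    if np.isscalar(lambda_grid[0]):
        pairs = list(product(lambda_grid, lambda_grid))
    else:
        pairs = [tuple(p) for p in lambda_grid]

    best = None
    for la, lp in sorted(pairs):
        cand = replace(spec, lambda_age=float(la), lambda_period=float(lp))
        fit = fit_psplines_2d(grid, cand)
        if not fit.converged:
            continue
        if best is None or fit.bic <= best[0] + 1e-9:
            best = (fit.bic, cand)
    if best is None:
        raise RuntimeError("no smoothing candidate converged")
    return best[1]


def surface_to_mx(
    surface: HazardSurface, age_edges, period: tuple[float, float]
) -> np.ndarray:
    """Aggregate the smoothed surface to age-group death rates for a period.

    Exposure-weighted average of exp(log_rate) over the fine cells whose
    age midpoint falls in each group and whose period midpoint falls in
    the window.
    """
    age_edges = np.asarray(age_edges, dtype=float)
    lo, hi = period
    pj = (surface.period_grid >= lo) & (surface.period_grid < hi)
    if not pj.any():
        raise ValueError(f"surface does not cover period {period}")
    if age_edges[0] < surface.age_grid[0] - 2.5 or age_edges[-1] > surface.age_grid[-1] + 10:
        raise ValueError("requested ages outside the smoothed surface")
    rates = np.exp(surface.log_rate[:, pj])
    wts = surface.exposures[:, pj]
    out = np.empty(len(age_edges) - 1)
    for i in range(len(out)):
        ai = (surface.age_grid >= age_edges[i]) & (surface.age_grid < age_edges[i + 1])
        if not ai.any():
            raise ValueError(f"no surface cells in age group [{age_edges[i]}, {age_edges[i+1]})")
        wsum = wts[ai].sum()
        if wsum <= 0:
            raise ValueError(
                f"zero exposure weight in age group [{age_edges[i]}, {age_edges[i+1]})"
            )
        out[i] = float((rates[ai] * wts[ai]).sum() / wsum)
    return out
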