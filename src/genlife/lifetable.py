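"""Abridged period life tables, remaining life expectancy and lifespan Gini.

Tables use 5-y age groups by default with a terminal open interval (80+),
built from group central death rates m_x by the standard chain

    q_x = n m_x / (1 + (n - a_x) m_x)        (capped at 1)
    l_{x+n} = l_x (1 - q_x),   d_x = l_x q_x
    L_x = n l_{x+n} + a_x d_x,  terminal L = l / m
    T_x = sum of L from x up,   e_x = T_x / l_x

where a_x is the average time lived in the interval by those dying in it
(default n/2; pass the observed deaths-weighted mean when tabulating
individual lifelines, which makes the cohort table exact).

Lifespan inequality is the Gini coefficient of remaining lifespan,
G = E|X1 - X2| / (2 E X), computed by the exact double sum over the
discrete group-level death distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

RADIX = 100_000.0


@dataclass
class AbridgedLifeTable:
    """Abridged life table with a terminal open age group."""

    age_edges: np.ndarray  # length n_groups + 1; last edge closes the open group
    mx: np.ndarray
    qx: np.ndarray
    ax: np.ndarray
    lx: np.ndarray
    dx: np.ndarray
    Lx: np.ndarray
    Tx: np.ndarray
    ex: np.ndarray

    @property
    def ages(self) -> np.ndarray:
        return self.age_edges[:-1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "age": self.ages,
                "mx": self.mx,
                "qx": self.qx,
                "ax": self.ax,
                "lx": self.lx,
                "dx": self.dx,
                "Lx": self.Lx,
                "Tx": self.Tx,
                "ex": self.ex,
            }
        )


def _chain(
    mx: np.ndarray, widths: np.ndarray, ax: np.ndarray
) -> tuple[np.ndarray, ...]:
    """Vectorized life-table chain; mx may be (n_groups,) or (k, n_groups)."""
    mx = np.atleast_2d(np.asarray(mx, dtype=float))
    k, g = mx.shape
    n = widths[np.newaxis, :]
    a = np.broadcast_to(ax, (k, g))
    with np.errstate(divide="ignore", invalid="ignore"):
        qx = n * mx / (1.0 + (n - a) * mx)
    qx = np.clip(qx, 0.0, 1.0)
    qx[:, -1] = 1.0

    lx = np.empty((k, g))
    lx[:, 0] = RADIX
    for i in range(g - 1):
        lx[:, i + 1] = lx[:, i] * (1.0 - qx[:, i])
    dx = lx * qx
    dx[:, -1] = lx[:, -1]

    Lx = n * (lx - dx) + a * dx
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(mx[:, -1] > 0, lx[:, -1] / mx[:, -1], 0.0)
    Lx[:, -1] = term
    Tx = np.cumsum(Lx[:, ::-1], axis=1)[:, ::-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        ex = np.where(lx > 0, Tx / lx, 0.0)
    return qx, lx, dx, Lx, Tx, ex


def mx_to_lifetable(
    mx, age_edges, ax=None
) -> AbridgedLifeTable:
    """Build an abridged life table from group central death rates.

    Parameters
    ----------
    mx : array
        Central death rate per age group, terminal open group last.
    age_edges : array
        Group boundaries; the final edge closes the open group (used only
        for bookkeeping — terminal person-years come from l/m).
    ax : array or float, optional
        Average person-years lived in the interval by those dying in it.
        Default: half the interval width; the terminal a is l/m-implied
        (reported as 1/m for reference).
    """
    mx = np.asarray(mx, dtype=float)
    age_edges = np.asarray(age_edges, dtype=float)
    if len(mx) != len(age_edges) - 1:
        raise ValueError("mx length must equal number of age groups")
    if np.any(mx < 0):
        raise ValueError("negative death rate")
    widths = np.diff(age_edges)
    if ax is None:
        ax_arr = widths / 2.0
    else:
        ax_arr = np.broadcast_to(np.asarray(ax, dtype=float), mx.shape).copy()
    ax_arr = np.asarray(ax_arr, dtype=float).copy()
    ax_arr[-1] = 1.0 / mx[-1] if mx[-1] > 0 else 0.0

    qx, lx, dx, Lx, Tx, ex = _chain(mx, widths, ax_arr)
    if mx[-1] <= 0 and lx[0, -1] > 0:
        raise ValueError("terminal group death rate must be positive")
    return AbridgedLifeTable(
        age_edges, mx, qx[0], ax_arr, lx[0], dx[0], Lx[0], Tx[0], ex[0]
    )


def grid_to_lifetable(grid, period: tuple[float, float] | None = None,
                      use_observed_ax: bool = True) -> AbridgedLifeTable:
    """Life table straight from a Lexis grid (optionally one period window)."""
    g = grid if period is None else grid.period_slice(period)
    d, e, ax_obs = g.marginal_by_age()
    if np.any(e <= 0):
        bad = g.age_edges[:-1][e <= 0]
        raise ValueError(f"zero exposure in age group(s) starting at {bad}")
    mx = d / e
    return mx_to_lifetable(mx, g.age_edges, ax=ax_obs if use_observed_ax else None)


def remaining_e(lt: AbridgedLifeTable, age: float = 30.0) -> float:
    """Remaining life expectancy at an exact age: T(age) / l(age)."""
    idx = np.where(np.isclose(lt.ages, age))[0]
    if len(idx) == 0:
        raise ValueError(f"age {age} is not a group boundary of the table")
    i = int(idx[0])
    return float(lt.Tx[i] / lt.lx[i])


def _remaining_death_distribution(
    lt: AbridgedLifeTable, age: float
) -> tuple[np.ndarray, np.ndarray]:
    idx = np.where(np.isclose(lt.ages, age))[0]
    if len(idx) == 0:
        raise ValueError(f"age {age} is not a group boundary of the table")
    i = int(idx[0])
    if lt.lx[i] <= 0:
        raise ValueError(f"no survivors at age {age}")
    w = lt.dx[i:] / lt.lx[i]
    t = lt.ages[i:] + lt.ax[i:] - age  # deaths placed at group lo + a_x
    return t, w


def gini_remaining(lt: AbridgedLifeTable, age: float = 30.0) -> float:
    """Gini of remaining lifespan at `age` under the table's death distribution.

    G = E|X1 - X2| / (2 E X) with X taking value (x_i + a_i - age) with
    probability d_i / l(age); exact double sum, no interpolation.
    """
    t, w = _remaining_death_distribution(lt, age)
    if len(t) < 2:
        return 0.0
    mean = float(np.sum(w * t))
    if mean <= 0:
        return 0.0
    mad = float(w @ np.abs(t[:, None] - t[None, :]) @ w)
    return mad / (2.0 * mean)


def sample_remaining_lifespans(
    lt: AbridgedLifeTable, age: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Monte Carlo draws from the table's discrete remaining-lifespan law."""
    t, w = _remaining_death_distribution(lt, age)
    return rng.choice(t, size=n, p=w / w.sum())


def read_lifetable(path) -> AbridgedLifeTable:
    """Read a life table written by :meth:`AbridgedLifeTable.to_frame`.

    Also accepts benchmark abridged tables in the same 5-y layout (an HMD
    style export reduced to the columns above).
    """
    df = pd.read_csv(path)
    ages = df["age"].to_numpy(float)
    widths = np.diff(ages)
    last_w = widths[-1] if len(widths) else 5.0
    edges = np.append(ages, ages[-1] + last_w)
    return AbridgedLifeTable(
        edges,
        df["mx"].to_numpy(float),
        df["qx"].to_numpy(float),
        df["ax"].to_numpy(float),
        df["lx"].to_numpy(float),
        df["dx"].to_numpy(float),
        df["Lx"].to_numpy(float),
        df["Tx"].to_numpy(float),
        df["ex"].to_numpy(float),
    )
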