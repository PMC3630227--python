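"""Deterministic single-cell layer: cell-cycle integration, generation map,
equilibria, stability, and the edge of plasmid stability.

Copy number ``n`` is treated as a continuous variable here.  For a cell
whose plasmids all share one genotype ``(alpha, kappa, beta)`` the cell
cycle obeys the coupled ODEs

    dM/dt = M * g(n, n*kappa)
    dn/dt = n * alpha / (1 + beta * tau * kappa * n / M)

starting from newborn biomass ``M0`` and dividing when ``M = 2*M0``.
Equipartition at division maps the copy number at the start of a parent's
cycle to that of its daughters: ``G(n0) = n_division / 2``.  Fixed points
of ``G`` are the characteristic copy numbers; a fold bifurcation in the
basal replication rate alpha marks the edge of plasmid stability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq, minimize_scalar

from .model_core import (
    CellParams,
    PlasmidGenotype,
    growth_rate,
    inhibition_response,
)

__all__ = [
    "CellCycleResult",
    "Equilibrium",
    "EquilibriumSet",
    "EdgeResult",
    "integrate_cell_cycle",
    "generation_map",
    "find_equilibria",
    "cell_fitness",
    "plasmid_free_fitness",
    "equilibrium_mean_copy_number",
    "edge_of_stability",
    "death_boundary",
]

Outcome = Literal["divides", "dies", "stalls"]

# Biomass fraction of M0 below which a shrinking cell is classified dead.
# Once g(n) < 0 on a trajectory it stays negative (n is non-decreasing and
# the benefit curve is concave), so any such crossing is irreversible.
DEATH_FRACTION = 0.5

# Stall horizon: multiple of the plasmid-free division time.
STALL_HORIZON_FACTOR = 50.0


@dataclass(frozen=True)
class CellCycleResult:
    """Outcome of integrating one cell cycle from (M0, n0)."""

    outcome: Outcome
    n_division: float = math.nan  # copy number when biomass reaches 2*M0
    T_div: float = math.nan       # cycle duration (time to division)
    n_final: float = math.nan     # copy number at termination (any outcome)

    @property
    def divided(self) -> bool:
        return self.outcome == "divides"


@dataclass(frozen=True)
class Equilibrium:
    n_star: float
    stable: bool
    T_div: float
    slope: float  # generation-map slope at the fixed point


@dataclass(frozen=True)
class EquilibriumSet:
    equilibria: tuple[Equilibrium, ...]

    def __len__(self) -> int:
        return len(self.equilibria)

    def __iter__(self):
        return iter(self.equilibria)

    @property
    def stable(self) -> tuple[Equilibrium, ...]:
        return tuple(e for e in self.equilibria if e.stable)

    @property
    def unstable(self) -> tuple[Equilibrium, ...]:
        return tuple(e for e in self.equilibria if not e.stable)


def _rhs(t, y, genotype: PlasmidGenotype, p: CellParams):
    M, n = y
    tk = n * genotype.kappa
    g = p.g0 + p.B * (-math.expm1(-p.steepness * n)) - p.c * n - p.c_inh * tk
    I = p.tau * tk / M
    r = genotype.alpha * inhibition_response(genotype.beta * I)
    return (M * g, n * r)


def integrate_cell_cycle(
    n0: float,
    genotype: PlasmidGenotype,
    p: CellParams,
    horizon: float | None = None,
    method: Literal["adaptive", "euler"] = "adaptive",
    euler_dt: float | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> CellCycleResult:
    """Integrate biomass and copy number over one cell cycle.

    Terminates when the biomass doubles (``divides``), when it collapses
    below ``DEATH_FRACTION * M0`` (``dies``; irreversible, see module
    notes), or when the horizon elapses (``stalls``).  The default
    integrator is adaptive Runge-Kutta with event detection; ``euler``
    reproduces the fixed-step update of the stochastic layer (with linear
    interpolation of the division crossing) and serves as an independent
    refinement oracle.
    """
    if n0 < 0:
        raise ValueError("initial copy number must be non-negative")
    if horizon is None:
        horizon = STALL_HORIZON_FACTOR * p.plasmid_free_division_time()

    if method == "euler":
        dt = p.dt if euler_dt is None else euler_dt
        M, n, t = p.M0, float(n0), 0.0
        while t < horizon:
            dM, dn = _rhs(t, (M, n), genotype, p)
            M1, n1 = M + dt * dM, n + dt * dn
            t += dt
            if M1 >= p.division_mass:
                theta = (p.division_mass - M) / (M1 - M)
                return CellCycleResult(
                    "divides",
                    n_division=n + theta * (n1 - n),
                    T_div=t - dt + theta * dt,
                    n_final=n + theta * (n1 - n),
                )
            if M1 < DEATH_FRACTION * p.M0:
                return CellCycleResult("dies", n_final=n1)
            M, n = M1, n1
        return CellCycleResult("stalls", n_final=n)

    def ev_divide(t, y, *args):
        return y[0] - p.division_mass

    ev_divide.terminal = True
    ev_divide.direction = 1.0

    def ev_death(t, y, *args):
        return y[0] - DEATH_FRACTION * p.M0

    ev_death.terminal = True
    ev_death.direction = -1.0

    sol = solve_ivp(
        _rhs,
        (0.0, horizon),
        (p.M0, float(n0)),
        args=(genotype, p),
        events=(ev_divide, ev_death),
        rtol=rtol,
        atol=atol,
        method="RK45",
        dense_output=False,
    )
    if not sol.success or not np.all(np.isfinite(sol.y)):
        raise ArithmeticError(
            f"cell-cycle integration failed for n0={n0}, genotype={genotype}: "
            f"{sol.message}"
        )
    if sol.t_events[0].size:
        t_div = float(sol.t_events[0][0])
        n_div = float(sol.y_events[0][0][1])
        return CellCycleResult("divides", n_division=n_div, T_div=t_div,
                               n_final=n_div)
    if sol.t_events[1].size:
        return CellCycleResult("dies", n_final=float(sol.y_events[1][0][1]))
    return CellCycleResult("stalls", n_final=float(sol.y[1, -1]))


def generation_map(n0: float, genotype: PlasmidGenotype, p: CellParams,
                   **kwargs) -> float:
    """Parent-to-daughter copy-number map G(n0) = n_division/2.

    Assumes equipartitioning at division.  Returns NaN where the map is
    undefined (the cell dies or stalls instead of dividing).
    """
    res = integrate_cell_cycle(n0, genotype, p, **kwargs)
    return res.n_division / 2.0 if res.divided else math.nan


def death_boundary(genotype: PlasmidGenotype, p: CellParams,
                   n_hi: float = 1e6) -> float:
    """Largest copy number with non-negative instantaneous growth rate.

    Solves ``g(n) = 0`` above the benefit optimum; cells starting beyond
    it shrink from the outset.  Used as the default upper end of root
    searches on the generation map.
    """
    kappa = genotype.kappa

    def g_of(n):
        return growth_rate(n, n * kappa, p)

    if g_of(n_hi) > 0:
        return n_hi
    # expand from the optimum region until g < 0
    n = max(1.0, 1.0 / p.steepness)
    while g_of(n) > 0 and n < n_hi:
        n *= 2.0
    return brentq(g_of, n / 2.0, min(n, n_hi), xtol=1e-9, rtol=1e-12)


def _map_slope(n_star: float, genotype, p, rel_h: float = 1e-4) -> float:
    h = rel_h * max(n_star, 1.0)
    g_hi = generation_map(n_star + h, genotype, p)
    g_lo = generation_map(max(n_star - h, 1e-12), genotype, p)
    return (g_hi - g_lo) / (n_star + h - max(n_star - h, 1e-12))


def find_equilibria(
    genotype: PlasmidGenotype,
    p: CellParams,
    n_range: tuple[float, float] | None = None,
    n_grid: int = 200,
    xtol: float = 1e-8,
) -> EquilibriumSet:
    """All fixed points of the generation map in ``n_range``, with stability.

    Roots of ``G(n) - n`` are bracketed by sign changes on a uniform grid
    and refined by Brent's method; stability is classified from the map
    slope (central difference): ``|G'(n*)| < 1``.  An empty set is a valid
    outcome (consistent under- or over-replication).
    """
    if n_range is None:
        hi = death_boundary(genotype, p)
        n_range = (1e-2, hi)
    lo, hi = n_range
    grid = np.linspace(lo, hi, n_grid)
    vals = np.array([generation_map(n, genotype, p) - n for n in grid])

    roots: list[float] = []
    for i in range(len(grid) - 1):
        a, b = vals[i], vals[i + 1]
        if not (np.isfinite(a) and np.isfinite(b)):
            continue
        if a == 0.0:
            roots.append(float(grid[i]))
        elif a * b < 0:
            root = brentq(
                lambda n: generation_map(n, genotype, p) - n,
                grid[i], grid[i + 1], xtol=xtol,
            )
            roots.append(float(root))

    eqs = []
    for n_star in roots:
        slope = _map_slope(n_star, genotype, p)
        res = integrate_cell_cycle(n_star, genotype, p)
        eqs.append(
            Equilibrium(n_star=n_star, stable=abs(slope) < 1.0,
                        T_div=res.T_div, slope=slope)
        )
    return EquilibriumSet(tuple(eqs))


def cell_fitness(genotype: PlasmidGenotype, p: CellParams,
                 equilibria: EquilibriumSet | None = None) -> float:
    """Cell fitness 1/T_div on the cycle starting at the stable copy number.

    Returns NaN (undefined, not zero) when no stable characteristic copy
    number exists.  If several stable fixed points exist the one with the
    largest copy number is used.
    """
    eqs = find_equilibria(genotype, p) if equilibria is None else equilibria
    stable = eqs.stable
    if not stable:
        return math.nan
    eq = max(stable, key=lambda e: e.n_star)
    return 1.0 / eq.T_div


def plasmid_free_fitness(p: CellParams) -> float:
    """Fitness of the plasmid-free reference cell: g0/ln 2."""
    return p.g0 / math.log(2.0)


def equilibrium_mean_copy_number(
    genotype: PlasmidGenotype, p: CellParams,
    equilibria: EquilibriumSet | None = None, n_points: int = 400,
) -> float:
    """Stationary snapshot mean copy number of an asynchronous population.

    At the stable fixed point the copy number runs from ``n*`` to ``2 n*``
    over each cycle of length T.  In a steadily growing asynchronous
    population cell ages are exponentially distributed with density
    ``f(a) = 2 (ln2/T) 2^(-a/T)``; the expected copy number observed in a
    population snapshot is ``E[n] = int n(a) f(a) da`` (~= 2 ln2 n* for
    exponential n growth).  This is the deterministic prediction matched
    by the stochastic layer's infected-cell mean.
    """
    eqs = find_equilibria(genotype, p) if equilibria is None else equilibria
    stable = eqs.stable
    if not stable:
        return math.nan
    eq = max(stable, key=lambda e: e.n_star)
    T = eq.T_div
    sol = solve_ivp(
        _rhs, (0.0, T), (p.M0, eq.n_star), args=(genotype, p),
        t_eval=np.linspace(0.0, T, n_points), rtol=1e-8, atol=1e-10,
    )
    ages = sol.t
    n_of_a = sol.y[1]
    lam = math.log(2.0) / T
    w = 2.0 * lam * np.exp2(-ages / T)
    return float(np.trapezoid(w * n_of_a, ages))


@dataclass(frozen=True)
class EdgeResult:
    """Edge of plasmid stability in the basal replication rate alpha."""

    alpha_crit: float
    mode: Literal["fold", "boundary"]
    n_fold: float = math.nan
    slope_at_fold: float = math.nan


def _has_stable_root(alpha, beta, kappa, p, n_range, n_grid) -> bool:
    g = PlasmidGenotype(alpha=alpha, kappa=kappa, beta=beta)
    return len(find_equilibria(g, p, n_range=n_range, n_grid=n_grid).stable) > 0


def edge_of_stability(
    beta: float,
    kappa: float,
    p: CellParams,
    alpha_range: tuple[float, float],
    coarse: int = 21,
    n_grid: int = 120,
    bisect_iter: int = 40,
    polish: bool = True,
) -> EdgeResult:
    """Critical basal replication rate where characteristic copy numbers vanish.

    Scans ``alpha_range`` for the transition from "a stable fixed point
    exists" to "none exists", refines it by bisection, and — when the
    transition is a genuine fold (stable and unstable roots coalescing in
    the interior) — polishes it by driving the generation map tangent to
    the diagonal: the signed gap ``min_n (G(n) - n)`` over the inter-root
    window crosses zero exactly at the fold, where the map slope is 1.

    Raises ``ValueError`` with a diagnostic if the whole range is in a
    single regime.
    """
    a_lo_in, a_hi_in = alpha_range
    alphas = np.linspace(a_lo_in, a_hi_in, coarse)

    def genotype(a):
        return PlasmidGenotype(alpha=a, kappa=kappa, beta=beta)

    hi_death = death_boundary(genotype(a_hi_in), p)
    n_range = (1e-2, hi_death)

    flags = [_has_stable_root(a, beta, kappa, p, n_range, n_grid) for a in alphas]
    if all(flags):
        raise ValueError(
            "no fold in range: a stable equilibrium exists over the whole "
            f"alpha range {alpha_range}"
        )
    if not any(flags):
        raise ValueError(
            "no fold in range: no stable equilibrium anywhere in "
            f"{alpha_range} (entirely under- or over-replicating)"
        )
    # last True before the trailing run of False
    idx = max(i for i, f in enumerate(flags) if f)
    if idx == len(flags) - 1:
        raise ValueError("stable region touches the top of alpha_range")
    a_lo, a_hi = float(alphas[idx]), float(alphas[idx + 1])

    for _ in range(bisect_iter):
        mid = 0.5 * (a_lo + a_hi)
        if _has_stable_root(mid, beta, kappa, p, n_range, n_grid):
            a_lo = mid
        else:
            a_hi = mid
        if (a_hi - a_lo) < 1e-10 * max(1.0, a_hi):
            break

    a_edge = 0.5 * (a_lo + a_hi)
    if not polish:
        return EdgeResult(alpha_crit=a_edge, mode="boundary")

    # Polish the fold by tangency.  The grid-based existence bisection can
    # only localise the edge down to the resolution at which the inter-root
    # dip of G(n)-n becomes invisible, so step back a little to identify the
    # coalescing root pair cleanly, then drive the signed dip depth to zero.
    da = 0.02 * (a_hi_in - a_lo_in)
    eqs = find_equilibria(genotype(a_edge - da), p, n_range=n_range,
                          n_grid=n_grid)
    stable = eqs.stable
    unstable = [e for e in eqs.unstable
                if e.n_star > max(s.n_star for s in stable)] if stable else []
    if not stable or not unstable:
        # roots disappear by collision with the death boundary, not a fold
        return EdgeResult(alpha_crit=a_edge, mode="boundary")

    n_s = max(s.n_star for s in stable)
    n_u = min(u.n_star for u in unstable)

    def gap(a):
        g = genotype(a)

        def f(n):
            return generation_map(n, g, p) - n

        res = minimize_scalar(f, bounds=(n_s * 0.95, n_u * 1.05),
                              method="bounded",
                              options={"xatol": 1e-9 * max(n_u, 1.0)})
        return res.fun, res.x

    g_lo, _ = gap(a_edge - da)
    g_hi, _ = gap(a_edge + da)
    if not (g_lo < 0 < g_hi):
        return EdgeResult(alpha_crit=a_edge, mode="boundary")
    a_crit = brentq(lambda a: gap(a)[0], a_edge - da, a_edge + da,
                    xtol=1e-13, rtol=8.9e-16)
    _, n_fold = gap(a_crit)
    slope = _map_slope(float(n_fold), genotype(a_crit), p)
    return EdgeResult(alpha_crit=float(a_crit), mode="fold",
                      n_fold=float(n_fold), slope_at_fold=float(slope))
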