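"""Stochastic multicellular engine.

Asynchronous host growth and division/death, Poisson plasmid replication
with optional mutation, binomial segregation at division, neutral
population-size regulation, and the observable recorders.

The population is stored flat for speed: one biomass array over cells and
one ``(n_plasmids, 3)`` trait array with a parallel cell-index array.  All
per-step work (growth, replication draws, mutation, death, division,
segregation) is vectorised over the whole population; the per-cell
operations :func:`step_cell` and :func:`divide_cell` are thin single-cell
views of the same arithmetic used in tests and small examples.

Update order within one time step is fixed (reproducibility):
grow -> replicate/mutate -> remove dead -> divide -> regulate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model_core import (
    TRAIT_NAMES,
    CellParams,
    EvolutionParams,
    HostCell,
    PlasmidGenotype,
    growth_rate,
    inhibition_response,
)

__all__ = [
    "Counters",
    "Population",
    "ObservableSeries",
    "ExtinctionError",
    "step",
    "step_cell",
    "divide_cell",
    "mutate",
    "regulate_population",
    "run_simulation",
    "variance_decomposition",
]

# Biomass floor (fraction of M0) below which a cell is dead.  The bare
# rule M < 0 is reachable in the discrete update only under extreme plasmid
# load (g*dt <= -1); the floor additionally removes cells shrinking
# geometrically towards zero with replication fully stalled, which can never
# divide again.
DEATH_FLOOR_FRACTION = 1e-3


class ExtinctionError(RuntimeError):
    """Raised when the host population has gone extinct."""


@dataclass
class Counters:
    divisions: int = 0
    deaths: int = 0
    seg_losses: int = 0
    infected_divisions: int = 0

    def copy(self) -> "Counters":
        return Counters(self.divisions, self.deaths, self.seg_losses,
                        self.infected_divisions)

    def delta(self, earlier: "Counters") -> "Counters":
        return Counters(
            self.divisions - earlier.divisions,
            self.deaths - earlier.deaths,
            self.seg_losses - earlier.seg_losses,
            self.infected_divisions - earlier.infected_divisions,
        )


@dataclass
class Population:
    """Flat-array host population: biomasses, plasmid traits, cell indices."""

    M: np.ndarray                      # (n_cells,)
    traits: np.ndarray                 # (n_plasmids, 3)
    cell_of: np.ndarray                # (n_plasmids,) int64
    rng: np.random.Generator
    labels: np.ndarray | None = None   # optional per-plasmid lineage labels
    t: float = 0.0
    counters: Counters = field(default_factory=Counters)

    # -- construction -------------------------------------------------------

    @classmethod
    def homogeneous(
        cls,
        n_cells: int,
        n_init: int,
        genotype: PlasmidGenotype,
        p: CellParams,
        seed: int | np.random.Generator = 0,
        stagger: bool = True,
        label: int = 0,
    ) -> "Population":
        """Found a population of identical cells carrying one genotype.

        With ``stagger`` (default) newborn biomasses are drawn from the
        stationary biomass distribution of a steadily dividing population
        (density proportional to 1/M^2 on [M0, 2*M0)), which desynchronises
        division times from the outset.
        """
        rng = seed if isinstance(seed, np.random.Generator) \
            else np.random.default_rng(seed)
        if stagger:
            u = rng.random(n_cells)
            M = p.M0 * 2.0 / (2.0 - u)   # inverse CDF of the 1/M^2 law
        else:
            M = np.full(n_cells, p.M0, dtype=float)
        npl = n_cells * n_init
        traits = np.tile(genotype.as_array(), (npl, 1))
        cell_of = np.repeat(np.arange(n_cells, dtype=np.int64), n_init)
        labels = np.full(npl, label, dtype=np.int64)
        return cls(M=M, traits=traits, cell_of=cell_of, rng=rng, labels=labels)

    @classmethod
    def from_cells(cls, cells: list[HostCell],
                   seed: int | np.random.Generator = 0) -> "Population":
        rng = seed if isinstance(seed, np.random.Generator) \
            else np.random.default_rng(seed)
        M = np.array([c.biomass for c in cells], dtype=float)
        blocks = [c.traits_array() for c in cells]
        traits = np.concatenate(blocks) if blocks else np.empty((0, 3))
        cell_of = np.repeat(np.arange(len(cells), dtype=np.int64),
                            [c.n for c in cells])
        return cls(M=M, traits=traits, cell_of=cell_of, rng=rng,
                   labels=np.zeros(len(cell_of), dtype=np.int64))

    # -- views --------------------------------------------------------------

    @property
    def n_cells(self) -> int:
        return int(self.M.size)

    @property
    def n_plasmids(self) -> int:
        return int(self.traits.shape[0])

    def counts(self) -> np.ndarray:
        return np.bincount(self.cell_of, minlength=self.n_cells)

    def kappa_sums(self) -> np.ndarray:
        return np.bincount(self.cell_of, weights=self.traits[:, 1],
                           minlength=self.n_cells)

    def infected_fraction(self) -> float:
        if self.n_cells == 0:
            return math.nan
        return float(np.count_nonzero(self.counts()) / self.n_cells)

    def cells(self) -> list[HostCell]:
        """Materialise per-cell objects (small populations / tests only)."""
        out = []
        counts = self.counts()
        order = np.argsort(self.cell_of, kind="stable")
        splits = np.cumsum(counts)[:-1]
        groups = np.split(self.traits[order], splits)
        for M, grp in zip(self.M, groups):
            out.append(HostCell(
                biomass=float(M),
                plasmids=[PlasmidGenotype.from_array(row) for row in grp],
            ))
        return out

    def _keep_cells(self, keep: np.ndarray) -> None:
        """Drop cells where ``keep`` is False and reindex plasmids."""
        remap = np.cumsum(keep) - 1
        pl_keep = keep[self.cell_of]
        self.M = self.M[keep]
        self.traits = self.traits[pl_keep]
        if self.labels is not None:
            self.labels = self.labels[pl_keep]
        self.cell_of = remap[self.cell_of[pl_keep]]


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def mutate(genotype: PlasmidGenotype, ev: EvolutionParams,
           rng: np.random.Generator) -> PlasmidGenotype:
    """Perturb exactly one trait of a genotype (uniform choice among free).

    Additive uniform step of half-width ``ev.step`` times the trait's
    bound, clipped into ``[0, bound]``.  Frozen traits are never touched.
    """
    free = ev.free_indices
    idx = int(free[rng.integers(0, free.size)])
    caps = ev.bounds.as_array()
    delta = rng.uniform(-1.0, 1.0) * ev.step * caps[idx]
    arr = genotype.as_array()
    arr[idx] = min(max(arr[idx] + delta, 0.0), caps[idx])
    return PlasmidGenotype.from_array(arr)


def divide_cell(cell: HostCell, rng: np.random.Generator
                ) -> tuple[HostCell, HostCell, int]:
    """Binary fission with binomial plasmid segregation.

    Each plasmid copy goes to either daughter with probability 1/2;
    biomass is split equally.  Returns both daughters and the number of
    segregational-loss events (plasmid-free daughters of an infected
    parent; at most one per division).
    """
    if cell.biomass < 0:
        raise ValueError("cannot divide a dead cell")
    side = rng.integers(0, 2, size=cell.n)
    pl_a = [pl for pl, s in zip(cell.plasmids, side) if s == 0]
    pl_b = [pl for pl, s in zip(cell.plasmids, side) if s == 1]
    half = cell.biomass / 2.0
    d1, d2 = HostCell(half, pl_a), HostCell(half, pl_b)
    losses = 0
    if cell.n > 0:
        losses = int(d1.n == 0) + int(d2.n == 0)
    return d1, d2, losses


def _replicate_and_mutate(pop: Population, p: CellParams,
                          ev: EvolutionParams | None,
                          form: str = "hyperbolic") -> None:
    """Draw Poisson replication events for every plasmid; append offspring."""
    if pop.n_plasmids == 0:
        return
    ksum = pop.kappa_sums()
    with np.errstate(divide="ignore"):
        I = np.where(pop.M > 0, p.tau * ksum / np.maximum(pop.M, 1e-300),
                     np.inf)
    x = pop.traits[:, 2] * I[pop.cell_of]
    lam = pop.traits[:, 0] * inhibition_response(x, form) * p.dt
    events = pop.rng.poisson(lam)
    total = int(events.sum())
    if total == 0:
        return
    parents = np.repeat(np.arange(pop.n_plasmids), events)
    new_traits = pop.traits[parents].copy()
    if ev is not None and ev.mu > 0.0:
        mut = pop.rng.random(total) < ev.mu
        k = int(mut.sum())
        if k:
            free = ev.free_indices
            which = free[pop.rng.integers(0, free.size, size=k)]
            caps = ev.bounds.as_array()
            deltas = pop.rng.uniform(-1.0, 1.0, size=k) * ev.step * caps[which]
            rows = np.flatnonzero(mut)
            new_traits[rows, which] = np.clip(
                new_traits[rows, which] + deltas, 0.0, caps[which])
    pop.traits = np.concatenate([pop.traits, new_traits])
    pop.cell_of = np.concatenate([pop.cell_of, pop.cell_of[parents]])
    if pop.labels is not None:
        pop.labels = np.concatenate([pop.labels, pop.labels[parents]])


def _grow(pop: Population, p: CellParams) -> None:
    counts = pop.counts()
    ksum = pop.kappa_sums()
    g = p.g0 + p.B * (-np.expm1(-p.steepness * counts)) \
        - p.c * counts - p.c_inh * ksum
    pop.M = pop.M * (1.0 + g * p.dt)


def _apply_deaths(pop: Population, p: CellParams) -> int:
    dead = pop.M < DEATH_FLOOR_FRACTION * p.M0
    ndead = int(dead.sum())
    if ndead:
        pop._keep_cells(~dead)
        pop.counters.deaths += ndead
    return ndead


def _apply_divisions(pop: Population, p: CellParams) -> int:
    div = pop.M >= p.division_mass
    ndiv = int(div.sum())
    if ndiv == 0:
        return 0
    counts = pop.counts()
    infected_div = div & (counts > 0)
    pop.counters.divisions += ndiv
    pop.counters.infected_divisions += int(infected_div.sum())

    n_old = pop.n_cells
    div_rank = np.full(n_old, -1, dtype=np.int64)
    div_rank[div] = np.arange(ndiv)

    pl_div = div[pop.cell_of]
    n_moving_pool = int(pl_div.sum())
    side = pop.rng.integers(0, 2, size=n_moving_pool)

    pl_idx = np.flatnonzero(pl_div)
    movers = pl_idx[side == 1]
    parent_cells = pop.cell_of[movers]
    pop.cell_of = pop.cell_of.copy()
    pop.cell_of[movers] = n_old + div_rank[parent_cells]

    # segregational losses: an infected parent leaving one daughter empty
    stay_counts = np.bincount(pop.cell_of[pl_idx[side == 0]],
                              minlength=n_old)[:n_old]
    go_counts = np.bincount(parent_cells, minlength=n_old)[:n_old]
    inf_idx = np.flatnonzero(infected_div)
    losses = int((stay_counts[inf_idx] == 0).sum()
                 + (go_counts[inf_idx] == 0).sum())
    pop.counters.seg_losses += losses

    pop.M[div] /= 2.0
    pop.M = np.concatenate([pop.M, pop.M[div]])
    return ndiv


def step(pop: Population, p: CellParams, ev: EvolutionParams | None = None,
         form: str = "hyperbolic") -> np.ndarray:
    """Advance the whole population by one time step ``p.dt`` in place.

    Returns the per-cell plasmid counts *before* the step (used by the
    recorders for copy-number histograms).  New daughter cells enter the
    schedule at the next step; divisions do not cascade within a step.
    """
    if pop.n_cells == 0:
        raise ExtinctionError("population is extinct")
    counts_before = pop.counts()
    _grow(pop, p)
    _replicate_and_mutate(pop, p, ev, form)
    _apply_deaths(pop, p)
    _apply_divisions(pop, p)
    pop.t += p.dt
    return counts_before


def step_cell(cell: HostCell, p: CellParams, ev: EvolutionParams | None,
              rng: np.random.Generator, form: str = "hyperbolic"
              ) -> tuple[HostCell, dict]:
    """Single-cell view of one engine step (growth + replication/mutation).

    Returns the updated cell and an event dict with ``divide`` and
    ``death`` flags; the division itself is performed by
    :func:`divide_cell`.
    """
    if not cell.alive:
        raise ValueError("cannot step a dead cell")
    pop = Population(
        M=np.array([cell.biomass], dtype=float),
        traits=cell.traits_array(),
        cell_of=np.zeros(cell.n, dtype=np.int64),
        rng=rng,
        labels=np.zeros(cell.n, dtype=np.int64),
    )
    _grow(pop, p)
    _replicate_and_mutate(pop, p, ev, form)
    new = HostCell(
        biomass=float(pop.M[0]),
        plasmids=[PlasmidGenotype.from_array(r) for r in pop.traits],
    )
    events = {
        "divide": new.biomass >= p.division_mass,
        "death": new.biomass < DEATH_FLOOR_FRACTION * p.M0,
    }
    return new, events


def regulate_population(pop: Population, cap: int) -> Population:
    """Neutral hard cap: uniformly random cells are culled down to ``cap``."""
    if cap < 1:
        raise ValueError("cap must be at least 1")
    if pop.n_cells == 0:
        raise ExtinctionError("population is extinct")
    if pop.n_cells <= cap:
        return pop
    keep_idx = pop.rng.permutation(pop.n_cells)[:cap]
    keep = np.zeros(pop.n_cells, dtype=bool)
    keep[keep_idx] = True
    pop._keep_cells(keep)
    return pop


# ---------------------------------------------------------------------------
# observables
# ---------------------------------------------------------------------------

def variance_decomposition(pop: Population) -> pd.DataFrame:
    """Within-host and between-host SDs of each trait over infected hosts.

    ``within`` is the SD of plasmid trait values around their host's mean,
    averaged across infected hosts; ``between`` is the SD of host means
    around the global mean of host means.  Raises ``ValueError`` when no
    host is infected.
    """
    counts = pop.counts()
    if not np.any(counts > 0):
        raise ValueError("variance decomposition undefined: no infected host")
    inf = counts > 0
    out = {}
    for j, name in enumerate(TRAIT_NAMES):
        x = pop.traits[:, j]
        s1 = np.bincount(pop.cell_of, weights=x, minlength=pop.n_cells)
        s2 = np.bincount(pop.cell_of, weights=x * x, minlength=pop.n_cells)
        m = s1[inf] / counts[inf]
        var_within = np.maximum(s2[inf] / counts[inf] - m * m, 0.0)
        within = float(np.mean(np.sqrt(var_within)))
        between = float(np.std(m))
        out[name] = {"within": within, "between": between}
    return pd.DataFrame(out).T[["within", "between"]]


@dataclass
class ObservableSeries:
    """Recorded time series plus the pooled copy-number histogram."""

    frame: pd.DataFrame
    copy_number_hist: np.ndarray
    terminated: bool
    population: Population

    def hist_moments(self) -> dict:
        """Mean, SD and skewness of the pooled infected-cell copy numbers."""
        h = self.copy_number_hist
        total = h.sum()
        if total == 0:
            return {"mean": math.nan, "sd": math.nan, "skew": math.nan,
                    "mass": 0}
        n = np.arange(h.size, dtype=float)
        w = h / total
        mean = float(np.sum(w * n))
        var = float(np.sum(w * (n - mean) ** 2))
        sd = math.sqrt(var)
        skew = float(np.sum(w * (n - mean) ** 3) / sd**3) if sd > 0 else math.nan
        return {"mean": mean, "sd": sd, "skew": skew, "mass": int(total)}


def _accumulate_hist(hist: np.ndarray, counts: np.ndarray) -> np.ndarray:
    pos = counts[counts > 0]
    if pos.size == 0:
        return hist
    add = np.bincount(pos)
    if add.size > hist.size:
        hist = np.concatenate([hist, np.zeros(add.size - hist.size,
                                              dtype=np.int64)])
    hist[: add.size] += add
    return hist


def use_compiled_engine(engine: str = "auto") -> bool:
    """Resolve the engine choice: compiled numba kernel vs numpy reference."""
    from . import _engine

    if engine == "numpy":
        return False
    if engine == "numba":
        if not _engine.HAVE_NUMBA:
            raise RuntimeError("numba is not available")
        return True
    if engine != "auto":
        raise ValueError(f"unknown engine {engine!r}")
    return _engine.HAVE_NUMBA


def run_simulation(
    pop: Population,
    p: CellParams,
    ev: EvolutionParams | None,
    cap: int,
    steps: int,
    record_every: int = 50,
    hist_start: int = 0,
    form: str = "hyperbolic",
    engine: str = "auto",
) -> ObservableSeries:
    """Iterate the engine for ``steps`` time steps, recording observables.

    One row is recorded every ``record_every`` steps: population size,
    infected fraction, per-plasmid trait means, within/between-host trait
    SDs, copy-number moments among infected cells, and per-interval event
    rates.  Division and death rates are per cell per unit time;
    ``seg_loss_rate`` is the fraction of infected-cell divisions that
    produced a plasmid-free daughter.  The copy-number histogram pools the
    counts of every infected cell at every step from ``hist_start`` on.
    Extinction truncates the series (``terminated=True``).

    ``engine='auto'`` uses the compiled kernel when numba is available and
    falls back to the vectorised numpy reference path otherwise; the two
    are statistically equivalent but draw different random streams.
    """
    if use_compiled_engine(engine) and form == "hyperbolic":
        return _run_simulation_compiled(pop, p, ev, cap, steps,
                                        record_every, hist_start)
    rows = []
    hist = np.zeros(1, dtype=np.int64)
    terminated = False
    last_counters = pop.counters.copy()
    cell_time = 0.0

    for k in range(steps):
        try:
            cell_time += pop.n_cells * p.dt
            counts_before = step(pop, p, ev, form)
            if k >= hist_start:
                hist = _accumulate_hist(hist, counts_before)
            regulate_population(pop, cap)
        except ExtinctionError:
            terminated = True
            break
        if (k + 1) % record_every == 0:
            rows.append(_observable_row(pop, pop.counters.delta(last_counters),
                                        cell_time))
            last_counters = pop.counters.copy()
            cell_time = 0.0
    if terminated or steps % record_every != 0:
        rows.append(_observable_row(pop, pop.counters.delta(last_counters),
                                    cell_time))
    return ObservableSeries(
        frame=pd.DataFrame(rows),
        copy_number_hist=hist,
        terminated=terminated,
        population=pop,
    )


def advance_population(pop: Population, p: CellParams,
                       ev: EvolutionParams | None, cap: int, n_steps: int,
                       engine: str = "auto") -> bool:
    """Advance a population by ``n_steps`` in place; True when extinct."""
    if use_compiled_engine(engine):
        from ._engine import EngineState

        st = EngineState(pop, p, cap, seed=int(pop.rng.integers(2**31)))
        done, extinct = st.advance(n_steps, ev, hist_on=False)
        pop.t += done * p.dt
        st.sync(pop)
        return extinct
    for _ in range(n_steps):
        try:
            step(pop, p, ev)
            regulate_population(pop, cap)
        except ExtinctionError:
            return True
    return False


def _observable_row(pop: Population, delta: Counters, cell_time: float) -> dict:
    """One recorded row of population observables (shared by both engines)."""
    counts = pop.counts() if pop.n_cells else np.zeros(0, dtype=np.int64)
    infected = counts[counts > 0]
    div_rate = delta.divisions / cell_time if cell_time > 0 else math.nan
    death_rate = delta.deaths / cell_time if cell_time > 0 else math.nan
    row = {
        "t": pop.t,
        "n_cells": pop.n_cells,
        "n_plasmids": pop.n_plasmids,
        "infected_fraction": (infected.size / pop.n_cells
                              if pop.n_cells else math.nan),
        "mean_n": float(infected.mean()) if infected.size else math.nan,
        "sd_n": float(infected.std()) if infected.size else math.nan,
        "division_rate": div_rate,
        "death_rate": death_rate,
        "net_growth_rate": div_rate - death_rate,
        "seg_loss_rate": (delta.seg_losses / delta.infected_divisions
                          if delta.infected_divisions else math.nan),
        "divisions": pop.counters.divisions,
        "deaths": pop.counters.deaths,
        "seg_losses": pop.counters.seg_losses,
        "infected_divisions": pop.counters.infected_divisions,
    }
    if pop.n_plasmids:
        for j, name in enumerate(TRAIT_NAMES):
            row[f"mean_{name}"] = float(pop.traits[:, j].mean())
        try:
            vd = variance_decomposition(pop)
            for name in TRAIT_NAMES:
                row[f"within_sd_{name}"] = vd.loc[name, "within"]
                row[f"between_sd_{name}"] = vd.loc[name, "between"]
        except ValueError:
            pass
    else:
        for name in TRAIT_NAMES:
            row[f"mean_{name}"] = math.nan
    return row


def _run_simulation_compiled(pop, p, ev, cap, steps, record_every,
                             hist_start) -> ObservableSeries:
    """Compiled-kernel driver: advance in record_every chunks, record rows.

    Histogram pooling starts at the first chunk boundary at or after
    ``hist_start``.
    """
    from ._engine import EngineState

    st = EngineState(pop, p, cap, seed=int(pop.rng.integers(2**31)))
    rows = []
    terminated = False
    last_counters = pop.counters.copy()
    k = 0
    while k < steps:
        chunk = min(record_every, steps - k)
        done, extinct = st.advance(chunk, ev, hist_on=(k >= hist_start))
        k += done
        pop.t += done * p.dt
        st.sync(pop)
        cell_time = float(st.stats[0])
        st.stats[0] = 0.0
        if extinct:
            terminated = True
            rows.append(_observable_row(pop, pop.counters.delta(last_counters),
                                        cell_time))
            break
        rows.append(_observable_row(pop, pop.counters.delta(last_counters),
                                    cell_time))
        last_counters = pop.counters.copy()
    hist = st.hist
    nz = np.flatnonzero(hist)
    hist = hist[: nz[-1] + 1].copy() if nz.size else np.zeros(1, np.int64)
    return ObservableSeries(
        frame=pd.DataFrame(rows),
        copy_number_hist=hist,
        terminated=terminated,
        population=pop,
    )
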