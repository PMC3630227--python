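"""Scripted experiment drivers.

Each driver reproduces the structure of one results protocol: the
homogeneous-strain fitness landscape, the obedience sweep of copy-number
distributions, trait co-evolution from a naive founder, the policing-cost
sweep, the paired comparison of evolving CNC vs passive (NO-CNC) control,
and invasion contests between fixed types.  Drivers return plain pandas
DataFrames; the CLI layer writes them as annotated delimited text.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd
from scipy import stats

from .model_core import (
    CellParams,
    EvolutionParams,
    PlasmidGenotype,
    optimal_copy_number,
)
from .stochastic import (
    Population,
    advance_population,
    run_simulation,
)

__all__ = [
    "ExperimentSpec",
    "SimSettings",
    "spawn_seeds",
    "classify_outcome",
    "fitness_landscape",
    "obedience_sweep",
    "coevolution",
    "policing_cost_sweep",
    "cnc_vs_nocnc",
    "compare_arms",
    "invasion",
]

OUTCOMES = ("stable-infected", "plasmid-loss-under", "plasmid-loss-over",
            "population-collapse")


@dataclass(frozen=True)
class ExperimentSpec:
    """Declarative description of one experiment for provenance tracking.

    ``sweep`` maps parameter names to their grids; ``seed`` is the master
    seed from which per-replicate streams are derived.  The hash is
    embedded in every output table an experiment writes.
    """

    name: str
    base: tuple[tuple[str, float | str], ...] = ()
    sweep: tuple[tuple[str, tuple[float, ...]], ...] = ()
    replicates: int = 1
    seed: int = 0
    recording_window: float = 0.5  # trailing fraction used for averages

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be at least 1")
        if not 0.0 < self.recording_window <= 1.0:
            raise ValueError("recording_window must lie in (0, 1]")

    def replicate_rngs(self) -> list[np.random.Generator]:
        """One independent, distinct stream per replicate."""
        return spawn_seeds(self.seed, self.replicates)

    def hash(self) -> str:
        import hashlib
        import json

        payload = json.dumps(
            [self.name, list(self.base), list(self.sweep), self.replicates,
             self.seed, self.recording_window])
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass(frozen=True)
class SimSettings:
    """Desk-scale stochastic simulation controls."""

    cap: int = 1000
    steps: int = 20_000
    record_every: int = 100
    n_init: int = 8
    burn_in_fraction: float = 0.5  # discarded when averaging observables

    def hist_start(self) -> int:
        return int(self.steps * self.burn_in_fraction)


def spawn_seeds(master_seed: int, k: int) -> list[np.random.Generator]:
    """Derive ``k`` independent RNG streams from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [np.random.default_rng(child) for child in ss.spawn(k)]


def _tail_mean(series: pd.Series, frac: float) -> float:
    tail = series.iloc[int(len(series) * frac):]
    tail = tail.dropna()
    return float(tail.mean()) if len(tail) else math.nan


def classify_outcome(obs, n_init: int) -> str:
    """Label a homogeneous-strain run with its qualitative fate.

    ``population-collapse``: extinction.  ``stable-infected``: a majority
    of hosts still carry plasmids at the end.  Otherwise the plasmids were
    lost; runs whose infected-cell mean copy number ever rose well above
    the inoculum are ``plasmid-loss-over`` (runaway replication outgrown
    by plasmid-free segregants), the rest ``plasmid-loss-under`` (dilution).
    """
    if obs.terminated:
        return "population-collapse"
    f = obs.frame
    final_inf = _tail_mean(f["infected_fraction"], 0.9)
    if final_inf >= 0.5:
        return "stable-infected"
    peak = f["mean_n"].max()
    if np.isfinite(peak) and peak >= 1.5 * n_init:
        return "plasmid-loss-over"
    return "plasmid-loss-under"


def _homogeneous_run(genotype, p, settings, rng, ev=None):
    pop = Population.homogeneous(
        settings.cap // 2, settings.n_init, genotype, p, seed=rng)
    return run_simulation(
        pop, p, ev, cap=settings.cap, steps=settings.steps,
        record_every=settings.record_every, hist_start=settings.hist_start())


# ---------------------------------------------------------------------------
# homogeneous-strain landscape
# ---------------------------------------------------------------------------

def fitness_landscape(
    alphas,
    betas,
    kappa: float,
    p: CellParams,
    settings: SimSettings,
    replicates: int = 1,
    seed: int = 0,
) -> pd.DataFrame:
    """Net growth rate and outcome over an (alpha, beta) grid at fixed kappa.

    One homogeneous (mutation-free) simulation per grid cell per
    replicate.  Net growth is the division-minus-death rate per cell per
    unit time averaged over the post-burn-in window; the outcome label is
    the modal classification across replicates.
    """
    alphas = np.asarray(alphas, dtype=float)
    betas = np.asarray(betas, dtype=float)
    rngs = spawn_seeds(seed, alphas.size * betas.size * replicates)
    rows = []
    i = 0
    for a in alphas:
        for b in betas:
            nets, outs = [], []
            for _ in range(replicates):
                obs = _homogeneous_run(
                    PlasmidGenotype(a, kappa, b), p, settings, rngs[i])
                i += 1
                nets.append(_tail_mean(obs.frame["net_growth_rate"],
                                       settings.burn_in_fraction))
                outs.append(classify_outcome(obs, settings.n_init))
            outcome = max(set(outs), key=outs.count)
            rows.append({
                "alpha": a, "beta": b, "kappa": kappa,
                "net_growth_rate": float(np.nanmean(nets)),
                "outcome": outcome,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# obedience sweep
# ---------------------------------------------------------------------------

def obedience_sweep(
    alpha: float,
    betas,
    kappa: float,
    p: CellParams,
    settings: SimSettings,
    replicates: int = 5,
    seed: int = 0,
) -> dict:
    """Copy-number distribution statistics along a fixed-alpha beta grid.

    ``alpha`` is meant to be the value that maximises net growth at full
    obedience (the landscape optimum at beta_max).  For each beta level
    the pooled copy-number distribution of all infected hosts (post
    burn-in) is summarised by its mean, SD and skewness, plus the
    discrepancy |mean(n) - n_opt|; runs that lose their plasmids are
    flagged.
    """
    betas = np.asarray(betas, dtype=float)
    n_opt = optimal_copy_number(p, kappa=kappa)
    rngs = spawn_seeds(seed, betas.size * replicates)
    per_rep, hists = [], {}
    i = 0
    for b in betas:
        pooled = np.zeros(1, dtype=np.int64)
        for r in range(replicates):
            obs = _homogeneous_run(
                PlasmidGenotype(alpha, kappa, b), p, settings, rngs[i])
            i += 1
            mom = obs.hist_moments()
            h = obs.copy_number_hist
            if h.size > pooled.size:
                pooled = np.concatenate(
                    [pooled, np.zeros(h.size - pooled.size, dtype=np.int64)])
            pooled[: h.size] += h
            per_rep.append({
                "beta": b, "replicate": r,
                "mean_n": mom["mean"], "sd_n": mom["sd"],
                "skew_n": mom["skew"], "mass": mom["mass"],
                "abs_dev_n_opt": abs(mom["mean"] - n_opt),
                "lost": classify_outcome(obs, settings.n_init)
                        != "stable-infected",
            })
        hists[float(b)] = pooled
    df = pd.DataFrame(per_rep)
    summary = (
        df.groupby("beta")
        .agg(mean_n=("mean_n", "mean"), sd_n=("sd_n", "mean"),
             skew_n=("skew_n", "mean"),
             abs_dev_n_opt=("abs_dev_n_opt", "mean"),
             sem_sd=("sd_n", "sem"), sem_skew=("skew_n", "sem"),
             sem_dev=("abs_dev_n_opt", "sem"),
             lost=("lost", "mean"))
        .reset_index()
    )
    return {"per_replicate": df, "summary": summary, "histograms": hists,
            "n_opt": n_opt}


# ---------------------------------------------------------------------------
# co-evolution
# ---------------------------------------------------------------------------

def coevolution(
    founder: PlasmidGenotype,
    p: CellParams,
    ev: EvolutionParams,
    settings: SimSettings,
    replicates: int = 10,
    seed: int = 0,
) -> dict:
    """Trait co-evolution from a founder genotype under mutation.

    Runs ``replicates`` independent simulations, returning per-replicate
    trait-mean trajectories, an endpoint summary (post-burn-in means of
    traits and performance metrics), and the within/between-host trait-SD
    decomposition averaged over the recording window.  Replicates that go
    extinct are flagged and excluded from averages.
    """
    rngs = spawn_seeds(seed, replicates)
    trajs, endpoints = [], []
    extinct = 0
    for r in range(replicates):
        obs = _homogeneous_run(founder, p, settings, rngs[r], ev=ev)
        f = obs.frame.copy()
        f["replicate"] = r
        trajs.append(f)
        if obs.terminated:
            extinct += 1
            continue
        frac = settings.burn_in_fraction
        ep = {"replicate": r}
        for col in ("mean_alpha", "mean_kappa", "mean_beta",
                    "division_rate", "death_rate", "net_growth_rate",
                    "seg_loss_rate", "infected_fraction", "mean_n"):
            ep[col] = _tail_mean(f[col], frac)
        for name in ("alpha", "kappa", "beta"):
            for side in ("within", "between"):
                col = f"{side}_sd_{name}"
                ep[col] = _tail_mean(f[col], frac) if col in f else math.nan
        endpoints.append(ep)
    return {
        "trajectories": pd.concat(trajs, ignore_index=True),
        "endpoint": pd.DataFrame(endpoints),
        "extinct_replicates": extinct,
    }


# ---------------------------------------------------------------------------
# policing costs
# ---------------------------------------------------------------------------

def policing_cost_sweep(
    c_inh_values,
    founder: PlasmidGenotype,
    p: CellParams,
    ev: EvolutionParams,
    settings: SimSettings,
    replicates: int = 4,
    seed: int = 0,
) -> pd.DataFrame:
    """Evolved trait means and performance metrics across policing costs.

    Runs the co-evolution protocol at each cost level ``c_inh`` (cost per
    unit of inhibitor produced, paid by the host through its growth rate).
    The founder defaults sensibly to an evolved maximal-CNC genotype so
    each cost level measures the relaxed evolved state rather than the
    transient from a naive founder.
    """
    rows = []
    for j, ci in enumerate(np.asarray(c_inh_values, dtype=float)):
        p_cost = dc_replace(p, c_inh=float(ci))
        res = coevolution(founder, p_cost, ev, settings,
                          replicates=replicates, seed=seed + 7919 * j)
        ep = res["endpoint"]
        for _, row in ep.iterrows():
            rows.append({
                "c_inh": float(ci),
                "cost_ratio": float(ci) / p.c if p.c > 0 else math.nan,
                "replicate": int(row["replicate"]),
                "mean_alpha": row["mean_alpha"],
                "mean_kappa": row["mean_kappa"],
                "mean_beta": row["mean_beta"],
                "division_rate": row["division_rate"],
                "seg_loss_rate": row["seg_loss_rate"],
                "infected_fraction": row["infected_fraction"],
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# CNC vs NO-CNC comparison
# ---------------------------------------------------------------------------

def cnc_vs_nocnc(
    founder_alpha: float,
    p: CellParams,
    ev: EvolutionParams,
    settings: SimSettings,
    replicates: int = 10,
    seed: int = 0,
    arms: tuple[tuple[str, tuple[str, ...], PlasmidGenotype | None], ...] | None = None,
) -> pd.DataFrame:
    """Paired-seed comparison of evolving arms.

    The default arms are the baseline model (only selfishness evolves,
    kappa=beta=0) and the full model (all three traits evolve).  Each arm
    is a ``(name, free_traits, founder)`` triple; a ``None`` founder means
    the naive ``(founder_alpha, 0, 0)`` genotype.  Both arms use the same
    replicate seed list.  Returns one row per (arm, replicate) with
    post-burn-in division rate, death rate, segregational-loss rate and
    infected fraction.
    """
    if arms is None:
        arms = (("NO-CNC", ("alpha",), None),
                ("CNC", ("alpha", "kappa", "beta"), None))
    naive = PlasmidGenotype(founder_alpha, 0.0, 0.0)
    rows = []
    for arm_name, free, founder in arms:
        ev_arm = dc_replace(ev, free=tuple(free))
        res = coevolution(founder or naive, p, ev_arm, settings,
                          replicates=replicates, seed=seed)
        ep = res["endpoint"]
        for _, row in ep.iterrows():
            rows.append({
                "arm": arm_name,
                "replicate": int(row["replicate"]),
                "division_rate": row["division_rate"],
                "death_rate": row["death_rate"],
                "seg_loss_rate": row["seg_loss_rate"],
                "infected_fraction": row["infected_fraction"],
                "mean_alpha": row["mean_alpha"],
                "mean_kappa": row["mean_kappa"],
                "mean_beta": row["mean_beta"],
            })
    return pd.DataFrame(rows)


def compare_arms(df: pd.DataFrame, arm_hi: str = "CNC",
                 arm_lo: str = "NO-CNC") -> pd.DataFrame:
    """One-sided rank-sum tests on replicate-level means, per metric.

    Expected directions: division rate and infected fraction higher in
    ``arm_hi``; death rate and segregational-loss rate lower.  Replicate
    means (not pooled time points) avoid autocorrelation
    pseudo-replication.
    """
    directions = {
        "division_rate": "greater",
        "infected_fraction": "greater",
        "death_rate": "less",
        "seg_loss_rate": "less",
    }
    out = []
    for metric, alternative in directions.items():
        x = df.loc[df["arm"] == arm_hi, metric].dropna()
        y = df.loc[df["arm"] == arm_lo, metric].dropna()
        stat, pval = stats.mannwhitneyu(x, y, alternative=alternative)
        out.append({"metric": metric, "alternative": alternative,
                    "U": float(stat), "p_value": float(pval),
                    f"median_{arm_hi}": float(x.median()),
                    f"median_{arm_lo}": float(y.median())})
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# invasion
# ---------------------------------------------------------------------------

def _mixed_population(resident, invader, mixing, settings, p, rng):
    n_cells = settings.cap // 2
    n = settings.n_init
    if mixing == "within-host":
        n_res = n // 2
        per_cell = np.concatenate([
            np.tile(resident.as_array(), (n_res, 1)),
            np.tile(invader.as_array(), (n - n_res, 1)),
        ])
        traits = np.tile(per_cell, (n_cells, 1))
        labels = np.tile(
            np.concatenate([np.zeros(n_res, dtype=np.int64),
                            np.ones(n - n_res, dtype=np.int64)]), n_cells)
        cell_of = np.repeat(np.arange(n_cells, dtype=np.int64), n)
    elif mixing == "between-host":
        half = n_cells // 2
        traits = np.concatenate([
            np.tile(resident.as_array(), (half * n, 1)),
            np.tile(invader.as_array(), ((n_cells - half) * n, 1)),
        ])
        labels = np.concatenate([
            np.zeros(half * n, dtype=np.int64),
            np.ones((n_cells - half) * n, dtype=np.int64),
        ])
        cell_of = np.repeat(np.arange(n_cells, dtype=np.int64), n)
    else:
        raise ValueError(f"unknown mixing scheme {mixing!r}")
    u = rng.random(n_cells)
    M = p.M0 * 2.0 / (2.0 - u)
    return Population(M=M, traits=traits, cell_of=cell_of, rng=rng,
                      labels=labels)


def invasion(
    resident: PlasmidGenotype,
    invader: PlasmidGenotype,
    mixing: str,
    p: CellParams,
    settings: SimSettings,
    replicates: int = 20,
    seed: int = 0,
    check_every: int = 20,
) -> pd.DataFrame:
    """Competition between two fixed plasmid types (no mutation).

    ``mixing='within-host'`` seeds every host with an equal mix of both
    types; ``'between-host'`` seeds half the hosts with each type.  A
    replicate ends when one type's plasmid copies are gone (fixation of
    the other), when all plasmids are gone, when the host population goes
    extinct, or at the step horizon (coexistence).  Returns one row per
    replicate with the outcome, the time, and the final invader frequency.
    """
    rngs = spawn_seeds(seed, replicates)
    rows = []
    for r in range(replicates):
        pop = _mixed_population(resident, invader, mixing, settings, p,
                                rngs[r])
        outcome, t_fix = "coexistence", math.nan
        freq = math.nan
        k = 0
        while k < settings.steps:
            chunk = min(check_every, settings.steps - k)
            extinct = advance_population(pop, p, None, settings.cap, chunk)
            k += chunk
            if extinct:
                outcome, t_fix = "extinct", pop.t
                break
            by = np.bincount(pop.labels, minlength=2)
            if by.sum() == 0:
                outcome, t_fix = "plasmid-free", pop.t
                break
            if by[0] == 0:
                outcome, t_fix = "invader", pop.t
                break
            if by[1] == 0:
                outcome, t_fix = "resident", pop.t
                break
        if pop.n_plasmids:
            by = np.bincount(pop.labels, minlength=2)
            freq = float(by[1] / by.sum())
        elif outcome == "invader":
            freq = 1.0
        elif outcome == "resident":
            freq = 0.0
        rows.append({"replicate": r, "mixing": mixing, "outcome": outcome,
                     "t_end": pop.t if math.isnan(t_fix) else t_fix,
                     "invader_freq": freq})
    return pd.DataFrame(rows)
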