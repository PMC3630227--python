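"""Compiled inner loop of the stochastic engine.

The numba kernel advances the flat population state by a chunk of time
steps with exactly the same update rule and ordering as the pure-numpy
reference path in :mod:`plasmidpol.stochastic` (grow -> replicate/mutate
-> deaths -> divisions -> neutral cap regulation), maintaining the event
counters and, optionally, the pooled copy-number histogram.  The two
paths use different random streams, so they agree distributionally, not
bitwise; each is bit-reproducible under its own seed.

The kernel works in place on preallocated arrays; on plasmid-capacity
overflow it rolls the current step back and returns so the caller can
grow the buffers and resume deterministically.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore
        def wrap(f):
            return f

        return wrap if not (args and callable(args[0])) else args[0]


STATUS_OK = 0
STATUS_EXTINCT = 1
STATUS_OVERFLOW = 2

HIST_BINS = 4096


@njit(cache=True)
def _seed_kernel(seed):  # pragma: no cover - trivial
    np.random.seed(seed)


@njit(cache=True)
def _remove_cells(M, traits, cell_of, labels, nc, npl, remove):
    """Drop marked cells; compact cells fully, plasmids by swap-fill.

    ``remove`` is a boolean mask over the first ``nc`` cells.  Kept cells
    keep their relative order; plasmid row order is NOT preserved (rows
    from the tail fill the holes), which is immaterial to the dynamics.
    """
    remap = np.empty(nc, np.int64)
    w = 0
    for c in range(nc):
        if remove[c]:
            remap[c] = -1
        else:
            remap[c] = w
            M[w] = M[c]
            w += 1
    holes = np.empty(npl, np.int64)
    nh = 0
    for i in range(npl):
        r = remap[cell_of[i]]
        if r < 0:
            holes[nh] = i
            nh += 1
        else:
            cell_of[i] = r
    for j in range(nh - 1, -1, -1):  # descending hole index
        h = holes[j]
        npl -= 1
        if h != npl:
            cell_of[h] = cell_of[npl]
            labels[h] = labels[npl]
            traits[h, 0] = traits[npl, 0]
            traits[h, 1] = traits[npl, 1]
            traits[h, 2] = traits[npl, 2]
    return w, npl


@njit(cache=True)
def _advance(
    M, traits, cell_of, labels, nc, npl,
    n_steps,
    g0, B, steep, cost, c_inh, M0, tau, dt, hyperbolic,
    mu, mstep, bounds, free_idx,
    cap, death_floor,
    counters, hist, hist_on, stats,
):
    two_m0 = 2.0 * M0
    nfree = free_idx.shape[0]
    plcap = traits.shape[0]
    for s in range(n_steps):
        if nc == 0:
            return nc, npl, s, STATUS_EXTINCT
        stats[0] += nc * dt  # cell-time integral, denominator of event rates
        # --- per-cell copy numbers and inhibitor production
        counts = np.zeros(nc, np.int64)
        ksum = np.zeros(nc, np.float64)
        for i in range(npl):
            c = cell_of[i]
            counts[c] += 1
            ksum[c] += traits[i, 1]
        if hist_on:
            for c in range(nc):
                k = counts[c]
                if k > 0:
                    if k >= HIST_BINS:
                        k = HIST_BINS - 1
                    hist[k] += 1
        # --- growth
        gfac = np.empty(nc, np.float64)
        for c in range(nc):
            n = counts[c]
            g = g0 + B * (1.0 - np.exp(-steep * n)) - cost * n \
                - c_inh * ksum[c]
            gfac[c] = 1.0 + g * dt
            M[c] *= gfac[c]
        # --- replication: one Poisson draw of the summed rate, events
        # assigned to plasmids by rate-weighted sampling (distributionally
        # identical to independent per-plasmid Poisson draws)
        Ic = np.empty(nc, np.float64)
        for c in range(nc):
            Ic[c] = tau * ksum[c] / M[c] if M[c] > 0.0 else 1.0e300
        cum = np.empty(npl + 1, np.float64)
        cum[0] = 0.0
        for i in range(npl):
            x = traits[i, 2] * Ic[cell_of[i]]
            h = 1.0 / (1.0 + x) if hyperbolic else np.exp(-x)
            cum[i + 1] = cum[i] + traits[i, 0] * h * dt
        total_lam = cum[npl]
        tot = np.random.poisson(total_lam) if total_lam > 0.0 else 0
        if npl + tot > plcap:
            for c in range(nc):  # roll the step back; retry after realloc
                M[c] /= gfac[c]
            stats[0] -= nc * dt
            return nc, npl, s, STATUS_OVERFLOW
        npl0 = npl
        for _ in range(tot):
            u = np.random.random() * total_lam
            lo, hi = 0, npl0
            while hi - lo > 1:  # find i with cum[i] <= u < cum[i+1]
                mid = (lo + hi) // 2
                if cum[mid] <= u:
                    lo = mid
                else:
                    hi = mid
            i = lo
            cell_of[npl] = cell_of[i]
            labels[npl] = labels[i]
            traits[npl, 0] = traits[i, 0]
            traits[npl, 1] = traits[i, 1]
            traits[npl, 2] = traits[i, 2]
            if mu > 0.0 and np.random.random() < mu:
                t = free_idx[np.random.randint(0, nfree)]
                d = (2.0 * np.random.random() - 1.0) * mstep * bounds[t]
                v = traits[npl, t] + d
                if v < 0.0:
                    v = 0.0
                elif v > bounds[t]:
                    v = bounds[t]
                traits[npl, t] = v
            npl += 1
        # --- deaths
        floor = death_floor * M0
        dead = np.empty(nc, np.bool_)
        ndead = 0
        for c in range(nc):
            dead[c] = M[c] < floor
            if dead[c]:
                ndead += 1
        if ndead > 0:
            nc, npl = _remove_cells(M, traits, cell_of, labels, nc, npl, dead)
            counters[1] += ndead
            if nc == 0:
                return nc, npl, s + 1, STATUS_EXTINCT
        # --- divisions with binomial segregation
        idx_map = np.full(nc, -1, np.int64)
        ndiv = 0
        for c in range(nc):
            if M[c] >= two_m0:
                idx_map[c] = nc + ndiv
                ndiv += 1
        if ndiv > 0:
            counters[0] += ndiv
            counts2 = np.zeros(nc, np.int64)
            stayc = np.zeros(nc, np.int64)
            goc = np.zeros(nc, np.int64)
            for i in range(npl):
                c = cell_of[i]
                counts2[c] += 1
                if idx_map[c] >= 0:
                    if np.random.randint(0, 2) == 1:
                        cell_of[i] = idx_map[c]
                        goc[c] += 1
                    else:
                        stayc[c] += 1
            for c in range(nc):
                if idx_map[c] >= 0:
                    if counts2[c] > 0:
                        counters[3] += 1
                        if stayc[c] == 0 or goc[c] == 0:
                            counters[2] += 1
                    M[c] *= 0.5
                    M[idx_map[c]] = M[c]
            nc += ndiv
        # --- neutral regulation down to cap
        if nc > cap:
            ncull = nc - cap
            # uniform sample of ncull cells to remove (partial Fisher-Yates)
            idxs = np.arange(nc)
            for j in range(ncull):
                pick = j + np.random.randint(0, nc - j)
                tmp = idxs[j]
                idxs[j] = idxs[pick]
                idxs[pick] = tmp
            cull = np.zeros(nc, np.bool_)
            for j in range(ncull):
                cull[idxs[j]] = True
            nc, npl = _remove_cells(M, traits, cell_of, labels, nc, npl, cull)
    return nc, npl, n_steps, STATUS_OK


class EngineState:
    """Preallocated buffers wrapping a flat population for the kernel."""

    def __init__(self, pop, p, cap, seed: int):
        self.p = p
        self.cap = cap
        mcap = 2 * cap + 8
        npl = pop.n_plasmids
        plcap = max(4 * npl + 1024, 8 * cap)
        self.M = np.zeros(mcap)
        self.M[: pop.n_cells] = pop.M
        self.traits = np.zeros((plcap, 3))
        self.traits[:npl] = pop.traits
        self.cell_of = np.zeros(plcap, dtype=np.int64)
        self.cell_of[:npl] = pop.cell_of
        self.labels = np.zeros(plcap, dtype=np.int64)
        if pop.labels is not None:
            self.labels[:npl] = pop.labels
        self.nc = pop.n_cells
        self.npl = npl
        self.counters = np.zeros(4, dtype=np.int64)
        self.counters[:] = (pop.counters.divisions, pop.counters.deaths,
                            pop.counters.seg_losses,
                            pop.counters.infected_divisions)
        self.hist = np.zeros(HIST_BINS, dtype=np.int64)
        self.stats = np.zeros(1)  # [0]: accumulated cell-time
        _seed_kernel(seed)

    def _grow_buffers(self) -> None:
        plcap = 2 * self.traits.shape[0]
        for name in ("traits", "cell_of", "labels"):
            old = getattr(self, name)
            shape = (plcap, 3) if old.ndim == 2 else (plcap,)
            new = np.zeros(shape, dtype=old.dtype)
            new[: self.npl] = old[: self.npl]
            setattr(self, name, new)

    def advance(self, n_steps: int, ev, hist_on: bool) -> tuple[int, bool]:
        """Run ``n_steps`` steps; returns (steps_done, extinct)."""
        p = self.p
        if ev is not None and ev.mu > 0.0:
            mu, mstep = ev.mu, ev.step
            bounds = ev.bounds.as_array()
            free_idx = ev.free_indices
        else:
            mu, mstep = 0.0, 1.0
            bounds = np.ones(3)
            free_idx = np.zeros(1, dtype=np.int64)
        from .stochastic import DEATH_FLOOR_FRACTION

        done = 0
        while done < n_steps:
            self.nc, self.npl, d, status = _advance(
                self.M, self.traits, self.cell_of, self.labels,
                self.nc, self.npl, n_steps - done,
                p.g0, p.B, p.steepness, p.c, p.c_inh, p.M0, p.tau, p.dt,
                True,
                mu, mstep, bounds, free_idx,
                self.cap, DEATH_FLOOR_FRACTION,
                self.counters, self.hist, hist_on, self.stats,
            )
            done += d
            if status == STATUS_OVERFLOW:
                self._grow_buffers()
                continue
            if status == STATUS_EXTINCT:
                return done, True
            break
        return done, False

    def sync(self, pop) -> None:
        """Write kernel state back into a Population object."""
        pop.M = self.M[: self.nc].copy()
        pop.traits = self.traits[: self.npl].copy()
        pop.cell_of = self.cell_of[: self.npl].copy()
        pop.labels = self.labels[: self.npl].copy()
        pop.counters.divisions = int(self.counters[0])
        pop.counters.deaths = int(self.counters[1])
        pop.counters.seg_losses = int(self.counters[2])
        pop.counters.infected_divisions = int(self.counters[3])
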