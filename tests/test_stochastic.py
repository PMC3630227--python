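"""Unit tests for the stochastic multicellular engine."""

import math
from dataclasses import replace

import numpy as np
import pytest

from plasmidpol.model_core import (
    CellParams,
    EvolutionParams,
    HostCell,
    PlasmidGenotype,
    TraitBounds,
)
from plasmidpol.stochastic import (
    Population,
    divide_cell,
    mutate,
    regulate_population,
    run_simulation,
    step,
    step_cell,
    variance_decomposition,
)


class TestStepCell:
    def test_plasmid_free_geometric_growth(self, p, rng):
        """Biomass doubles after ceil(ln2 / (g0 dt)) steps of pure growth."""
        cell = HostCell(p.M0, [])
        steps = 0
        while True:
            cell, events = step_cell(cell, p, None, rng)
            steps += 1
            if events["divide"]:
                break
        assert steps == math.ceil(math.log(2) / (p.g0 * p.dt))

    def test_no_mutation_copies_parent_exactly(self, p, rng):
        g = PlasmidGenotype(0.08, 0.01, 0.2)
        cell = HostCell(p.M0, [g] * 10)
        for _ in range(50):
            cell, _ = step_cell(cell, p, None, rng)
        assert cell.n > 10  # some replication happened
        assert all(pl == g for pl in cell.plasmids)

    def test_poisson_replication_mean(self, p, rng):
        """Mean replications per plasmid per step match r*dt (Monte Carlo)."""
        alpha = 0.05
        n_cells, n_per = 1000, 100  # 1e5 plasmid-steps
        pop = Population.homogeneous(n_cells, n_per,
                                     PlasmidGenotype(alpha), p, seed=rng)
        before = pop.n_plasmids
        step(pop, p, None)
        events = pop.n_plasmids - before
        lam = before * alpha * p.dt
        assert abs(events - lam) < 3 * math.sqrt(lam)


class TestDivideCell:
    def test_plasmid_free_parent(self, rng):
        d1, d2, losses = divide_cell(HostCell(2.0, []), rng)
        assert d1.n == d2.n == 0 and losses == 0
        assert d1.biomass == d2.biomass == 1.0

    def test_copy_number_and_biomass_conserved(self, rng):
        parent = HostCell(2.2, [PlasmidGenotype(0.03)] * 17)
        for _ in range(200):
            d1, d2, _ = divide_cell(parent, rng)
            assert d1.n + d2.n == 17
            assert d1.biomass + d2.biomass == pytest.approx(2.2)

    def test_segregational_loss_probability_closed_form(self, rng):
        """P(plasmid-free daughter | n=5) = 2 * (1/2)^5, Monte Carlo check."""
        n, reps = 5, 20000
        parent = HostCell(2.0, [PlasmidGenotype(0.03)] * n)
        losses = sum(divide_cell(parent, rng)[2] for _ in range(reps))
        p_loss = 2 * 0.5**n
        se = math.sqrt(p_loss * (1 - p_loss) / reps)
        assert abs(losses / reps - p_loss) < 3 * se


class TestMutate:
    def test_exactly_one_trait_changes(self, ev, rng):
        g = PlasmidGenotype(0.05, 0.02, 0.5)
        for _ in range(200):
            m = mutate(g, ev, rng)
            changed = [a != b for a, b in zip(g.as_array(), m.as_array())]
            assert sum(changed) <= 1  # zero only if the draw hit the clip

    def test_trait_choice_is_uniform(self, ev, rng):
        g = PlasmidGenotype(0.05, 0.02, 0.5)
        reps = 30000
        counts = np.zeros(3)
        for _ in range(reps):
            m = mutate(g, ev, rng)
            diff = m.as_array() != g.as_array()
            if diff.any():
                counts[np.argmax(diff)] += 1
        se = math.sqrt((1 / 3) * (2 / 3) / reps)
        for c in counts:
            assert abs(c / reps - 1 / 3) < 3 * se

    def test_bounds_respected_at_saturation(self, rng):
        ev = EvolutionParams(step=0.5)
        g = PlasmidGenotype(0.1, 0.05, 1.0)  # every trait at its bound
        for _ in range(300):
            m = mutate(g, ev, rng)
            ev.bounds.validate(m)

    def test_frozen_trait_never_mutates(self, rng):
        ev = EvolutionParams(free=("alpha", "beta"))
        g = PlasmidGenotype(0.05, 0.02, 0.5)
        assert all(mutate(g, ev, rng).kappa == g.kappa for _ in range(500))


class TestRegulation:
    def test_below_cap_unchanged(self, p, rng):
        pop = Population.homogeneous(50, 3, PlasmidGenotype(0.03), p, seed=rng)
        M_before = pop.M.copy()
        regulate_population(pop, 100)
        assert np.array_equal(pop.M, M_before)

    def test_culling_is_selection_neutral(self, p):
        """Two neutral labelled halves stay at 50:50 on average under the
        cap, with hypergeometric drift variance."""
        reps, n0, cap = 400, 200, 100
        fracs = []
        for s in range(reps):
            pop = Population.homogeneous(n0, 1, PlasmidGenotype(0.03), p,
                                         seed=s)
            pop.labels[: n0 // 2] = 1
            regulate_population(pop, cap)
            fracs.append(pop.labels.mean())
        fracs = np.asarray(fracs)
        # hypergeometric sampling of cap from n0 with K=n0/2 successes
        var = (cap * 0.5 * 0.5 * (n0 - cap) / (n0 - 1)) / cap**2
        assert abs(fracs.mean() - 0.5) < 4 * math.sqrt(var / reps)
        assert 0.5 * var < fracs.var() < 2.0 * var

    def test_cap_one_keeps_single_lineage(self, p, rng):
        pop = Population.homogeneous(10, 2, PlasmidGenotype(0.03), p, seed=rng)
        regulate_population(pop, 1)
        assert pop.n_cells == 1
        assert set(pop.cell_of) <= {0}


class TestEngineInvariants:
    def test_plasmid_count_conserved_without_replication(self, p, rng):
        """With alpha=0 and no deaths, divisions only redistribute copies."""
        pop = Population.homogeneous(64, 9, PlasmidGenotype(0.0, 0.02, 0.5),
                                     p, seed=rng)
        for _ in range(300):
            step(pop, p, None)
            assert pop.n_plasmids == 64 * 9

    def test_biomass_conserved_at_division(self, p, rng):
        pop = Population.homogeneous(1, 5, PlasmidGenotype(0.0), p, seed=rng,
                                     stagger=False)
        pop.M[:] = 1.999
        from plasmidpol.model_core import growth_rate

        g = growth_rate(5, 0.0, p)
        step(pop, p, None)
        assert pop.n_cells == 2
        assert pop.M.sum() == pytest.approx(1.999 * (1 + g * p.dt))
        assert pop.M[0] == pop.M[1]

    def test_seg_losses_bounded_by_infected_divisions(self, p, rng):
        pop = Population.homogeneous(100, 2, PlasmidGenotype(0.04), p,
                                     seed=rng)
        for _ in range(2000):
            step(pop, p, None)
            regulate_population(pop, 100)
        c = pop.counters
        assert 0 < c.seg_losses <= c.infected_divisions <= c.divisions

    @pytest.mark.parametrize("engine", ["numpy", "numba"])
    def test_seeded_runs_are_bit_reproducible(self, p, cnc_genotype, engine):
        outs = []
        for _ in range(2):
            pop = Population.homogeneous(60, 8, cnc_genotype, p, seed=7)
            obs = run_simulation(pop, p, None, cap=60, steps=800,
                                 record_every=200, engine=engine)
            c = obs.population.counters
            outs.append((c.divisions, c.deaths, c.seg_losses,
                         c.infected_divisions,
                         obs.population.M.sum(), obs.population.n_plasmids))
        assert outs[0] == outs[1]

    def test_mutation_free_run_keeps_traits_exactly(self, p, cnc_genotype):
        pop = Population.homogeneous(50, 8, cnc_genotype, p, seed=3)
        obs = run_simulation(pop, p, None, cap=50, steps=1500,
                             record_every=500)
        assert np.all(obs.population.traits == cnc_genotype.as_array())
        means = obs.frame[["mean_alpha", "mean_kappa", "mean_beta"]]
        assert np.allclose(means, cnc_genotype.as_array(), atol=0)

    def test_engines_agree_statistically(self, p, cnc_genotype):
        """numpy and compiled paths sample the same stationary process."""
        means = {}
        for engine in ("numpy", "numba"):
            pop = Population.homogeneous(150, 8, cnc_genotype, p, seed=11)
            obs = run_simulation(pop, p, None, cap=150, steps=2500,
                                 record_every=250, hist_start=1000,
                                 engine=engine)
            means[engine] = obs.hist_moments()["mean"]
        assert means["numpy"] == pytest.approx(means["numba"], rel=0.05)

    def test_extinction_truncates_series(self, p):
        pop = Population.homogeneous(30, 16, PlasmidGenotype(0.1), p, seed=5)
        obs = run_simulation(pop, p, None, cap=30, steps=50000,
                             record_every=100)
        assert obs.terminated
        assert obs.population.n_cells == 0


class TestVarianceDecomposition:
    def test_identical_plasmids_give_zero_everywhere(self, p, rng):
        pop = Population.homogeneous(20, 5, PlasmidGenotype(0.05, 0.01, 0.5),
                                     p, seed=rng)
        vd = variance_decomposition(pop)
        assert np.allclose(vd.to_numpy(), 0.0, atol=1e-12)

    def test_two_host_classes_between_only(self, p, rng):
        cells = [HostCell(1.0, [PlasmidGenotype(0.02)] * 4)] * 10 + \
                [HostCell(1.0, [PlasmidGenotype(0.08)] * 4)] * 10
        pop = Population.from_cells(cells, seed=rng)
        vd = variance_decomposition(pop)
        assert vd.loc["alpha", "within"] == 0.0
        assert vd.loc["alpha", "between"] == pytest.approx(0.03)

    def test_matches_direct_two_level_computation(self, p, rng):
        pop = Population.homogeneous(30, 6, PlasmidGenotype(0.05, 0.02, 0.5),
                                     p, seed=rng)
        pop.traits += rng.normal(0, 0.003, size=pop.traits.shape)
        pop.traits = np.clip(pop.traits, 0, None)
        vd = variance_decomposition(pop)
        # independent oracle: explicit per-host loop
        for j, name in enumerate(("alpha", "kappa", "beta")):
            host_means, host_sds = [], []
            for c in range(pop.n_cells):
                vals = pop.traits[pop.cell_of == c, j]
                if vals.size:
                    host_means.append(vals.mean())
                    host_sds.append(vals.std())
            assert vd.loc[name, "within"] == pytest.approx(np.mean(host_sds))
            assert vd.loc[name, "between"] == pytest.approx(np.std(host_means))

    def test_undefined_without_infected_hosts(self, p, rng):
        pop = Population.homogeneous(10, 0, PlasmidGenotype(0.03), p, seed=rng)
        with pytest.raises(ValueError, match="no infected host"):
            variance_decomposition(pop)
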