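"""Unit tests for the deterministic single-cell layer."""

import math

import numpy as np
import pytest
from scipy.optimize import newton

from plasmidpol.deterministic import (
    cell_fitness,
    death_boundary,
    edge_of_stability,
    equilibrium_mean_copy_number,
    find_equilibria,
    generation_map,
    integrate_cell_cycle,
    plasmid_free_fitness,
)
from plasmidpol.model_core import PlasmidGenotype


class TestCellCycle:
    def test_plasmid_free_closed_form(self, p):
        """A plasmid-free cell divides after exactly ln2/g0."""
        res = integrate_cell_cycle(0.0, PlasmidGenotype(0.05), p)
        assert res.outcome == "divides"
        assert res.T_div == pytest.approx(math.log(2) / p.g0, rel=1e-8)
        assert res.n_division == 0.0

    def test_frozen_plasmids_keep_their_copy_number(self, p):
        res = integrate_cell_cycle(7.0, PlasmidGenotype(0.0, 0.01, 0.5), p)
        assert res.outcome == "divides"
        assert res.n_division == pytest.approx(7.0, rel=1e-9)

    @pytest.mark.parametrize("genotype", [
        PlasmidGenotype(0.03, 0.0, 0.0),
        PlasmidGenotype(0.06, 0.05, 1.0),
        PlasmidGenotype(0.02, 0.02, 0.4),
    ])
    def test_adaptive_agrees_with_euler_refinement(self, p, genotype):
        """Fixed-step Euler at small dt converges to the adaptive result."""
        ad = integrate_cell_cycle(6.0, genotype, p)
        eu = integrate_cell_cycle(6.0, genotype, p, method="euler",
                                  euler_dt=2e-3)
        assert ad.outcome == eu.outcome == "divides"
        assert eu.T_div == pytest.approx(ad.T_div, rel=1e-3)
        assert eu.n_division == pytest.approx(ad.n_division, rel=1e-3)

    def test_runaway_replication_kills_the_cell(self, p):
        res = integrate_cell_cycle(40.0, PlasmidGenotype(0.09), p)
        assert res.outcome == "dies"

    def test_negative_initial_copy_number_rejected(self, p):
        with pytest.raises(ValueError):
            integrate_cell_cycle(-1.0, PlasmidGenotype(0.03), p)


class TestGenerationMap:
    def test_fixed_point_maps_to_itself(self, p, nocnc_genotype):
        eqs = find_equilibria(nocnc_genotype, p)
        for eq in eqs:
            assert generation_map(eq.n_star, nocnc_genotype, p) == \
                pytest.approx(eq.n_star, abs=1e-6)

    def test_consistent_under_replication_stays_below_diagonal(self, p):
        low = PlasmidGenotype(0.006)
        for n0 in np.linspace(0.5, 30, 8):
            assert generation_map(n0, low, p) < n0

    def test_map_undefined_where_cell_dies(self, p):
        assert math.isnan(generation_map(45.0, PlasmidGenotype(0.09), p))

    def test_map_agrees_with_tighter_tolerance_integration(self, p,
                                                           cnc_genotype):
        for n0 in (3.0, 9.0, 15.0):
            coarse = generation_map(n0, cnc_genotype, p)
            fine = integrate_cell_cycle(n0, cnc_genotype, p,
                                        rtol=1e-9, atol=1e-11).n_division / 2
            assert coarse == pytest.approx(fine, rel=1e-6)


class TestEquilibria:
    def test_mid_stability_genotype_has_stable_and_unstable_root(self, p,
                                                                 nocnc_genotype):
        eqs = find_equilibria(nocnc_genotype, p)
        assert len(eqs.stable) == 1 and len(eqs.unstable) == 1
        n_s = eqs.stable[0].n_star
        n_u = eqs.unstable[0].n_star
        assert n_s < n_u
        assert abs(eqs.stable[0].slope) < 1 < eqs.unstable[0].slope

    def test_sign_structure_around_stable_root(self, p, nocnc_genotype):
        """Below the characteristic copy number plasmids over-replicate,
        above it they under-replicate."""
        n_s = find_equilibria(nocnc_genotype, p).stable[0].n_star
        assert generation_map(0.9 * n_s, nocnc_genotype, p) > 0.9 * n_s
        assert generation_map(1.1 * n_s, nocnc_genotype, p) < 1.1 * n_s

    def test_under_replicating_genotype_has_no_roots(self, p):
        assert len(find_equilibria(PlasmidGenotype(0.006), p)) == 0

    def test_roots_match_independent_newton_refinement(self, p,
                                                       nocnc_genotype):
        for eq in find_equilibria(nocnc_genotype, p):
            refined = newton(
                lambda n: generation_map(n, nocnc_genotype, p) - n,
                eq.n_star * 1.001, tol=1e-10)
            assert refined == pytest.approx(eq.n_star, abs=1e-6)

    def test_policing_obedience_exchange_symmetry(self, p):
        """Homogeneous dynamics depend only on the beta*kappa product."""
        a = find_equilibria(PlasmidGenotype(0.05, 0.04, 0.8), p)
        b = find_equilibria(PlasmidGenotype(0.05, 0.8, 0.04), p)
        assert len(a) == len(b)
        for ea, eb in zip(a, b):
            assert ea.n_star == pytest.approx(eb.n_star, rel=1e-6)
            assert ea.stable == eb.stable
            assert ea.T_div == pytest.approx(eb.T_div, rel=1e-6)


class TestFitness:
    def test_plasmid_free_reference(self, p):
        assert plasmid_free_fitness(p) == pytest.approx(p.g0 / math.log(2))

    def test_undefined_without_stable_equilibrium(self, p):
        assert math.isnan(cell_fitness(PlasmidGenotype(0.006), p))

    def test_continuous_in_alpha_within_stable_region(self, p):
        fits = [cell_fitness(PlasmidGenotype(a, 0.05, 1.0), p)
                for a in (0.058, 0.06, 0.062)]
        assert np.all(np.isfinite(fits))
        assert max(abs(np.diff(fits))) < 0.05 * fits[1]

    def test_snapshot_mean_exceeds_cycle_start_value(self, p, cnc_genotype):
        """Asynchronous snapshot mean is ~2 ln2 times the cycle-start copy
        number (copy number doubles over the cycle)."""
        eqs = find_equilibria(cnc_genotype, p)
        n_star = eqs.stable[0].n_star
        mean = equilibrium_mean_copy_number(cnc_genotype, p, eqs)
        assert mean == pytest.approx(2 * math.log(2) * n_star, rel=0.02)


@pytest.fixture(scope="module")
def nocnc_edge():
    from plasmidpol.model_core import CellParams

    return edge_of_stability(0.0, 0.0, CellParams(), (0.015, 0.06))


class TestEdgeOfStability:
    def test_fold_defining_property(self, p, nocnc_edge):
        """Two fixed points just below the critical alpha, none just above."""
        ac = nocnc_edge.alpha_crit
        below = find_equilibria(PlasmidGenotype(ac * 0.98), p)
        above = find_equilibria(PlasmidGenotype(ac * 1.02), p)
        assert len(below) == 2
        assert len(above) == 0

    def test_tangency_slope_is_one(self, nocnc_edge):
        assert nocnc_edge.mode == "fold"
        assert nocnc_edge.slope_at_fold == pytest.approx(1.0, abs=1e-3)

    def test_no_fold_in_range_is_diagnosed(self, p):
        with pytest.raises(ValueError, match="no fold"):
            edge_of_stability(0.0, 0.0, p, (0.001, 0.008))


def test_death_boundary_is_where_growth_vanishes(p):
    from plasmidpol.model_core import growth_rate

    g = PlasmidGenotype(0.05, 0.05, 1.0)
    nb = death_boundary(g, p)
    assert growth_rate(nb, nb * g.kappa, p) == pytest.approx(0.0, abs=1e-10)
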