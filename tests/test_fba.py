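import numpy as np
import pytest

from gemkit.fba import (
    add_demand,
    finite_difference_check,
    flux_variability,
    producibility,
    solve_fba,
    stoichiometric_matrix,
    zero_flux_reactions,
)
from gemkit.gem_core import Metabolite, Reaction
from gemkit.model_io import MediumDefinition, apply_medium
from gemkit.synth import random_toy_model, toy1
from .conftest import to_cobra


def assert_solution_consistent(model, sol, tol_residual=1e-6, tol_bounds=1e-9):
    """Steady state and bound feasibility of a reported optimum."""
    S, met_ids, rxn_ids = stoichiometric_matrix(model)
    v = np.array([sol.fluxes[r] for r in rxn_ids])
    assert np.max(np.abs(S @ v)) <= tol_residual
    lb = np.array([r.lower_bound for r in model.reactions])
    ub = np.array([r.upper_bound for r in model.reactions])
    assert np.all(v >= lb - tol_bounds) and np.all(v <= ub + tol_bounds)


class TestSolveFba:
    def test_toy1_growth_capped_by_uptake(self, toy1_model):
        sol = solve_fba(toy1_model)
        assert sol.status == "optimal"
        assert sol.objective == pytest.approx(10.0, abs=1e-9)
        assert_solution_consistent(toy1_model, sol)

    def test_closed_exchanges_give_zero_growth(self, toy1_model):
        closed = apply_medium(toy1_model, MediumDefinition(bounds={}))
        assert solve_fba(closed).objective == pytest.approx(0.0, abs=1e-9)

    def test_unbounded_detected(self, toy1_model):
        m = toy1_model.copy()
        m.reaction("EX_A").lower_bound = -np.inf
        for rid in ("T_A", "R1", "GROWTH"):
            m.reaction(rid).upper_bound = np.inf
        assert solve_fba(m).status == "unbounded"

    def test_min_direction(self, toy1_model):
        assert solve_fba(toy1_model, direction="min").objective == pytest.approx(0.0)

    def test_unknown_objective_raises(self, toy1_model):
        with pytest.raises(KeyError):
            solve_fba(toy1_model, objective="nope")

    def test_matches_independent_solver_on_many_random_models(self, rng):
        for _ in range(100):
            m = random_toy_model(rng)
            ours = solve_fba(m)
            ref = to_cobra(m).optimize()
            assert ours.status == "optimal" and ref.status == "optimal"
            assert ours.objective == pytest.approx(ref.objective_value, abs=1e-6)
            assert_solution_consistent(m, ours)

    def test_strong_duality(self, rng):
        # at the optimum, the objective equals the value implied by the
        # duals: sum over bounds of rc * bound (equality rows contribute 0)
        for _ in range(25):
            m = random_toy_model(rng)
            sol = solve_fba(m)
            dual_obj = 0.0
            for r in m.reactions:
                rc = sol.reduced_costs[r.id]
                if rc > 0:
                    dual_obj += rc * r.upper_bound
                elif rc < 0:
                    dual_obj += rc * r.lower_bound
            assert dual_obj == pytest.approx(sol.objective, abs=1e-6)


class TestFva:
    def test_unique_path_pins_flux_at_full_growth(self, toy1_model):
        assert flux_variability(toy1_model, ["T_A"], 1.0)["T_A"] == pytest.approx((10.0, 10.0))

    def test_dead_end_reaction_is_pinned_to_zero(self, toy1_model):
        m = toy1_model.copy()
        m.metabolites.append(Metabolite("D_c", "", "c"))
        m.reactions.append(Reaction("R_dead", "", {"B_c": -1.0, "D_c": 1.0}, 0, 1000))
        assert flux_variability(m, ["R_dead"], 0.0)["R_dead"] == pytest.approx((0.0, 0.0))

    def test_internal_2cycle_spans_full_bounds_at_fraction_zero(self, toy1_model):
        m = toy1_model.copy()
        m.metabolites.append(Metabolite("D_c", "", "c"))
        m.metabolites.append(Metabolite("E_c", "", "c"))
        m.reactions.append(Reaction("C1", "", {"D_c": -1.0, "E_c": 1.0}, -1000, 1000))
        m.reactions.append(Reaction("C2", "", {"E_c": -1.0, "D_c": 1.0}, -1000, 1000))
        assert flux_variability(m, ["C1"], 0.0)["C1"] == pytest.approx((-1000.0, 1000.0))

    def test_intervals_shrink_monotonically_with_fraction(self, rng):
        for _ in range(10):
            m = random_toy_model(rng)
            lo_f = flux_variability(m, growth_fraction=0.3)
            hi_f = flux_variability(m, growth_fraction=0.9)
            for rid in m.reaction_ids:
                assert lo_f[rid][0] <= hi_f[rid][0] + 1e-7
                assert lo_f[rid][1] >= hi_f[rid][1] - 1e-7

    def test_feasible_fba_flux_lies_within_fva_interval(self, rng):
        m = random_toy_model(rng)
        sol = solve_fba(m)
        fva = flux_variability(m, growth_fraction=1.0)
        for rid, flux in sol.fluxes.items():
            lo, hi = fva[rid]
            assert lo - 1e-6 <= flux <= hi + 1e-6


class TestZeroFlux:
    def test_disconnected_reaction_always_zero(self, toy1_model):
        m = toy1_model.copy()
        m.metabolites += [Metabolite("D_c", "", "c"), Metabolite("E_c", "", "c")]
        m.reactions.append(Reaction("R_dead", "", {"D_c": -1.0, "E_c": 1.0}, 0, 1000))
        for fraction in (0.0, 0.5, 1.0):
            assert "R_dead" in zero_flux_reactions(m, fraction)

    def test_open_toy1_has_no_zero_flux_at_fraction_zero(self, toy1_model):
        assert zero_flux_reactions(toy1_model, 0.0) == set()

    def test_closed_medium_forces_all_reactions_to_zero(self, toy1_model):
        closed = apply_medium(toy1_model, MediumDefinition(bounds={}))
        assert zero_flux_reactions(closed, 0.0) == set(closed.reaction_ids)

    def test_superset_of_structurally_blocked(self, rng):
        for _ in range(5):
            m = random_toy_model(rng)
            blocked = zero_flux_reactions(m, 0.0)  # blocked at no growth demand
            assert blocked <= zero_flux_reactions(m, 0.9)


class TestDemandAndProducibility:
    def test_add_demand_idempotent(self, toy1_model):
        m1, d1 = add_demand(toy1_model, "B_c")
        m2, d2 = add_demand(m1, "B_c")
        assert d1 == d2 == "DM_B_c"
        assert len(m2.reactions) == len(m1.reactions)

    def test_add_demand_leaves_original_untouched(self, toy1_model):
        n = len(toy1_model.reactions)
        add_demand(toy1_model, "B_c")
        assert len(toy1_model.reactions) == n

    def test_unknown_metabolite_raises(self, toy1_model):
        with pytest.raises(KeyError):
            add_demand(toy1_model, "nope")

    def test_producible_metabolite(self, toy1_model):
        flux, ok = producibility(toy1_model, "B_c")
        assert ok and flux == pytest.approx(10.0)

    def test_removing_only_producer_blocks(self, toy1_model):
        m = toy1_model.copy()
        m.reactions = [r for r in m.reactions if r.id != "R1"]
        flux, ok = producibility(m, "B_c")
        assert not ok and flux == pytest.approx(0.0, abs=1e-9)

    def test_extracellular_production_bounded_by_exchange(self, toy1_model):
        m = toy1_model.copy()
        m.reaction("EX_A").upper_bound = 4.0
        # A_e can only be (re)drawn from uptake; demand competes with nothing
        flux, ok = producibility(m, "A_e")
        assert ok and flux == pytest.approx(10.0)


class TestReducedCosts:
    def test_binding_uptake_bound_has_unit_reduced_cost(self, toy1_model):
        rc, slope = finite_difference_check(toy1_model, "GROWTH", "EX_A", delta=1.0)
        assert abs(rc) == pytest.approx(1.0)
        assert slope == pytest.approx(1.0)

    def test_non_binding_bound_has_zero_reduced_cost(self, toy1_model):
        m = toy1_model.copy()
        m.reaction("T_A").upper_bound = 500.0  # far from binding
        sol = solve_fba(m)
        assert sol.reduced_costs["T_A"] == pytest.approx(0.0, abs=1e-9)

    def test_large_delta_crossing_a_basis_change_underestimates(self, toy1_model):
        m = toy1_model.copy()
        m.reaction("T_A").upper_bound = 12.0  # second bottleneck at 12
        rc, slope = finite_difference_check(m, "GROWTH", "EX_A", delta=10.0)
        # after 2 units of relaxation the transporter binds instead
        assert abs(rc) == pytest.approx(1.0)
        assert slope == pytest.approx(0.2)
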