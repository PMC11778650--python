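import numpy as np
import pytest

from sulfurflux.core import MetabolicModel, Metabolite, Reaction
from sulfurflux.fba import (
    FBAError,
    duality_gap,
    finite_difference_price,
    price_subgradient_interval,
    reduced_costs,
    shadow_prices,
    solve_fba,
)

from conftest import chain_model, random_small_model
from oracles import enumerate_vertices_objective


class TestPrimal:
    def test_chain_growth_equals_uptake_bound(self):
        res = solve_fba(chain_model())
        assert res.status == "optimal"
        assert res.objective_value == pytest.approx(1.0, abs=1e-9)

    def test_stoichiometric_doubling(self):
        res = solve_fba(chain_model(expand=2.0))
        assert res.objective_value == pytest.approx(2.0, abs=1e-9)

    def test_infeasible_reported_not_zeroed(self):
        m = chain_model()
        # force the biomass drain to run faster than uptake allows
        m.set_bounds("BIO", 5.0, 10.0)
        res = solve_fba(m, check_orientation=False)
        assert res.status == "infeasible"
        assert res.objective_value is None

    def test_unbounded_reported(self):
        m = MetabolicModel(
            metabolites=[Metabolite(id="A[c]")],
            reactions=[
                Reaction(id="in", stoichiometry={"A[c]": 1},
                         lower_bound=-np.inf, upper_bound=np.inf),
                Reaction(id="out", stoichiometry={"A[c]": -1},
                         lower_bound=-np.inf, upper_bound=np.inf),
            ])
        res = solve_fba(m, objective="out", check_orientation=False)
        assert res.status == "unbounded"

    def test_missing_objective_errors(self):
        with pytest.raises(FBAError):
            solve_fba(chain_model(), objective="nope")

    def test_solution_satisfies_mass_balance_and_bounds(self, toy):
        res = solve_fba(toy)
        S = toy.stoichiometric_matrix()
        v = np.array([res.fluxes[r.id] for r in toy.reactions])
        assert np.abs(S @ v).max() < 1e-6
        lb, ub = toy.bounds_arrays()
        assert np.all(v >= lb - 1e-9) and np.all(v <= ub + 1e-9)
        j = [r.id for r in toy.reactions].index(toy.objective)
        assert res.objective_value == pytest.approx(v[j], abs=1e-12)

    def test_matches_vertex_enumeration_on_random_models(self):
        # independent oracle: brute-force enumeration of basic solutions
        rng = np.random.default_rng(2024)
        checked = 0
        while checked < 50:
            model, objective = random_small_model(rng)
            res = solve_fba(model, objective, check_orientation=False)
            if res.status != "optimal":
                continue
            S = model.stoichiometric_matrix().toarray()
            lb, ub = model.bounds_arrays()
            c = np.zeros(len(model.reactions))
            c[model._rxn_index[objective]] = 1.0
            oracle = enumerate_vertices_objective(S, lb, ub, c, sense="max")
            assert oracle is not None
            assert res.objective_value == pytest.approx(oracle, abs=1e-6)
            checked += 1


class TestDuals:
    def test_chain_shadow_price_is_minus_one(self):
        # each unit of B diverted to a sink costs one unit of growth;
        # finite-difference oracle agrees
        m = chain_model()
        prices = shadow_prices(m)
        assert prices["B[c]"] == pytest.approx(-1.0, abs=1e-9)
        fd = finite_difference_price(m, "B[c]", objective="BIO", eps=1e-5)
        assert fd == pytest.approx(-1.0, abs=1e-6)

    def test_free_valve_metabolite_has_zero_price(self):
        m = chain_model()
        # C is produced as a byproduct and freely secreted: no objective role
        m.metabolites.append(Metabolite(id="C[c]"))
        m._reindex()
        m.reaction("R1").stoichiometry["C[c]"] = 1.0
        m.add_reaction(Reaction(id="EX_C", stoichiometry={"C[c]": -1},
                                lower_bound=0, upper_bound=1000,
                                kind="exchange"))
        prices = shadow_prices(m)
        assert prices["C[c]"] == pytest.approx(0.0, abs=1e-9)

    def test_chain_reduced_cost_of_uptake_bound(self):
        rc = reduced_costs(chain_model())
        # relaxing the uptake bound by one unit raises growth by one
        assert rc["EX_A"] == pytest.approx(-1.0, abs=1e-9)
        assert rc["R1"] == pytest.approx(0.0, abs=1e-9)   # interior

    def test_strong_duality_on_random_models(self):
        rng = np.random.default_rng(11)
        checked = 0
        while checked < 25:
            model, objective = random_small_model(rng)
            try:
                gap = duality_gap(model, objective)
            except FBAError:
                continue
            assert gap < 1e-7
            checked += 1

    def test_strong_duality_on_toy(self, toy, toy_dbt):
        assert duality_gap(toy) < 1e-7
        assert duality_gap(toy_dbt) < 1e-7

    def test_prices_match_finite_differences_when_nondegenerate(self):
        rng = np.random.default_rng(5)
        checked = 0
        while checked < 20:
            model, objective = random_small_model(rng)
            res = solve_fba(model, objective, check_orientation=False)
            if res.status != "optimal":
                continue
            met = model.metabolites[int(rng.integers(len(model.metabolites)))].id
            left, right = price_subgradient_interval(model, met, objective)
            if left is None or right is None or abs(left - right) > 1e-6:
                continue   # degenerate: dual lies in the subgradient interval
            assert res.shadow_prices[met] == pytest.approx(right, abs=1e-5)
            checked += 1

    def test_reduced_costs_match_bound_finite_differences(self, toy):
        res = solve_fba(toy)
        eps = 1e-5
        for rid in ["EX_glc", "EX_so4", "GLK", "RESP"]:
            r = toy.reaction(rid)
            v = res.fluxes[rid]
            probe = toy.copy()
            if abs(v - r.lower_bound) < 1e-8:
                probe.set_bounds(rid, r.lower_bound - eps, r.upper_bound)
                fd = (solve_fba(probe, check_orientation=False).objective_value
                      - res.objective_value) / (-eps)
            elif abs(v - r.upper_bound) < 1e-8:
                probe.set_bounds(rid, r.lower_bound, r.upper_bound + eps)
                fd = (solve_fba(probe, check_orientation=False).objective_value
                      - res.objective_value) / eps
            else:
                fd = 0.0
            assert res.reduced_costs[rid] == pytest.approx(fd, abs=1e-5)

    def test_row_scaling_rescales_price_inversely(self):
        # doubling a metabolite's row (all its coefficients) halves its
        # price and leaves the optimum unchanged
        base = chain_model()
        prices0 = shadow_prices(base)
        z0 = solve_fba(base).objective_value
        scaled = chain_model()
        for r in scaled.reactions:
            if "B[c]" in r.stoichiometry:
                r.stoichiometry["B[c]"] *= 2.0
        z1 = solve_fba(scaled).objective_value
        prices1 = shadow_prices(scaled)
        assert z1 == pytest.approx(z0, abs=1e-9)
        assert prices1["B[c]"] == pytest.approx(prices0["B[c]"] / 2, abs=1e-9)


class TestFourSPattern:
    def test_linear_chain_price_progression(self, toy_dbt):
        # uniform per-step flavin cost makes intermediate prices integer
        # multiples of the first oxidation's price, and the end product's
        # price equal and opposite
        sp = shadow_prices(toy_dbt)
        p = sp["dbto[c]"]
        assert p < 0
        assert sp["dbto2[c]"] == pytest.approx(2 * p, abs=1e-6)
        assert sp["hbps[c]"] == pytest.approx(3 * p, abs=1e-6)
        assert sp["hbp[c]"] == pytest.approx(-p, abs=1e-6)
        # sulfite carries the full chain cost plus the end-product disposal
        assert sp["slf[c]"] == pytest.approx(4 * p, abs=1e-6)

    def test_pattern_follows_flavin_cost_config(self):
        from sulfurflux.synth import ToyModelConfig, build_desulfurization_toy

        m = build_desulfurization_toy(ToyModelConfig(fmnh2_per_step=2.0))
        m.set_bounds("EX_so4", 0, 1000)
        m.set_bounds("EX_h2s", 0, 1000)
        m.set_bounds("EX_dbt", -10, 0)
        sp = shadow_prices(m)
        p = sp["dbto[c]"]
        assert sp["dbto2[c]"] == pytest.approx(2 * p, abs=1e-6)
        assert sp["hbps[c]"] == pytest.approx(3 * p, abs=1e-6)

    def test_orientation_probe_agrees_on_toy(self, toy_dbt):
        # the probe runs inside solve_fba; a sign flip would raise
        res = solve_fba(toy_dbt, check_orientation=True)
        assert res.optimal
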