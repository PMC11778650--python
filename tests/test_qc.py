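import numpy as np
import pytest

from sulfurflux.core import MetabolicModel, Metabolite, Reaction
from sulfurflux.fba import solve_fba
from sulfurflux.qc import (
    GapFillError,
    balance_model,
    check_balance,
    connectivity_profile,
    find_dead_ends,
    gap_fill,
)

from conftest import chain_model, random_small_model
from oracles import dead_ends_brute


def mets(*specs):
    return {m.id: m for m in (Metabolite(**s) for s in specs)}


class TestBalance:
    def test_isomerization_balanced(self):
        lookup = mets({"id": "A[c]", "formula": "C6H12O6", "charge": 0},
                      {"id": "B[c]", "formula": "C6H12O6", "charge": 0})
        r = Reaction(id="r", stoichiometry={"A[c]": -1, "B[c]": 1})
        report = check_balance(r, lookup)
        assert report.verdict == "balanced"
        assert report.element_delta == {}
        assert report.charge_delta == 0

    def test_carbon_loss_detected(self):
        lookup = mets({"id": "A[c]", "formula": "C6H12O6", "charge": 0},
                      {"id": "B[c]", "formula": "C5H10O5", "charge": 0})
        r = Reaction(id="r", stoichiometry={"A[c]": -1, "B[c]": 1})
        report = check_balance(r, lookup)
        assert report.verdict == "imbalanced"
        assert report.element_delta == {"C": -1, "H": -2, "O": -1}

    def test_atp_hydrolysis_with_charges(self):
        # charged species bookkeeping: ATP^4- + H2O -> ADP^3- + HPO4^2- + H+
        lookup = mets(
            {"id": "atp[c]", "formula": "C10H12N5O13P3", "charge": -4},
            {"id": "h2o[c]", "formula": "H2O", "charge": 0},
            {"id": "adp[c]", "formula": "C10H12N5O10P2", "charge": -3},
            {"id": "pi[c]", "formula": "HO4P", "charge": -2},
            {"id": "h[c]", "formula": "H", "charge": 1},
        )
        r = Reaction(id="ATPase", stoichiometry={
            "atp[c]": -1, "h2o[c]": -1, "adp[c]": 1, "pi[c]": 1, "h[c]": 1})
        report = check_balance(r, lookup)
        assert report.verdict == "balanced"

    def test_missing_formula_is_unverifiable_not_balanced(self):
        lookup = mets({"id": "A[c]", "formula": "C6H12O6", "charge": 0},
                      {"id": "B[c]"})
        r = Reaction(id="r", stoichiometry={"A[c]": -1, "B[c]": 1})
        report = check_balance(r, lookup)
        assert report.verdict == "unverifiable"
        assert "B[c]" in report.reason

    def test_exempt_kinds_rejected(self):
        lookup = mets({"id": "A[c]", "formula": "C6H12O6", "charge": 0})
        ex = Reaction(id="EX", stoichiometry={"A[c]": -1}, kind="exchange")
        with pytest.raises(ValueError):
            check_balance(ex, lookup)

    @pytest.mark.parametrize("scale", [0.5, 2.0, 7.3])
    def test_verdict_invariant_under_scaling(self, toy, scale):
        lookup = {m.id: m for m in toy.metabolites}
        for r in toy.reactions:
            if r.kind in ("exchange", "biomass"):
                continue
            scaled = Reaction(
                id=r.id, kind=r.kind,
                stoichiometry={k: scale * v for k, v in r.stoichiometry.items()})
            assert check_balance(scaled, lookup).verdict == \
                check_balance(r, lookup).verdict

    def test_toy_is_fully_balanced(self, toy):
        reports = balance_model(toy)
        assert reports and all(r.verdict == "balanced" for r in reports)


class TestConnectivity:
    def chain3(self):
        return MetabolicModel(
            metabolites=[Metabolite(id=x) for x in ("A[c]", "B[c]", "C[c]")],
            reactions=[
                Reaction(id="r1", stoichiometry={"A[c]": -1, "B[c]": 1}),
                Reaction(id="r2", stoichiometry={"B[c]": -1, "C[c]": 1}),
            ])

    def test_chain_profile(self):
        prof = connectivity_profile(self.chain3())
        # A and C touch one reaction, B touches two
        assert prof.degree_counts == {1: 2, 2: 1}
        assert prof.total_connected == 3

    def test_empty_model(self):
        prof = connectivity_profile(MetabolicModel())
        assert prof.degree_counts == {}

    def test_counts_sum_to_connected_metabolites(self, toy):
        prof = connectivity_profile(toy)
        connected = {m for r in toy.reactions if r.kind == "metabolic"
                     for m in r.stoichiometry}
        assert prof.total_connected == len(connected)

    def test_widening_scope_never_decreases_degree(self, toy):
        narrow = connectivity_profile(toy, scope=("metabolic",))
        wide = connectivity_profile(
            toy, scope=("metabolic", "transport", "exchange", "biomass"))
        # compare per-metabolite degrees, not the histograms
        def degrees(scope):
            out = {}
            for r in toy.reactions:
                if r.kind in scope:
                    for m in r.stoichiometry:
                        out[m] = out.get(m, 0) + 1
            return out
        dn = degrees(("metabolic",))
        dw = degrees(("metabolic", "transport", "exchange", "biomass"))
        assert all(dw[m] >= d for m, d in dn.items())
        assert wide.total_connected >= narrow.total_connected


class TestDeadEnds:
    def test_unconsumed_product_is_dead(self):
        m = MetabolicModel(
            metabolites=[Metabolite(id="A[c]"), Metabolite(id="B[c]")],
            reactions=[
                Reaction(id="EX_A", stoichiometry={"A[c]": -1},
                         lower_bound=-1, upper_bound=0, kind="exchange"),
                Reaction(id="r", stoichiometry={"A[c]": -1, "B[c]": 1}),
            ])
        assert find_dead_ends(m) == ["B[c]"]

    def test_exchange_rescues_dead_end(self):
        m = MetabolicModel(
            metabolites=[Metabolite(id="A[c]"), Metabolite(id="B[c]")],
            reactions=[
                Reaction(id="EX_A", stoichiometry={"A[c]": -1},
                         lower_bound=-1, upper_bound=0, kind="exchange"),
                Reaction(id="r", stoichiometry={"A[c]": -1, "B[c]": 1}),
                Reaction(id="EX_B", stoichiometry={"B[c]": -1},
                         lower_bound=0, upper_bound=1000, kind="exchange"),
            ])
        assert find_dead_ends(m) == []

    def test_reversible_counts_both_ways(self):
        m = MetabolicModel(
            metabolites=[Metabolite(id="A[c]"), Metabolite(id="B[c]")],
            reactions=[Reaction(id="r", stoichiometry={"A[c]": -1, "B[c]": 1},
                                lower_bound=-1000, upper_bound=1000)])
        assert find_dead_ends(m) == []

    def test_matches_brute_force_on_random_models(self):
        rng = np.random.default_rng(33)
        for _ in range(20):
            model, _ = random_small_model(rng, n_rxns=8)
            lb, ub = model.bounds_arrays()
            oracle = dead_ends_brute(model.stoichiometric_matrix(), lb, ub,
                                     [m.id for m in model.metabolites])
            assert find_dead_ends(model) == oracle

    def test_toy_has_no_dead_ends(self, toy):
        assert find_dead_ends(toy) == []


def make_gap_model():
    """A->B->C->biomass chain with the middle reactions removable."""
    mets = [Metabolite(id=x) for x in ("A[c]", "B[c]", "C[c]")]
    rxns = [
        Reaction(id="EX_A", stoichiometry={"A[c]": -1},
                 lower_bound=-10, upper_bound=1000, kind="exchange"),
        Reaction(id="r1", stoichiometry={"A[c]": -1, "B[c]": 1}),
        Reaction(id="r2", stoichiometry={"B[c]": -1, "C[c]": 1}),
        Reaction(id="BIO", stoichiometry={"C[c]": -1}, kind="biomass"),
    ]
    return MetabolicModel(metabolites=mets, reactions=rxns, genes=[],
                          objective="BIO").validate()


class TestGapFill:
    def test_single_missing_reaction_recovered(self):
        m = make_gap_model()
        missing = m.reaction("r2")
        m.set_bounds("r2", 0, 0)
        pool = [Reaction(id="u_good", stoichiometry=dict(missing.stoichiometry)),
                Reaction(id="u_junk", stoichiometry={"A[c]": -1, "B[c]": 2})]
        assert gap_fill(m, pool, min_growth=1.0) == ["u_good"]

    def test_already_growing_returns_empty(self):
        assert gap_fill(make_gap_model(), [], min_growth=1.0) == []

    def test_unfillable_raises(self):
        m = make_gap_model()
        m.set_bounds("r2", 0, 0)
        pool = [Reaction(id="u_junk", stoichiometry={"A[c]": -1, "B[c]": 1})]
        with pytest.raises(GapFillError):
            gap_fill(m, pool, min_growth=1.0)

    def test_cardinality_matches_exhaustive_search(self):
        # two chain links missing, pool of six; brute-force over all
        # subsets up to size 3 gives the certified minimum
        from itertools import combinations

        m = make_gap_model()
        m.set_bounds("r1", 0, 0)
        m.set_bounds("r2", 0, 0)
        pool = [
            Reaction(id="u1", stoichiometry={"A[c]": -1, "B[c]": 1}),
            Reaction(id="u2", stoichiometry={"B[c]": -1, "C[c]": 1}),
            Reaction(id="u3", stoichiometry={"C[c]": -1, "B[c]": 1}),
            Reaction(id="u4", stoichiometry={"B[c]": -1, "A[c]": 1}),
            Reaction(id="u5", stoichiometry={"A[c]": -2, "C[c]": 1}),
            Reaction(id="u6", stoichiometry={"C[c]": -1, "A[c]": 1}),
        ]
        chosen = gap_fill(m, pool, min_growth=1.0)

        def grows(subset):
            trial = m.copy()
            for r in subset:
                trial.add_reaction(Reaction(id=r.id,
                                            stoichiometry=dict(r.stoichiometry)))
            res = solve_fba(trial, check_orientation=False)
            return res.optimal and res.objective_value >= 1.0 - 1e-9

        exhaustive_min = None
        for k in range(0, 4):
            if any(grows(sub) for sub in combinations(pool, k)):
                exhaustive_min = k
                break
        assert exhaustive_min is not None
        assert len(chosen) == exhaustive_min

    def test_solution_verified_by_resolve(self):
        m = make_gap_model()
        m.set_bounds("r2", 0, 0)
        missing = Reaction(id="u_good", stoichiometry={"B[c]": -1, "C[c]": 1})
        chosen = gap_fill(m, [missing], min_growth=2.0)
        augmented = m.copy()
        augmented.add_reaction(missing)
        res = solve_fba(augmented, check_orientation=False)
        assert chosen == ["u_good"]
        assert res.objective_value >= 2.0 - 1e-9
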