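from itertools import combinations

import numpy as np
import pytest

from sulfurflux.core import (
    MetabolicModel,
    Metabolite,
    Reaction,
    parse_gpr,
    rich_medium,
)
from sulfurflux.essentiality import (
    ConfusionMatrix,
    EssentialityCall,
    OrthologMap,
    evaluate_gpr,
    knockout_reactions,
    single_gene_deletion,
    validate_against_reference,
)
from sulfurflux.fba import FBAError, solve_fba

from oracles import gpr_truth_table


class TestGPREvaluation:
    def test_isozyme_rule_keeps_reaction_active(self):
        # a reaction controlled by two or more isozymes stays active in
        # the absence of any one associated gene
        rule = parse_gpr("(g1 and g2) or g3")
        assert evaluate_gpr(rule, {"g1"}) is True
        assert evaluate_gpr(rule, {"g1", "g3"}) is False

    def test_matches_truth_tables_for_all_deletion_subsets(self):
        rng = np.random.default_rng(17)
        genes = [f"g{i}" for i in range(8)]

        def random_rule(depth=0):
            if depth >= 2 or rng.random() < 0.4:
                return genes[rng.integers(len(genes))]
            op = "and" if rng.random() < 0.5 else "or"
            children = tuple(random_rule(depth + 1)
                             for _ in range(rng.integers(2, 4)))
            return (op, children)

        from sulfurflux.core import GeneProductRule

        for _ in range(15):
            rule = GeneProductRule(random_rule())
            used = sorted(rule.genes)
            for k in range(len(used) + 1):
                for deleted in combinations(used, k):
                    assert rule.evaluate(deleted) == \
                        gpr_truth_table(rule.expression, used, set(deleted))


def tiny_gene_model():
    """Two-route model: R1 (gene a) or R2 (isozymes b1/b2) feed biomass."""
    mets = [Metabolite(id="A[c]"), Metabolite(id="B[c]")]
    rxns = [
        Reaction(id="EX_A", stoichiometry={"A[c]": -1},
                 lower_bound=-1, upper_bound=1000, kind="exchange"),
        Reaction(id="R1", stoichiometry={"A[c]": -1, "B[c]": 1}, gpr="a"),
        Reaction(id="R2", stoichiometry={"A[c]": -1, "B[c]": 0.5},
                 gpr="b1 or b2"),
        Reaction(id="BIO", stoichiometry={"B[c]": -1}, kind="biomass"),
    ]
    return MetabolicModel(metabolites=mets, reactions=rxns,
                          genes=["a", "b1", "b2", "idle"],
                          objective="BIO").validate()


class TestSingleGeneDeletion:
    def test_sole_controller_of_only_route_is_essential(self):
        m = tiny_gene_model()
        m.set_bounds("R2", 0, 0)   # only R1 remains
        calls = {c.gene: c for c in single_gene_deletion(m)}
        assert calls["a"].essential
        assert calls["a"].knockout_growth == pytest.approx(0.0, abs=1e-9)

    def test_gene_absent_from_gprs_is_nonessential_ratio_one(self):
        calls = {c.gene: c for c in single_gene_deletion(tiny_gene_model())}
        assert not calls["idle"].essential
        assert calls["idle"].growth_ratio == pytest.approx(1.0, abs=1e-9)

    def test_isozymes_are_individually_nonessential(self):
        calls = {c.gene: c for c in single_gene_deletion(tiny_gene_model())}
        assert not calls["b1"].essential and not calls["b2"].essential

    def test_scan_equals_manual_per_gene_resolve(self, toy):
        # independent oracle: rebuild the knocked-out model explicitly and
        # re-solve, gene by gene
        from sulfurflux.core import apply_medium

        medium = rich_medium(toy)
        calls = {c.gene: c for c in single_gene_deletion(toy, medium=medium)}
        conditioned = apply_medium(toy, medium)
        rng = np.random.default_rng(3)
        sample = rng.choice(conditioned.genes, size=12, replace=False)
        for gene in sample:
            manual = conditioned.copy()
            for rid in knockout_reactions(manual, {gene}):
                manual.set_bounds(rid, 0.0, 0.0)
            res = solve_fba(manual, check_orientation=False)
            growth = res.objective_value if res.optimal else 0.0
            assert calls[gene].knockout_growth == pytest.approx(
                growth, abs=1e-8)

    def test_deletion_never_increases_growth(self, toy):
        for c in single_gene_deletion(toy):
            assert c.knockout_growth <= c.wild_type_growth + 1e-9

    def test_order_independence(self, toy):
        forward = single_gene_deletion(toy, genes=list(toy.genes))
        backward = single_gene_deletion(toy, genes=list(reversed(toy.genes)))
        fw = {c.gene: (c.knockout_growth, c.essential) for c in forward}
        bw = {c.gene: (c.knockout_growth, c.essential) for c in backward}
        assert fw == bw

    def test_dead_wild_type_errors(self):
        m = tiny_gene_model()
        medium = rich_medium(m)
        m.set_bounds("R1", 0, 0)
        m.set_bounds("R2", 0, 0)
        with pytest.raises(FBAError):
            single_gene_deletion(m, medium=medium)


def make_calls(classes):
    return [EssentialityCall(g, 1.0, 0.0 if c == "E" else 1.0, c == "E")
            for g, c in classes.items()]


class TestValidation:
    def test_published_style_counts_give_78_point_1(self):
        # counts (18, 105, 8, 931) over 1,215 shared genes: the four cells
        # sum to 1062, the remaining shared genes are unmatched, and
        # accuracy = 100*(18+931)/1215 = 78.1%
        cm = ConfusionMatrix(ee=18, en=105, ne=8, nn=931, n_shared=1215)
        assert f"{cm.accuracy:.1f}" == "78.1"

    def test_identical_call_sets_are_100_percent(self):
        calls = make_calls({f"g{i}": ("E" if i % 3 == 0 else "NE")
                            for i in range(30)})
        omap = OrthologMap(rows=[(c.gene, f"Y{c.gene}", 1e-30)
                                 for c in calls])
        reference = {f"Y{c.gene}": c.call for c in calls}
        cm = validate_against_reference(calls, omap, reference)
        assert cm.accuracy == 100.0
        assert cm.n_shared == 30

    def test_random_reference_matches_hand_tally(self):
        rng = np.random.default_rng(99)
        calls = make_calls({f"g{i}": ("E" if rng.random() < 0.2 else "NE")
                            for i in range(200)})
        omap = OrthologMap(rows=[(c.gene, f"Y{c.gene}", 1e-20) for c in calls])
        reference = {f"Y{c.gene}": ("E" if rng.random() < 0.2 else "NE")
                     for c in calls}
        cm = validate_against_reference(calls, omap, reference)
        agree = sum(1 for c in calls if reference[f"Y{c.gene}"] == c.call)
        assert cm.agreements == agree
        assert cm.accuracy == pytest.approx(100.0 * agree / 200)

    def test_evalue_filter_drops_weak_hits(self):
        calls = make_calls({"g1": "E", "g2": "NE"})
        omap = OrthologMap(rows=[("g1", "Y1", 1e-30), ("g2", "Y2", 1e-3)],
                           evalue_threshold=1e-6)
        cm = validate_against_reference(calls, omap, {"Y1": "E", "Y2": "NE"})
        assert cm.n_shared == 1

    def test_many_to_many_resolves_essential_if_any(self):
        calls = make_calls({"g1": "E"})
        omap = OrthologMap(rows=[("g1", "Ya", 1e-30), ("g1", "Yb", 1e-30)])
        cm = validate_against_reference(calls, omap, {"Ya": "NE", "Yb": "E"})
        assert cm.ee == 1

    def test_counts_plus_unmatched_account_for_every_shared_gene(self):
        calls = make_calls({"g1": "E", "g2": "NE", "g3": "NE"})
        omap = OrthologMap(rows=[("g1", "Y1", 1e-30), ("g2", "Y2", 1e-30),
                                 ("g3", "Ymissing", 1e-30)])
        cm = validate_against_reference(calls, omap, {"Y1": "E", "Y2": "NE"})
        assert cm.ee + cm.en + cm.ne + cm.nn + len(cm.unmatched) == cm.n_shared

    def test_empty_overlap_errors(self):
        calls = make_calls({"g1": "E"})
        omap = OrthologMap(rows=[("other", "Y", 1e-30)])
        with pytest.raises(ValueError):
            validate_against_reference(calls, omap, {"Y": "E"})
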