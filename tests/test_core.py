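"""Core domain types: GPR logic, stoichiometric matrix, model statistics."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gsmm.core import (
    GprExpression,
    GprParseError,
    MetabolicModel,
    Metabolite,
    ModelStructureError,
    Reaction,
    build_stoichiometric_matrix,
    evaluate_gpr,
    model_summary,
    orf_coverage,
)
from oracles import truth_table_gpr


def _tiny_model(gprs=("", "", "")):
    m = MetabolicModel(id="tiny")
    m.add_metabolite(Metabolite("A", compartment="c"))
    m.add_metabolite(Metabolite("B", compartment="c"))
    m.add_reaction(Reaction("R1", {"A": 1.0}, lower_bound=-10, upper_bound=10,
                            gpr=GprExpression.from_string(gprs[0])))
    m.add_reaction(Reaction("R2", {"A": -1.0, "B": 1.0},
                            gpr=GprExpression.from_string(gprs[1])))
    m.add_reaction(Reaction("R3", {"B": -1.0},
                            gpr=GprExpression.from_string(gprs[2])))
    return m


class TestGpr:
    @pytest.mark.parametrize(
        "text,deleted,expected",
        [
            ("g1 and g2", {"g1"}, False),
            ("g1 or g2", {"g1"}, True),
            ("g1 and (g2 or g3)", {"g2"}, True),
            ("g1 and (g2 or g3)", {"g2", "g3"}, False),
            ("", {"g1"}, True),  # empty GPR never removable
        ],
    )
    def test_evaluation(self, text, deleted, expected):
        assert evaluate_gpr(GprExpression.from_string(text), deleted) is expected

    def test_parse_structure(self):
        gpr = GprExpression.from_string("(g1 and (g2 or g3))")
        assert gpr.root[0] == "and"
        assert gpr.genes() == {"g1", "g2", "g3"}

    def test_and_binds_tighter_than_or(self):
        gpr = GprExpression.from_string("g1 or g2 and g3")
        # g1 alone must satisfy the expression
        assert gpr.evaluate({"g2", "g3"}) is True
        assert gpr.evaluate({"g1", "g3"}) is False

    def test_case_insensitive_operators(self):
        gpr = GprExpression.from_string("g1 AND g2 Or g3")
        assert gpr.evaluate({"g3"}) is True

    @pytest.mark.parametrize("bad", ["g1 and", "(g1 or g2", "and g1", "g1 g2"])
    def test_malformed_strings_raise(self, bad):
        with pytest.raises(GprParseError):
            GprExpression.from_string(bad)

    def test_four_leaf_tree_matches_truth_table_on_all_subsets(self):
        tree = ("or", [("and", ["g1", "g2"]), ("and", ["g3", "g4"])])
        gpr = GprExpression(tree)
        genes = ["g1", "g2", "g3", "g4"]
        for k in range(5):
            for subset in itertools.combinations(genes, k):
                deleted = set(subset)
                assert gpr.evaluate(deleted) == truth_table_gpr(tree, genes, deleted)

    @settings(derandomize=True, max_examples=200)
    @given(st.recursive(
        st.sampled_from(["g1", "g2", "g3", "g4", "g5"]),
        lambda inner: st.tuples(
            st.sampled_from(["and", "or"]),
            st.lists(inner, min_size=2, max_size=3),
        ).map(lambda t: (t[0], t[1])),
        max_leaves=5,
    ), st.sets(st.sampled_from(["g1", "g2", "g3", "g4", "g5"])))
    def test_random_trees_match_truth_table(self, tree, deleted):
        gpr = GprExpression(tree)
        assert gpr.evaluate(deleted) == truth_table_gpr(tree, list(gpr.genes()), deleted)

    def test_round_trip_through_string(self):
        text = "g1 and (g2 or (g3 and g4))"
        gpr = GprExpression.from_string(text)
        again = GprExpression.from_string(gpr.to_string())
        for k in range(5):
            for subset in itertools.combinations(["g1", "g2", "g3", "g4"], k):
                assert gpr.evaluate(set(subset)) == again.evaluate(set(subset))


class TestStoichiometricMatrix:
    def test_toy_chain_shape_and_nonzeros(self):
        m = _tiny_model()
        S = build_stoichiometric_matrix(m)
        assert S.shape == (2, 3)
        assert S.nnz == 4
        assert S[0, 0] == 1.0 and S[0, 1] == -1.0 and S[1, 1] == 1.0

    def test_nonzero_count_equals_sum_of_stoichiometry_sizes(self, toy_core):
        model, _ = toy_core
        S = build_stoichiometric_matrix(model)
        assert S.nnz == sum(len(r.stoichiometry) for r in model.reactions.values())

    def test_rebuild_from_matrix_is_bijective(self, toy_core):
        model, _ = toy_core
        S = build_stoichiometric_matrix(model).todok()
        mids = model.metabolite_ids()
        rids = model.reaction_ids()
        rebuilt = {rid: {} for rid in rids}
        for (i, j), coef in S.items():
            rebuilt[rids[j]][mids[i]] = coef
        for rid in rids:
            assert rebuilt[rid] == model.reactions[rid].stoichiometry

    def test_unknown_metabolite_is_structural_error_naming_reaction(self):
        m = _tiny_model()
        m.reactions["R2"].stoichiometry["ghost"] = 1.0
        with pytest.raises(ModelStructureError, match="R2"):
            build_stoichiometric_matrix(m)


class TestModelSummary:
    def test_orf_coverage_from_published_counts(self):
        assert orf_coverage(767, 5426) == 14.1

    def test_coverage_unavailable_without_orf_count(self):
        m = _tiny_model()
        assert model_summary(m).orf_coverage is None

    def test_all_empty_gprs_give_zero_gene_association(self):
        m = _tiny_model()
        assert model_summary(m).frac_gene_associated == 0.0

    def test_gene_associated_fraction_counts_nonempty_gprs(self):
        m = _tiny_model(gprs=("gA", "gA or gB", ""))
        stats = model_summary(m)
        assert stats.frac_gene_associated == pytest.approx(66.7)
        assert stats.n_genes == 2

    def test_counts_invariant_under_reaction_reordering(self, toy_core):
        model, _ = toy_core
        stats = model_summary(model)
        reordered = MetabolicModel(id="re", genome_orf_count=model.genome_orf_count)
        for met in model.metabolites.values():
            reordered.add_metabolite(met)
        for rid in sorted(model.reactions, reverse=True):
            reordered.add_reaction(model.reactions[rid])
        stats2 = model_summary(reordered)
        assert (stats.n_reactions, stats.n_genes, stats.frac_gene_associated) == (
            stats2.n_reactions, stats2.n_genes, stats2.frac_gene_associated
        )

    def test_exchange_reactions_touch_one_metabolite(self, toy_core):
        model, _ = toy_core
        for rxn in model.exchanges():
            assert len(rxn.stoichiometry) == 1

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ModelStructureError):
            Reaction("bad", {"A": -1.0}, lower_bound=5, upper_bound=-5)
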