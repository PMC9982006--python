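"""MUST/FORCE strain design: planted recovery, oracles, soundness."""

import itertools

import pytest

from gsmm.core import MetabolicModel, Metabolite, Reaction
from gsmm.fba import InfeasibleProblemError, fba
from gsmm.optforce import (
    DOWN,
    KNOCKOUT,
    UP,
    FluxSpaceSpec,
    force_set_search,
    must_sets,
    targets_to_genes,
)
from gsmm.synth import TestbedSpec, make_geosmin_testbed
from gsmm.synth import make_testbed_specs as companion_specs
from oracles import brute_force_fva


def _branch_model(drain_cap=6.0):
    """One source (fixed 10), a product sink and a competing drain."""
    m = MetabolicModel(id="branch")
    m.add_metabolite(Metabolite("A_c", compartment="c"))
    m.add_reaction(Reaction("SRC", {"A_c": 1.0}, lower_bound=10.0, upper_bound=10.0))
    m.add_reaction(Reaction("PROD", {"A_c": -1.0}, lower_bound=0.0))
    m.add_reaction(Reaction("DRAIN", {"A_c": -1.0}, lower_bound=0.0,
                            upper_bound=drain_cap))
    m.objective_reaction_id = "PROD"
    return m


class TestMustSets:
    def test_identical_specs_give_empty_sets(self, toy_core):
        model, _ = toy_core
        spec = FluxSpaceSpec("same", min_growth=1.0)
        sets = must_sets(model, spec, spec)
        assert not sets.all_targets()

    def test_testbed_recovers_planted_directions(self, testbed):
        model, _, key, wild, over = testbed
        found = must_sets(model, wild, over).reaction_ids()
        for rid, direction in key.directions.items():
            assert found.get(rid) == direction

    def test_sets_are_pairwise_disjoint(self, testbed):
        model, _, _, wild, over = testbed
        sets = must_sets(model, wild, over)
        ids = [t.reaction_id for t in sets.all_targets()]
        assert len(ids) == len(set(ids))

    def test_branch_toy_drain_must_decrease(self):
        """With wild-type production measured low, a product target at 80%
        of input forces the competing drain down; ranges verified against
        vertex enumeration."""
        m = _branch_model(drain_cap=6.0)
        wild = FluxSpaceSpec("wild", fixed_fluxes={"PROD": (0.0, 5.0)})
        over = FluxSpaceSpec("over", product_reaction_id="PROD",
                             min_product_flux=8.0)
        sets = must_sets(m, wild, over)
        assert "DRAIN" in {t.reaction_id for t in sets.must_l}
        (drain,) = [t for t in sets.must_l if t.reaction_id == "DRAIN"]
        # oracle: enumerate vertices of the wild space directly
        m.reactions["PROD"].upper_bound = 5.0
        bf_wild = brute_force_fva(m, fraction=0.0, objective_id="PROD")
        assert drain.wild_range == pytest.approx(bf_wild["DRAIN"], abs=1e-6)
        assert drain.wild_range == pytest.approx((5.0, 6.0), abs=1e-6)
        assert drain.over_range == pytest.approx((0.0, 2.0), abs=1e-6)

    def test_shrinking_product_target_shrinks_must_sets(self, testbed):
        model, _, key, wild, over = testbed
        big = must_sets(model, wild, over)
        smaller = FluxSpaceSpec(
            name="over_small",
            medium=over.medium,
            fixed_fluxes=over.fixed_fluxes,
            product_reaction_id=over.product_reaction_id,
            min_product_flux=0.3 * over.min_product_flux,
        )
        small = must_sets(model, wild, smaller)
        big_ids = {t.reaction_id for t in big.all_targets()}
        small_ids = {t.reaction_id for t in small.all_targets()}
        assert small_ids <= big_ids

    def test_unreachable_product_target_names_the_maximum(self, testbed):
        model, _, key, wild, over = testbed
        impossible = FluxSpaceSpec(
            name="impossible",
            medium=over.medium,
            fixed_fluxes=over.fixed_fluxes,
            product_reaction_id=over.product_reaction_id,
            min_product_flux=1e6,
        )
        with pytest.raises(InfeasibleProblemError, match="theoretical maximum"):
            must_sets(model, wild, impossible)


class TestForceSearch:
    def test_single_knockout_suffices_on_testbed(self, testbed):
        model, medium, key, wild, over = testbed
        sets = must_sets(model, wild, over)
        base = FluxSpaceSpec(
            "engineering", medium=medium,
            fixed_fluxes=wild.fixed_fluxes, min_growth=1.0,
        )
        prod_max = over.min_product_flux
        res = force_set_search(
            model, sets, base, key.product_exchange_id, 0.5 * prod_max,
            max_interventions=2,
        )
        assert res.success
        assert res.achieved_min_product >= 0.5 * prod_max - 1e-6
        chosen = {t.reaction_id for t in res.intervention_sets[0]}
        assert "NUO" in chosen  # the planted energy-supply knockout

    def test_zero_interventions_rejected(self, testbed):
        model, medium, key, wild, over = testbed
        sets = must_sets(model, wild, over)
        with pytest.raises(ValueError):
            force_set_search(model, sets, wild, key.product_exchange_id, 1.0, 0)

    def test_greedy_agrees_with_exhaustive_on_two_drain_toy(self):
        """Both partial-capacity drains must be tightened; greedy's pick
        matches the best exhaustive <=2-subset."""
        m = MetabolicModel(id="twodrain")
        m.add_metabolite(Metabolite("A_c", compartment="c"))
        m.add_reaction(Reaction("SRC", {"A_c": 1.0}, lower_bound=10.0,
                                upper_bound=10.0))
        m.add_reaction(Reaction("PROD", {"A_c": -1.0}, lower_bound=0.0))
        m.add_reaction(Reaction("D1", {"A_c": -1.0}, lower_bound=0.0,
                                upper_bound=6.0))
        m.add_reaction(Reaction("D2", {"A_c": -1.0}, lower_bound=0.0,
                                upper_bound=6.0))
        m.objective_reaction_id = "PROD"
        # wild production measured at <= 3, so each drain carries >= 1
        wild = FluxSpaceSpec("wild", fixed_fluxes={"PROD": (0.0, 3.0)})
        over = FluxSpaceSpec("over", product_reaction_id="PROD",
                             min_product_flux=9.5)
        sets = must_sets(m, wild, over)
        assert {t.reaction_id for t in sets.must_l} >= {"D1", "D2"}
        base = FluxSpaceSpec("engineering")
        res = force_set_search(m, sets, base, "PROD", 8.0, max_interventions=2)
        assert res.success
        chosen = {t.reaction_id for t in res.intervention_sets[0]}
        assert chosen == {"D1", "D2"}

        # exhaustive oracle over all <=2-subsets of candidates
        def min_prod(subset):
            snapshot = m.snapshot_bounds()
            try:
                base.apply(m)
                for t in subset:
                    r = m.reactions[t.reaction_id]
                    if t.direction == DOWN:
                        r.upper_bound = min(r.upper_bound, t.wild_range[0])
                    elif t.direction == UP:
                        r.lower_bound = max(r.lower_bound, t.wild_range[1])
                    else:
                        r.lower_bound = r.upper_bound = 0.0
                sol = fba(m, "PROD", direction="min")
                return sol.objective_value if sol.optimal else float("-inf")
            finally:
                m.restore_bounds(snapshot)

        cands = sets.all_targets()
        feasible_subsets = [
            s
            for k in (1, 2)
            for s in itertools.combinations(cands, k)
            if min_prod(s) >= 8.0 - 1e-6
        ]
        assert {frozenset(t.reaction_id for t in s) for s in feasible_subsets} == {
            frozenset({"D1", "D2"})
        }

    def test_soundness_reverified_by_resolve(self, testbed):
        model, medium, key, wild, over = testbed
        sets = must_sets(model, wild, over)
        base = FluxSpaceSpec("engineering", medium=medium,
                             fixed_fluxes=wild.fixed_fluxes, min_growth=1.0)
        target = 0.5 * over.min_product_flux
        res = force_set_search(model, sets, base, key.product_exchange_id,
                               target, max_interventions=3)
        assert res.success
        snapshot = model.snapshot_bounds()
        try:
            base.apply(model)
            for t in res.intervention_sets[0]:
                r = model.reactions[t.reaction_id]
                if t.direction == UP:
                    r.lower_bound = max(r.lower_bound, t.wild_range[1])
                elif t.direction == DOWN:
                    r.upper_bound = min(r.upper_bound, t.wild_range[0])
                else:
                    r.lower_bound = r.upper_bound = 0.0
            sol = fba(model, key.product_exchange_id, direction="min")
            assert sol.optimal and sol.objective_value >= target - 1e-6
        finally:
            model.restore_bounds(snapshot)


class TestGeneReport:
    def test_planted_gene_directions_recovered(self, testbed):
        model, _, key, wild, over = testbed
        sets = must_sets(model, wild, over)
        report = targets_to_genes(sets.all_targets(), model)
        by_gene = {g.gene_id: g for g in report.gene_targets}
        for gene, direction in key.gene_directions.items():
            assert by_gene[gene].directions == (direction,)
            assert not by_gene[gene].conflicting

    def test_and_gpr_knockout_lists_both_genes(self, toy_core):
        model, _ = toy_core
        from gsmm.optforce import InterventionTarget

        t = InterventionTarget("GLY", ("g_gly1", "g_gly2"), KNOCKOUT,
                               (0.0, 10.0), (0.0, 0.0))
        report = targets_to_genes([t], model)
        assert {g.gene_id for g in report.gene_targets} == {"g_gly1", "g_gly2"}
        assert report.counts[KNOCKOUT] == 2

    def test_conflicting_directions_flagged(self, toy_core):
        model, _ = toy_core
        from gsmm.optforce import InterventionTarget

        ts = [
            InterventionTarget("GLY", ("g_gly1",), UP, (0, 1), (2, 3)),
            InterventionTarget("PROD", ("g_gly1",), DOWN, (2, 3), (0, 1)),
        ]
        report = targets_to_genes(ts, model)
        (g,) = report.gene_targets
        assert g.conflicting
        assert report.counts["conflicting"] == 1

    def test_empty_gpr_reported_as_non_genetic(self, toy_core):
        model, _ = toy_core
        from gsmm.optforce import InterventionTarget

        t = InterventionTarget("EX_glc", (), UP, (0, 1), (2, 3))
        report = targets_to_genes([t], model)
        assert not report.gene_targets
        assert [x.reaction_id for x in report.non_genetic] == ["EX_glc"]


def test_planted_labels_recovered_across_seeded_testbeds():
    """Randomized drain capacities and cofactor coupling never change the
    planted up/down/knockout answer key."""
    for seed in range(20):
        spec = TestbedSpec(seed=seed).randomized()
        model, medium, key = make_geosmin_testbed(spec)
        wild, over = companion_specs(model, medium, key)
        found = must_sets(model, wild, over).reaction_ids()
        for rid, direction in key.directions.items():
            assert found.get(rid) == direction, (seed, rid, found.get(rid))
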