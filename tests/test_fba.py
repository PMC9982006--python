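"""FBA/FVA/robustness against brute-force vertex enumeration and closed forms."""

import numpy as np
import pytest

from gsmm.core import GprExpression, MetabolicModel, Metabolite, Reaction
from gsmm.fba import (
    InfeasibleProblemError,
    SolverStatus,
    fba,
    fva,
    robustness_analysis,
)
from oracles import brute_force_fva, brute_force_optimum


def _chain_model(uptake=10.0, conversion_cap=None):
    """A_ext -> A -> B -> B_ext; objective is the B drain."""
    m = MetabolicModel(id="chain")
    for mid, comp in [("A_e", "e"), ("A_c", "c"), ("B_c", "c"), ("B_e", "e")]:
        m.add_metabolite(Metabolite(mid, compartment=comp))
    m.add_reaction(Reaction("EX_A", {"A_e": -1.0}, lower_bound=-uptake))
    m.add_reaction(Reaction("At", {"A_e": -1.0, "A_c": 1.0}, lower_bound=0))
    m.add_reaction(
        Reaction("CONV", {"A_c": -1.0, "B_c": 1.0}, lower_bound=0,
                 upper_bound=conversion_cap if conversion_cap else 1000.0)
    )
    m.add_reaction(Reaction("Bt", {"B_c": -1.0, "B_e": 1.0}, lower_bound=0))
    m.add_reaction(Reaction("EX_B", {"B_e": -1.0}, lower_bound=0))
    m.objective_reaction_id = "EX_B"
    return m


class TestFba:
    def test_single_path_is_uptake_limited(self):
        sol = fba(_chain_model(uptake=10.0))
        assert sol.optimal
        assert sol.objective_value == pytest.approx(10.0, abs=1e-8)

    def test_toy_core_optimum_matches_hand_solution(self, toy_core):
        model, _ = toy_core
        # 10 glucose -> 20 pyruvate -> 20/3 biomass
        assert fba(model).objective_value == pytest.approx(20.0 / 3.0, rel=1e-9)

    def test_toy_core_optimum_matches_vertex_enumeration(self, toy_core):
        model, _ = toy_core
        assert fba(model).objective_value == pytest.approx(
            brute_force_optimum(model, "BIOMASS"), rel=1e-7
        )

    def test_random_bound_perturbations_match_oracle(self, toy_core):
        model, _ = toy_core
        rng = np.random.default_rng(7)
        for _ in range(30):
            snapshot = model.snapshot_bounds()
            model.reactions["EX_glc"].lower_bound = -float(rng.uniform(1, 15))
            model.reactions["GLY"].upper_bound = float(rng.uniform(2, 12))
            model.reactions["PROD"].upper_bound = float(rng.uniform(0, 5))
            try:
                lp = fba(model).objective_value
                bf = brute_force_optimum(model, "BIOMASS")
                assert lp == pytest.approx(bf, rel=1e-6, abs=1e-8)
            finally:
                model.restore_bounds(snapshot)

    def test_closed_exchanges_give_zero_growth(self, toy_core):
        model, _ = toy_core
        for rxn in model.exchanges():
            rxn.lower_bound = 0.0
        assert fba(model).objective_value == pytest.approx(0.0, abs=1e-9)

    def test_infeasible_reported_as_status_not_exception(self, toy_core):
        model, _ = toy_core
        model.reactions["BIOMASS"].lower_bound = 100.0  # above any optimum
        sol = fba(model)
        assert sol.status == SolverStatus.INFEASIBLE
        assert sol.objective_value is None

    def test_minimization_direction(self, toy_core):
        model, _ = toy_core
        assert fba(model, direction="min").objective_value == pytest.approx(
            0.0, abs=1e-9
        )

    def test_unknown_objective_raises(self, toy_core):
        model, _ = toy_core
        with pytest.raises(KeyError):
            fba(model, "NOPE")


class TestFva:
    def test_blocked_reaction_has_zero_range(self):
        m = _chain_model()
        m.add_metabolite(Metabolite("orphan_c", compartment="c"))
        m.add_reaction(Reaction("ORPHAN", {"orphan_c": 1.0}, lower_bound=0))
        ranges = fva(m, ["ORPHAN"], fraction_of_optimum=0.0)
        assert ranges["ORPHAN"] == pytest.approx((0.0, 0.0), abs=1e-9)

    @pytest.mark.parametrize("fraction", [0.0, 1.0])
    def test_ranges_match_vertex_enumeration(self, toy_core, fraction):
        model, _ = toy_core
        lp = fva(model, fraction_of_optimum=fraction)
        bf = brute_force_fva(model, fraction=fraction)
        for rid in model.reactions:
            assert lp[rid][0] == pytest.approx(bf[rid][0], rel=1e-6, abs=1e-7)
            assert lp[rid][1] == pytest.approx(bf[rid][1], rel=1e-6, abs=1e-7)

    def test_fraction_zero_ranges_nest_fraction_one(self, toy_core):
        model, _ = toy_core
        loose = fva(model, fraction_of_optimum=0.0)
        tight = fva(model, fraction_of_optimum=1.0)
        for rid in model.reactions:
            assert loose[rid][0] <= tight[rid][0] + 1e-8
            assert loose[rid][1] >= tight[rid][1] - 1e-8

    def test_optimal_fba_flux_lies_inside_fraction_one_ranges(self, toy_core):
        model, _ = toy_core
        sol = fba(model)
        ranges = fva(model, fraction_of_optimum=1.0)
        for rid, v in sol.fluxes.items():
            lo, hi = ranges[rid]
            assert lo - 1e-6 <= v <= hi + 1e-6

    def test_midpoint_flux_is_feasible(self, toy_core):
        model, _ = toy_core
        ranges = fva(model, ["PROD"], fraction_of_optimum=0.0)
        lo, hi = ranges["PROD"]
        mid = 0.5 * (lo + hi)
        snapshot = model.snapshot_bounds()
        try:
            model.reactions["PROD"].lower_bound = mid
            model.reactions["PROD"].upper_bound = mid
            assert fba(model).status == SolverStatus.OPTIMAL
        finally:
            model.restore_bounds(snapshot)

    def test_infeasible_base_problem_raises(self, toy_core):
        model, _ = toy_core
        model.reactions["BIOMASS"].lower_bound = 100.0
        with pytest.raises(InfeasibleProblemError):
            fva(model, fraction_of_optimum=1.0)

    def test_bad_fraction_rejected(self, toy_core):
        model, _ = toy_core
        with pytest.raises(ValueError):
            fva(model, fraction_of_optimum=1.5)


class TestRobustness:
    def test_piecewise_linear_curve_and_plateau(self):
        # objective = min(control, 5): rises linearly, kinks at 5, then flat
        m = _chain_model(uptake=10.0, conversion_cap=5.0)
        curve = robustness_analysis(m, "At", n_points=21, objective_reaction_id="EX_B")
        for c, o in zip(curve.control_values, curve.objective_values):
            assert o == pytest.approx(min(c, 5.0), abs=1e-7)
        assert curve.plateau_onset == pytest.approx(5.0, abs=1e-6)

    def test_two_points_are_exactly_the_range_endpoints(self, toy_core):
        model, _ = toy_core
        curve = robustness_analysis(model, "EX_glc", n_points=2)
        lo, hi = fva(model, ["EX_glc"], fraction_of_optimum=0.0)["EX_glc"]
        assert curve.control_values == pytest.approx([lo, hi], abs=1e-7)

    def test_curve_maximum_equals_unconstrained_optimum(self, toy_core):
        model, _ = toy_core
        curve = robustness_analysis(model, "EX_glc", n_points=11)
        assert max(curve.objective_values) == pytest.approx(
            fba(model).objective_value, rel=1e-6
        )

    def test_empty_control_range_is_error(self, toy_core):
        model, _ = toy_core
        model.reactions["PROD"].upper_bound = 0.0
        with pytest.raises(InfeasibleProblemError):
            robustness_analysis(model, "PROD", n_points=5)

    def test_fewer_than_two_points_rejected(self, toy_core):
        model, _ = toy_core
        with pytest.raises(ValueError):
            robustness_analysis(model, "EX_glc", n_points=1)


def test_optimum_agrees_with_independent_cobra_formulation(toy_core, tmp_path):
    """Duality-style check: a differently built LP (cobra/optlang via SBML)
    reproduces the optimum within 1e-6 relative tolerance."""
    cobra = pytest.importorskip("cobra")
    from gsmm.io import write_sbml

    model, _ = toy_core
    write_sbml(model, tmp_path / "m.xml")
    cm = cobra.io.read_sbml_model(str(tmp_path / "m.xml"))
    assert fba(model).objective_value == pytest.approx(
        cm.optimize().objective_value, rel=1e-6
    )
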