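"""LP engine: FBA, two-step photoautotrophic optimization, loop detection."""

import numpy as np
import pytest

import photogem as pg
from photogem.stoich_audit import build_matrix

from conftest import brute_force_lp


def _check_feasible(model, sol, tol=1e-6):
    sm = build_matrix(model)
    v = np.array([sol.fluxes[r] for r in sm.cols])
    assert np.max(np.abs(sm.matrix @ v)) <= tol if sm.shape[0] else True
    for rid in sm.cols:
        rxn = model.reactions[rid]
        assert rxn.lower_bound - tol <= sol.fluxes[rid] <= rxn.upper_bound + tol
        if not rxn.reversible:
            assert sol.fluxes[rid] >= -tol


class TestSolveFBA:
    def test_single_path_bound_propagation(self, simple_chain_text):
        model = pg.parse_model(simple_chain_text)
        sol = pg.solve_fba(model, pg.OptimizationSpec(objective_id="G"))
        assert sol.optimal
        assert sol.objective_value == pytest.approx(10.0, abs=1e-8)
        _check_feasible(model, sol)

    def test_stoichiometric_halving(self):
        model = pg.parse_model(
            "-REACTIONS\nE1: A_ext -> A\nR1: 2 A -> B\nG: B -> biomass_ext\n"
            "-CONSTRAINTS\nE1 [0, 10]\n-OBJ\nG 1")
        sol = pg.solve_fba(model, pg.OptimizationSpec(objective_id="G"))
        assert sol.objective_value == pytest.approx(5.0, abs=1e-8)

    def test_infeasible_reported_not_silent_zero(self):
        # forced uptake with no outlet
        model = pg.parse_model(
            "-REACTIONS\nE1: A_ext -> A\nR1: A -> B\n-CONSTRAINTS\nE1 [5, 10]\n")
        # B has no sink: steady state impossible with E1 >= 5
        sol = pg.solve_fba(model, pg.OptimizationSpec(objective_id="R1"))
        assert sol.status == "infeasible"
        assert sol.objective_value is None
        assert sol.fluxes == {}

    def test_unbounded_reported(self):
        model = pg.parse_model("E1: A_ext <-> B_ext")
        model.reactions["E1"].upper_bound = float("inf")
        sol = pg.solve_fba(model, pg.OptimizationSpec(objective_id="E1"))
        assert sol.status == "unbounded"

    def test_bound_override_is_per_solve(self):
        model = pg.parse_model(self_text := "-REACTIONS\nE1: A_ext -> A\n"
                               "G: A -> biomass_ext\n-CONSTRAINTS\nE1 [0, 10]\n")
        spec = pg.OptimizationSpec(objective_id="G",
                                   bound_overrides={"E1": (0.0, 3.0)})
        assert pg.solve_fba(model, spec).objective_value == pytest.approx(3.0)
        assert model.reactions["E1"].upper_bound == 10.0  # untouched

    def test_agrees_with_independent_cobra_solver(self, tmp_path):
        """Growth optimum cross-checked against cobrapy reading our SBML."""
        import logging

        import cobra

        model, growth, _ = pg.make_toy_phototroph(pg.PhototrophSpec(
            n_intermediates=2, photons_per_atp=1, atp_per_fixation=3,
            carbon_bound=2.0, seed=7))
        ours = pg.solve_fba(model, pg.OptimizationSpec(objective_id="growth"))
        sbml_path = tmp_path / "toy.xml"
        sbml_path.write_text(pg.export_sbml(model)[0])
        logging.getLogger("cobra").setLevel(logging.ERROR)
        cb = cobra.io.read_sbml_model(str(sbml_path))
        theirs = cb.optimize()
        assert ours.objective_value == pytest.approx(growth, rel=1e-9)
        assert theirs.objective_value == pytest.approx(ours.objective_value, rel=1e-6)

    @pytest.mark.parametrize("seed", range(40))
    def test_matches_vertex_enumeration(self, seed):
        model = pg.make_random_lp_model(seed)
        sol = pg.solve_fba(model, pg.OptimizationSpec(objective_id=model.objective_id))
        status, best = brute_force_lp(model, model.objective_id)
        assert sol.status == status
        if status == "optimal":
            assert sol.objective_value == pytest.approx(best, abs=1e-6)
            _check_feasible(model, sol)


class TestTwoStep:
    def test_toy_phototroph_hand_accounting(self):
        # photon -> ATP (1:1); CO2 uptake <= 2; fixation burns 3 ATP:
        # growth 2, photon minimum 2 * 3 = 6
        model, growth, photons = pg.make_toy_phototroph(
            pg.PhototrophSpec(n_intermediates=1, photons_per_atp=1,
                              atp_per_fixation=3, carbon_bound=2.0, seed=7))
        assert (growth, photons) == (2.0, 6.0)
        s1, s2 = pg.two_step_photoautotrophic(model, pg.photon_reactions_of(model))
        assert s1.objective_value == pytest.approx(2.0, rel=1e-9)
        assert s2.objective_value == pytest.approx(6.0, rel=1e-4)

    def test_no_photon_reactions_rejected(self):
        model, _, _ = pg.make_toy_phototroph(pg.PhototrophSpec(seed=1))
        with pytest.raises(pg.ModelError):
            pg.two_step_photoautotrophic(model, [])
        with pytest.raises(pg.ModelError):
            pg.two_step_photoautotrophic(model, ["nope"])

    def test_step2_growth_held_and_photons_not_larger(self):
        model, _, _ = pg.make_toy_phototroph(pg.PhototrophSpec(
            n_intermediates=2, photons_per_atp=2, atp_per_fixation=2,
            carbon_bound=1.7, seed=3))
        photon_ids = pg.photon_reactions_of(model)
        s1, s2 = pg.two_step_photoautotrophic(model, photon_ids)
        growth_id = model.objective_id
        assert s2.fluxes[growth_id] == pytest.approx(s1.objective_value, rel=1e-5)
        assert s2.total(photon_ids) <= s1.total(photon_ids) + 1e-9

    def test_split_photosystems_carry_equal_flux(self):
        model, growth, photons = pg.make_toy_phototroph(pg.PhototrophSpec(
            n_intermediates=1, photons_per_atp=2, atp_per_fixation=2,
            carbon_bound=1.0, seed=5, split_photosystems=True))
        s1, s2 = pg.two_step_photoautotrophic(model, pg.photon_reactions_of(model))
        psii = s2.fluxes["EX_photon_psII"]
        psi = s2.fluxes["EX_photon_psI"]
        assert psii == pytest.approx(psi, rel=1e-6)
        assert psii + psi == pytest.approx(photons, rel=1e-4)

    def test_combined_carbon_constraint(self):
        # two carbon sources, combined uptake fixed: growth equals the sum
        model = pg.parse_model("\n".join([
            "-REACTIONS",
            "L: hv_ext -> hv",
            "P: hv -> atp",
            "C1: co2_ext -> c",
            "C2: hco3_ext -> c",
            "F: c + 2 atp -> sugar",
            "G: sugar -> biomass_ext",
            "-OBJ", "G 1"]))
        s1, s2 = pg.two_step_photoautotrophic(
            model, ["L"], carbon_uptake=1.99, carbon_reactions=["C1", "C2"])
        assert s1.objective_value == pytest.approx(1.99, rel=1e-9)
        assert s2.objective_value == pytest.approx(2 * 1.99, rel=1e-4)
        # individual reading doubles the available carbon
        s1b, _ = pg.two_step_photoautotrophic(
            model, ["L"], carbon_uptake=1.99, carbon_reactions=["C1", "C2"],
            combined_carbon=False)
        assert s1b.objective_value == pytest.approx(2 * 1.99, rel=1e-9)


class TestLoopDetection:
    def test_linear_chain_clean(self):
        model = pg.parse_model(
            "-REACTIONS\nE1: A_ext -> A\nR1: A -> B\nE2: B -> B_ext\n")
        assert pg.detect_internal_loops(model) == set()

    def test_reversible_triangle_flagged(self):
        model = pg.parse_model(
            "-REACTIONS\nR1: A <-> B\nR2: B <-> C\nR3: C <-> A\n"
            "E1: A_ext -> A\nE2: C -> C_ext\n")
        assert pg.detect_internal_loops(model) == {"R1", "R2", "R3"}

    def test_dangling_branch_not_flagged(self):
        model = pg.parse_model(
            "-REACTIONS\nR1: A <-> B\nR2: B <-> C\nR3: C <-> A\n"
            "B1: C -> D\nE1: A_ext -> A\nE2: D -> D_ext\n")
        assert pg.detect_internal_loops(model) == {"R1", "R2", "R3"}

    def test_empty_model_empty_set(self):
        assert pg.detect_internal_loops(pg.MetabolicModel()) == set()

    def test_invariant_under_reaction_order(self):
        texts = [
            "-REACTIONS\nR1: A <-> B\nR2: B <-> A\nE1: A_ext -> A\n",
            "-REACTIONS\nR2: B <-> A\nE1: A_ext -> A\nR1: A <-> B\n",
        ]
        results = [pg.detect_internal_loops(pg.parse_model(t)) for t in texts]
        assert results[0] == results[1] == {"R1", "R2"}
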