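"""Reaction-list dialect parsing, serialisation and SBML round-trips."""

from fractions import Fraction

import pytest

import photogem as pg
from photogem.model_core import ModelFormatError


class TestParse:
    def test_single_reaction_defaults(self):
        model = pg.parse_model("R1: A -> B")
        assert len(model.reactions) == 1
        assert set(model.metabolites) == {"A", "B"}
        rxn = model.reactions["R1"]
        assert (rxn.lower_bound, rxn.upper_bound) == (0.0, 1000.0)
        assert not rxn.reversible

    def test_reversible_defaults(self):
        rxn = pg.parse_model("R1: A <-> B").reactions["R1"]
        assert rxn.reversible
        assert (rxn.lower_bound, rxn.upper_bound) == (-1000.0, 1000.0)

    def test_coefficients_are_exact_rationals(self):
        rxn = pg.parse_model("R1: 2 A + 0.53439 B -> 3/2 C").reactions["R1"]
        assert rxn.stoichiometry["A"] == -2
        assert rxn.stoichiometry["B"] == -Fraction("0.53439")  # consumed
        assert rxn.stoichiometry["C"] == Fraction(3, 2)
        assert rxn.substrates["B"] == Fraction("0.53439")

    def test_constraint_overrides_defaults(self, simple_chain_text):
        model = pg.parse_model(simple_chain_text)
        assert model.reactions["E1"].upper_bound == 10.0
        assert model.objective_id == "G"

    def test_external_by_suffix_and_section(self):
        text = "-REACTIONS\nR1: hv + A -> B\n-EXTERNAL METABOLITES\nhv\n"
        model = pg.parse_model(text)
        assert model.metabolites["hv"].external  # explicit section
        model2 = pg.parse_model("R1: hv_ext + A -> B")
        assert model2.metabolites["hv_ext"].external  # suffix convention
        assert not model2.metabolites["A"].external

    def test_identifiers_case_sensitive(self):
        model = pg.parse_model("-REACTIONS\nr1: a -> b\nR1: A -> B\n")
        assert set(model.reactions) == {"r1", "R1"}
        assert set(model.metabolites) == {"a", "b", "A", "B"}

    def test_comments_and_blank_lines_ignored(self):
        model = pg.parse_model("% header\n\nR1: A -> B  # trailing\n")
        assert set(model.reactions) == {"R1"}

    @pytest.mark.parametrize("text,fragment,lineno", [
        ("R1: A -> B\nR1: A -> C", "duplicate reaction id", 2),
        ("R1: 2x A -> B", "coefficient", 1),
        ("-REACTIONS\nR1: A -> B\n-CONSTRAINTS\nR9 [0, 5]", "unknown reaction", 4),
        ("R1: A B -> C", "coefficient", 1),
        ("R1: A = B", "arrow", 1),
    ])
    def test_errors_carry_line_numbers(self, text, fragment, lineno):
        with pytest.raises(ModelFormatError) as err:
            pg.parse_model(text)
        assert fragment in str(err.value)
        assert err.value.line == lineno


class TestWrite:
    def test_empty_model_refused(self):
        with pytest.raises(pg.ModelError):
            pg.write_model(pg.MetabolicModel())

    def test_one_reaction_layout(self):
        text = pg.write_model(pg.parse_model("R1: A -> 2 B"))
        lines = text.strip().splitlines()
        assert lines[0] == "-REACTIONS"
        assert lines[1] == "R1: A -> 2 B"

    @pytest.mark.parametrize("seed", range(5))
    def test_round_trip_on_synthetic_phototrophs(self, seed):
        model, _, _ = pg.make_toy_phototroph(pg.PhototrophSpec(
            n_intermediates=3, photons_per_atp=2, atp_per_fixation=2,
            carbon_bound=1.5, seed=seed, split_photosystems=seed % 2 == 0))
        again = pg.parse_model(pg.write_model(model))
        assert model.equivalent(again)
        assert pg.write_model(again) == pg.write_model(model)

    def test_round_trip_preserves_fractional_coefficients(self):
        model = pg.parse_model("R1: 0.140389293 A + 1/3 B -> C")
        again = pg.parse_model(pg.write_model(model))
        assert again.reactions["R1"].stoichiometry == \
            model.reactions["R1"].stoichiometry


class TestInvariants:
    def test_irreversible_negative_lower_bound_rejected(self):
        with pytest.raises(pg.ModelError):
            pg.Reaction("R", {"A": Fraction(-1)}, reversible=False, lower_bound=-1)

    def test_crossed_bounds_rejected(self):
        with pytest.raises(pg.ModelError):
            pg.Reaction("R", {"A": Fraction(-1)}, lower_bound=5, upper_bound=1)

    def test_unknown_metabolite_rejected(self):
        model = pg.MetabolicModel(metabolites=[pg.Metabolite("A")])
        with pytest.raises(pg.ModelError):
            model.add_reaction(pg.Reaction("R", {"A": Fraction(-1), "Z": Fraction(1)}))

    def test_empty_stoichiometry_rejected(self):
        with pytest.raises(pg.ModelError):
            pg.Reaction("R", {})


class TestSBML:
    def test_minimal_export(self):
        text, mapping = pg.export_sbml(pg.parse_model("R1: A -> B"))
        assert text.startswith("<?xml")
        assert mapping == {"A": "A", "B": "B", "R1": "R1"}
        model = pg.import_sbml(text)
        assert set(model.reactions) == {"R1"}
        assert set(model.metabolites) == {"A", "B"}

    def test_invalid_sid_sanitized_with_mapping(self):
        text, mapping = pg.export_sbml(pg.parse_model("R1: 2-ketoglut -> B"))
        assert mapping["2-ketoglut"] == "M_2_ketoglut"
        assert "M_2_ketoglut" in text

    def test_export_validates_against_schema(self):
        import libsbml
        model, _, _ = pg.make_toy_phototroph(pg.PhototrophSpec(seed=1))
        text, _ = pg.export_sbml(model)
        doc = libsbml.readSBMLFromString(text)
        assert doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) == 0
        doc.checkConsistency()
        assert doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) == 0

    @pytest.mark.parametrize("split", [False, True])
    def test_export_reimport_preserves_stoichiometry_and_bounds(self, split):
        model, _, _ = pg.make_toy_phototroph(pg.PhototrophSpec(
            n_intermediates=2, carbon_bound=2.5, seed=4,
            split_photosystems=split))
        text, mapping = pg.export_sbml(model)
        again = pg.import_sbml(text)
        assert model.equivalent(again)
        assert again.objective_id == model.objective_id

    def test_load_model_dispatches_on_content(self):
        model, _, _ = pg.make_toy_phototroph(pg.PhototrophSpec(seed=2))
        sbml_text, _ = pg.export_sbml(model)
        assert pg.load_model(sbml_text).equivalent(pg.load_model(pg.write_model(model)))
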