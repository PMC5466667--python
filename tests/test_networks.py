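import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from protocell.networks import (
    ConfigurationError,
    NetworkModel,
    ReactionSpec,
    SpeciesSpec,
    StructuralError,
    add_lipid_synthesis,
    build_pm1,
    build_pm2,
    closed_variant,
    moiety_content,
    reaction_moiety_delta,
    reaction_rate,
)


class TestBuildPM1:
    def test_counts_by_construction(self, pm1_model):
        assert len(pm1_model.species) == 8
        assert len(pm1_model.reactions) == 4
        assert set(pm1_model.species_names()) == {"A", "B", "C", "D", "AB", "ACD", "w", "acd"}

    def test_permeability_classes(self, pm1_model):
        smap = pm1_model.species_map
        for n in "ABCD":
            assert smap[n].permeability_class == "composition_dependent"
        assert smap["w"].permeability_class == "constant"
        assert smap["acd"].permeability_class == "impermeable"
        assert smap["acd"].base_permeability == 0.0

    def test_zero_catalyst_dead_state(self, pm1_model):
        conc = {n: 10.0 for n in "ABCD"}
        conc.update({"AB": 0.0, "ACD": 0.0, "w": 0.0, "acd": 0.0})
        for rxn in pm1_model.reactions:
            assert reaction_rate(rxn, conc) == 0.0

    def test_condensations_conserve_moieties(self, pm1_model):
        # w carries none of the primitive moieties; every condensation and the
        # trapped-product decay balance a, b, c, d exactly
        for name in ("R1", "R2", "D2"):
            delta = reaction_moiety_delta(pm1_model.get_reaction(name))
            assert all(v == 0 for v in delta.values()), (name, delta)

    def test_missing_rate_constant_names_reaction(self):
        with pytest.raises(ConfigurationError, match="R2"):
            build_pm1({"k2": None, "k1": 0.01, "d1": 0.1, "d2": 0.1})


class TestBuildPM2:
    def test_contains_ac(self, pm2_model, pm1_model):
        assert "AC" in pm2_model.species_names()
        assert "AC" not in pm1_model.species_names()

    def test_reduction_to_pm1_stoichiometry(self, pm2_model, pm1_model):
        kept = [r for r in pm2_model.reactions if r.name not in ("R2", "R3", "D3")]
        pm1_r2 = pm1_model.get_reaction("R2")
        reduced = kept[:1] + [pm1_r2] + kept[1:]
        by_name = {r.name: r for r in reduced}
        for r in pm1_model.reactions:
            other = by_name[r.name]
            assert dict(other.reactants) == dict(r.reactants)
            assert dict(other.products) == dict(r.products)
            assert other.catalyst == r.catalyst

    def test_moiety_conservation_all_condensations(self, pm2_model):
        for name in ("R1", "R2", "R3", "D2"):
            delta = reaction_moiety_delta(pm2_model.get_reaction(name))
            assert all(v == 0 for v in delta.values())

    def test_shared_permeability_classes_with_pm1(self, pm1_model, pm2_model):
        s1, s2 = pm1_model.species_map, pm2_model.species_map
        for name in set(s1) & set(s2):
            assert s1[name].permeability_class == s2[name].permeability_class
            assert s1[name].base_permeability == s2[name].base_permeability


class TestLipidSynthesis:
    def test_adds_expected_species_and_one_reaction(self, pm2_model):
        ext = add_lipid_synthesis(pm2_model, k_syn=0.01, k_d=0.05)
        assert len(ext.reactions) == len(pm2_model.reactions) + 1
        new = set(ext.species_names()) - set(pm2_model.species_names())
        assert new == {"P", "L", "l_mem", "L_mem"}
        assert ext.membrane_params["k_d"] == 0.05

    def test_zero_k_syn_forbidden(self, pm2_model):
        with pytest.raises(ConfigurationError):
            add_lipid_synthesis(pm2_model, k_syn=0.0)

    def test_k_d_does_not_touch_rate_law(self, pm2_model):
        a = add_lipid_synthesis(pm2_model, k_syn=0.01, k_d=0.0)
        b = add_lipid_synthesis(pm2_model, k_syn=0.01, k_d=10.0)
        ra, rb = a.get_reaction("RS"), b.get_reaction("RS")
        assert ra.rate_constant == rb.rate_constant
        assert dict(ra.reactants) == dict(rb.reactants)
        assert ra.catalyst == rb.catalyst == "AB"

    def test_requires_ab(self):
        bare = NetworkModel(
            "bare",
            [
                SpeciesSpec("N", "nutrient", env_concentration=1.0),
                SpeciesSpec("M", "metabolite"),
            ],
            [],
        )
        with pytest.raises(StructuralError):
            add_lipid_synthesis(bare, k_syn=0.01)

    def test_head_areas_on_membrane_lipids_only(self, pm2_model):
        ext = add_lipid_synthesis(pm2_model, k_syn=0.01)
        smap = ext.species_map
        assert smap["l_mem"].head_area == 0.2
        assert smap["L_mem"].head_area == 0.6
        assert smap["L"].head_area is None


class TestReactionRate:
    def test_catalyst_zero(self):
        rxn = ReactionSpec("r", {"A": 1}, {"B": 1}, 2.0, catalyst="E")
        assert reaction_rate(rxn, {"A": 5.0, "B": 0.0, "E": 0.0}) == 0.0

    def test_bimolecular_arithmetic(self):
        rxn = ReactionSpec("r", {"A": 1, "B": 1}, {"C": 1}, 1.0)
        assert reaction_rate(rxn, {"A": 2.0, "B": 3.0, "C": 0.0}) == 6.0

    def test_catalyzed_arithmetic(self):
        rxn = ReactionSpec("r", {"A": 1}, {"B": 1}, 0.5, catalyst="E")
        assert reaction_rate(rxn, {"A": 4.0, "B": 0.0, "E": 2.0}) == 4.0

    def test_negative_concentration_rejected(self):
        rxn = ReactionSpec("r", {"A": 1}, {"B": 1}, 1.0)
        with pytest.raises(ValueError):
            reaction_rate(rxn, {"A": -1.0, "B": 0.0})

    @given(
        ca=st.floats(0, 1e3),
        cb=st.floats(0, 1e3),
        ce=st.floats(0, 1e3),
        k=st.floats(1e-12, 1e3),
    )
    @settings(max_examples=50, deadline=None)
    def test_rates_nonnegative(self, ca, cb, ce, k):
        rxn = ReactionSpec("r", {"A": 1, "B": 1}, {"C": 1}, k, catalyst="E")
        assert reaction_rate(rxn, {"A": ca, "B": cb, "E": ce, "C": 0.0}) >= 0.0


class TestSpecValidation:
    def test_impermeable_needs_zero_permeability(self):
        with pytest.raises(ConfigurationError):
            SpeciesSpec("x", "waste", "impermeable", base_permeability=1e-12)

    def test_head_area_iff_membrane_lipid(self):
        with pytest.raises(ConfigurationError):
            SpeciesSpec("x", "waste", head_area=0.3)
        with pytest.raises(ConfigurationError):
            SpeciesSpec("x", "membrane_lipid", osmotically_active=False)

    def test_catalyst_not_in_stoichiometry(self):
        with pytest.raises(ConfigurationError):
            ReactionSpec("r", {"A": 1}, {"B": 1}, 1.0, catalyst="A")

    def test_stoichiometry_positive_integers(self):
        with pytest.raises(ConfigurationError):
            ReactionSpec("r", {"A": 0}, {"B": 1}, 1.0)
        with pytest.raises(ConfigurationError):
            ReactionSpec("r", {"A": 1.5}, {"B": 1}, 1.0)

    def test_undeclared_species_rejected(self):
        with pytest.raises(StructuralError):
            NetworkModel(
                "bad",
                [
                    SpeciesSpec("A", "nutrient", env_concentration=1.0),
                    SpeciesSpec("M", "metabolite"),
                ],
                [ReactionSpec("r", {"A": 1}, {"Z": 1}, 1.0)],
            )


class TestClosedVariant:
    @pytest.mark.parametrize("builder", [build_pm1, build_pm2])
    def test_every_reaction_conserves_moieties(self, builder):
        closed = closed_variant(builder())
        for rxn in closed.reactions:
            delta = reaction_moiety_delta(rxn)
            assert all(v == 0 for v in delta.values()), (rxn.name, delta)

    def test_w_carries_no_moieties(self):
        assert moiety_content("w") == {}
        assert moiety_content("acd") == {"a": 1, "c": 1, "d": 1}


class TestSerialization:
    @pytest.mark.parametrize("builder", [build_pm1, build_pm2])
    def test_round_trip_lossless(self, builder):
        model = add_lipid_synthesis(builder(), k_syn=0.02, k_d=0.1)
        d = model.to_dict()
        again = NetworkModel.from_dict(d)
        assert again.to_dict() == d
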