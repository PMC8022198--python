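"""Model construction: reaction splitting, dummy assignment, expression
layer, and the invariants the built model must satisfy."""

import numpy as np
import pytest

from pcfba.build import (
    DUMMY_ENZYME_ID,
    DUMMY_PROTEIN_ID,
    ExpressionConfig,
    assign_dummy,
    build_expression_layer,
    protein_cost,
    split_isozymes,
    split_reversible,
)
from pcfba.core import (
    EnzymeSpec,
    MachinerySpec,
    Metabolite,
    ProteinSpec,
    ProteomeBudget,
    Reaction,
    StoichiometricModel,
)


def _two_species_model():
    m = StoichiometricModel(id="mini")
    m.add_metabolite(Metabolite("a", elemental_composition={"C": 1}))
    m.add_metabolite(Metabolite("b", elemental_composition={"C": 1}))
    return m


def test_split_reversible_creates_negated_pair():
    m = _two_species_model()
    m.add_reaction(Reaction("r", {"a": -1.0, "b": 1.0}, lower_bound=-10.0,
                            upper_bound=10.0))
    out = split_reversible(m)
    fwd, rev = out.reactions["r"], out.reactions["r_rev"]
    assert (fwd.lower_bound, fwd.upper_bound) == (0.0, 10.0)
    assert (rev.lower_bound, rev.upper_bound) == (0.0, 10.0)
    assert rev.stoichiometry == {"a": 1.0, "b": -1.0}
    assert out.split_map["r"] == ("r", "r_rev")


def test_split_reversible_leaves_irreversible_untouched():
    m = _two_species_model()
    m.add_reaction(Reaction("r", {"a": -1.0, "b": 1.0}, upper_bound=10.0))
    out = split_reversible(m)
    assert "r_rev" not in out.reactions
    assert out.split_map["r"] == ("r", None)


def test_net_flux_reporting_collapses_split_pair():
    m = _two_species_model()
    m.add_reaction(Reaction("r", {"a": -1.0, "b": 1.0}, lower_bound=-10.0))
    out = split_reversible(m)
    net = out.net_fluxes({"r": 3.0, "r_rev": 0.0})
    assert net["r"] == 3.0
    assert out.net_fluxes({"r": 1.0, "r_rev": 4.0})["r"] == -3.0


def test_splitting_round_trip_reproduces_stoichiometric_matrix():
    m = _two_species_model()
    m.add_reaction(Reaction("r1", {"a": -1.0, "b": 1.0}, lower_bound=-5.0))
    m.add_reaction(Reaction("r2", {"b": -2.0, "a": 1.0}))
    S0, mets0, _ = m.stoichiometric_matrix()
    out = split_reversible(m)
    # net column of each split pair equals the original column
    for rid, (fwd, rev) in out.split_map.items():
        for met in m.metabolites:
            orig = m.reactions[rid].stoichiometry.get(met, 0.0)
            got = out.reactions[fwd].stoichiometry.get(met, 0.0)
            if rev:
                got_rev = out.reactions[rev].stoichiometry.get(met, 0.0)
                assert orig == got == -got_rev
            else:
                assert orig == got
    assert S0.shape == (len(mets0), 2)


def test_split_isozymes_one_copy_per_enzyme_and_flux_sum():
    m = _two_species_model()
    m.proteins["p"] = ProteinSpec.from_composition("p", {"ala": 100})
    m.enzymes["E1"] = EnzymeSpec("E1", {"p": 1}, {"r": 100.0})
    m.enzymes["E2"] = EnzymeSpec("E2", {"p": 1}, {"r": 200.0})
    m.add_reaction(Reaction("r", {"a": -1.0, "b": 1.0}, isozymes=["E1", "E2"]))
    out = split_isozymes(m)
    assert "r" not in out.reactions
    assert out.reactions["r__E1"].catalyst_id == "E1"
    assert out.reactions["r__E2"].catalyst_id == "E2"
    assert out.enzymes["E1"].catalyzed == {"r__E1": 100.0}
    net = out.net_fluxes({"r__E1": 1.0, "r__E2": 2.0})
    assert net["r"] == 3.0


def test_single_enzyme_reaction_not_duplicated():
    m = _two_species_model()
    m.proteins["p"] = ProteinSpec.from_composition("p", {"ala": 100})
    m.enzymes["E1"] = EnzymeSpec("E1", {"p": 1}, {"r": 100.0})
    m.add_reaction(Reaction("r", {"a": -1.0, "b": 1.0}, isozymes=["E1"]))
    out = split_isozymes(m)
    assert set(out.reactions) == {"r"}
    assert out.reactions["r"].catalyst_id == "E1"


def test_assign_dummy_covers_orphans_only():
    m = _two_species_model()
    m.add_metabolite(Metabolite("x_e", compartment="extracellular"))
    m.proteins["p"] = ProteinSpec.from_composition("p", {"ala": 90, "arg": 10})
    m.enzymes["E1"] = EnzymeSpec("E1", {"p": 1}, {"cat": 100.0})
    m.add_reaction(Reaction("cat", {"a": -1.0, "b": 1.0}, catalyst_id="E1"))
    m.add_reaction(Reaction("orphan", {"b": -1.0, "a": 1.0}))
    m.add_reaction(Reaction("spont", {"a": -1.0, "b": 1.0}, spontaneous=True))
    m.add_reaction(Reaction("ex", {"x_e": -1.0}, kind="exchange"))
    out = assign_dummy(m)
    assert out.reactions["orphan"].catalyst_id == DUMMY_ENZYME_ID
    assert out.reactions["spont"].catalyst_id is None
    assert out.reactions["ex"].catalyst_id is None
    assert out.reactions["cat"].catalyst_id == "E1"
    # dummy k_cat defaults to the median of existing turnover numbers
    assert out.enzymes[DUMMY_ENZYME_ID].catalyzed["orphan"] == 100.0
    assert DUMMY_PROTEIN_ID in out.proteins


@pytest.mark.parametrize(
    "mw,kcat,expected",
    [(100.0, 100.0, 1.0), (330.0, 90000.0, 330.0 / 90000.0)],
)
def test_protein_cost_is_mass_over_turnover(mw, kcat, expected):
    comp = {"ala": round(mw / 0.07108)}
    p = ProteinSpec.from_composition("p", comp)
    enz = EnzymeSpec("e", {"p": 1}, {"r": kcat})
    got = protein_cost(enz, "r", {"p": p})
    assert got == pytest.approx(p.molecular_weight / kcat)
    # doubling the turnover number halves the cost
    enz2 = EnzymeSpec("e2", {"p": 1}, {"r": 2 * kcat})
    assert protein_cost(enz2, "r", {"p": p}) == pytest.approx(got / 2)


def test_protein_cost_requires_positive_kcat():
    p = ProteinSpec.from_composition("p", {"ala": 100})
    enz = EnzymeSpec("e", {"p": 1}, {"r": 10.0})
    with pytest.raises(Exception):
        protein_cost(enz, "other", {"p": p})


def test_zero_gene_model_degenerates_to_metabolic_layer():
    m = _two_species_model()
    m.add_reaction(Reaction("r", {"a": -1.0, "b": 1.0}))
    pc = build_expression_layer(
        m, {}, ProteomeBudget(0.2, transporter_cap=0.001)
    )
    assert set(pc.reactions) == {"r"}
    assert pc.budget.total_modeled_fraction == 0.2


class TestExpressionLayerOnToy:
    def test_translation_consumes_length_charged_trnas(self, toy_pc):
        cfg = ExpressionConfig()
        prot = toy_pc.proteins["ldh"]
        tl = toy_pc.reactions["TL_ldh"]
        for aa, n in prot.aa_composition.items():
            assert tl.stoichiometry[f"trnac_{aa}"] == -n
            assert tl.stoichiometry[f"trna_{aa}"] == n
        # energy budget per residue from the config (ATP equivalents)
        L = prot.length
        assert tl.stoichiometry["adp_c"] == pytest.approx(
            cfg.atp_per_elongation * L
        )

    def test_enzyme_formation_consumes_subunit_stoichiometry(self, toy_pc):
        form = toy_pc.reactions["FORM_E_atps"]
        assert form.stoichiometry["protein_atpsA"] == -3.0
        assert form.stoichiometry["protein_atpsB"] == -1.0
        assert form.stoichiometry["enz_E_atps"] == 1.0

    def test_built_model_balances_elements_and_charge(self, toy_pc):
        toy_pc.check_balances(elements=("C", "N", "H", "O", "P", "S"))

    def test_every_catalyzed_reaction_has_coupling(self, toy_pc):
        for rid, rxn in toy_pc.reactions.items():
            if rxn.kind in ("metabolic", "transport") and not rxn.spontaneous:
                if rid in toy_pc.blocked_reactions:
                    continue
                assert rxn.catalyst_id is not None, rid
                assert rid in toy_pc.catalytic_coupling, rid

    def test_proteome_masses_cover_all_catalyst_species(self, toy_pc):
        for species in toy_pc.protein_mass_of:
            assert species in toy_pc.dilution_of
            assert toy_pc.protein_mass_of[species] > 0

    def test_missing_aa_formula_is_a_build_error(self):
        m = _two_species_model()
        m.proteins["p"] = ProteinSpec.from_composition("p", {"trp": 10, "ala": 90})
        with pytest.raises(Exception, match="trp"):
            build_expression_layer(
                m,
                {
                    "ribosome": MachinerySpec("ribosome", 45000.0,
                                              composition={"p": 1}),
                    "rna_polymerase": MachinerySpec("rna_polymerase", 180000.0,
                                                    composition={"p": 1}),
                },
                ProteomeBudget(0.2, transporter_cap=0.001),
            )
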