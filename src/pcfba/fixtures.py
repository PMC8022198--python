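"""Synthetic fixtures: a toy fermentative network and chemostat datasets.

The toy organism is a homolactic/mixed-acid fermenter with three
ATP-producing routes:

* glycolysis (PTS uptake, lumped EMP pathway) feeding a mixed-acid branch
  (pyruvate formate-lyase, phosphotransacetylase + acetate kinase, and an
  ethanol branch re-oxidizing NADH) — 3 ATP per glucose;
* the same glycolysis feeding lactate dehydrogenase — 2 ATP per glucose;
* the arginine deiminase pathway (arginine/ornithine antiport, arginine
  deiminase, catabolic ornithine transcarbamylase, carbamate kinase) — 1 ATP
  of substrate-level phosphorylation per arginine plus the ATP-equivalent of
  the two cytosolic protons the pathway consumes, recovered through a
  membrane ATP synthase translocating ``atpase_h_per_atp`` protons per ATP
  (1 + 2/3 = 1.67 at the default stoichiometry of 3).

All internal reactions balance C, H, N, O, P, S and charge exactly; the
proton bookkeeping uses H2PO4- for phosphate and NH4+ for ammonium, which
places the pathway's two-proton consumption at the carbamate-kinase step.
With ``include_expression_layer`` the network is pushed through the full
construction pipeline (reversible split, isozyme split, dummy assignment,
expression layer) and wired for chemostat simulation.

Chemostat measurement tables emulate steady-state cultures where amino
acids are taken up linearly with growth rate; concentrations are
back-computed through q = D (C_supernatant - C_medium) / X and perturbed
with Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .build import (
    ExpressionConfig,
    assign_dummy,
    build_expression_layer,
    split_isozymes,
    split_reversible,
)
from .core import (
    EnzymeSpec,
    MachinerySpec,
    Metabolite,
    PCModel,
    ProteinSpec,
    ProteomeBudget,
    Reaction,
    StoichiometricModel,
)
from .simulation import calibrate_transporter_cap

__all__ = [
    "ToyNetworkSpec",
    "ChemostatRecord",
    "make_toy_network",
    "make_toy_pcmodel",
    "make_micro_model",
    "make_chemostat_dataset",
    "flux_from_chemostat",
    "fit_uptake_bounds",
    "dilution_rate",
    "UptakeFit",
]


@dataclass
class ToyNetworkSpec:
    """Conditions of the bundled toy organism."""

    include_expression_layer: bool = True
    atpase_h_per_atp: int = 3  # protons translocated per ATP by the synthase
    pts_glucose: bool = True  # glucose import phosphorylated at PEP expense
    seed: int = 0
    ngam: float = 0.4  # growth-independent maintenance, mmol ATP/gCDW/h
    #: g/gCDW of modeled protein; with 40% of total protein unmodeled this
    #: corresponds to a total protein content of 0.46 g/gCDW
    total_modeled_fraction: float = 0.276
    unmodeled_fraction: float = 0.40
    biomass_coefficient: float = 1.54  # mmol non-protein/RNA biomass per gCDW
    kcat_transporter: float = 24000.0  # 1/h
    km_glucose: float = 0.2  # mM
    protein_k_deg: float = 0.02  # 1/h

    def __post_init__(self) -> None:
        if self.atpase_h_per_atp <= 0:
            raise ValueError("atpase_h_per_atp must be > 0")


# fraction of ala/arg/ser residues in every toy protein (by count)
_AA_FRACTIONS = {"ala": 0.70, "arg": 0.15, "ser": 0.15}

#: growth-rate-dependent amino-acid uptake bounds, mmol/gCDW/h =
#: slope x mu + intercept; arginine is deliberately overconsumable
#: (catabolized) while alanine/serine track protein demand.
DEFAULT_UPTAKE_BOUNDS = {
    "ala": (4.5, 0.1),
    "arg": (2.0, 0.3),
    "ser": (1.0, 0.05),
}


def _formula(C=0, H=0, N=0, O=0, P=0, S=0) -> dict[str, int]:
    out = {"C": C, "H": H, "N": N, "O": O, "P": P, "S": S}
    return {k: v for k, v in out.items() if v}


# (elements, charge) per species name; _c and _e variants share formulas
_SPECIES: dict[str, tuple[dict[str, int], int]] = {
    "glc": (_formula(C=6, H=12, O=6), 0),
    "g6p": (_formula(C=6, H=11, O=9, P=1), -2),
    "pep": (_formula(C=3, H=2, O=6, P=1), -3),
    "pyr": (_formula(C=3, H=3, O=3), -1),
    "lac": (_formula(C=3, H=5, O=3), -1),
    "coa": (_formula(C=21, H=32, N=7, O=16, P=3, S=1), -4),
    "accoa": (_formula(C=23, H=34, N=7, O=17, P=3, S=1), -4),
    "for": (_formula(C=1, H=1, O=2), -1),
    "ac": (_formula(C=2, H=3, O=2), -1),
    "acp": (_formula(C=2, H=3, O=5, P=1), -2),
    "etoh": (_formula(C=2, H=6, O=1), 0),
    "atp": (_formula(C=10, H=12, N=5, O=13, P=3), -4),
    "adp": (_formula(C=10, H=12, N=5, O=10, P=2), -3),
    "pi": (_formula(H=2, O=4, P=1), -1),
    "h2o": (_formula(H=2, O=1), 0),
    "h": (_formula(H=1), 1),
    "nad": (_formula(C=21, H=26, N=7, O=14, P=2), -1),
    "nadh": (_formula(C=21, H=27, N=7, O=14, P=2), -2),
    "co2": (_formula(C=1, O=2), 0),
    "o2": (_formula(O=2), 0),
    "h2o2": (_formula(H=2, O=2), 0),
    "nh4": (_formula(N=1, H=4), 1),
    "arg": (_formula(C=6, H=15, N=4, O=2), 1),
    "orn": (_formula(C=5, H=13, N=2, O=2), 1),
    "citr": (_formula(C=6, H=13, N=3, O=3), 0),
    "cbp": (_formula(C=1, H=2, N=1, O=5, P=1), -2),
    "ala": (_formula(C=3, H=7, N=1, O=2), 0),
    "ser": (_formula(C=3, H=7, N=1, O=3), 0),
    "ntp": (_formula(C=10, H=12, N=5, O=13, P=3), -4),
    "nmp": (_formula(C=10, H=8, N=5, O=5, P=1), -2),
    "biomass": (_formula(C=6, H=11, O=9, P=1), -2),
}

#: enzyme id -> (subunits [(protein, count, nominal MW g/mmol)],
#:               {reaction: k_cat 1/h})
_ENZYMES: list[tuple[str, list[tuple[str, int, float]], dict[str, float]]] = [
    ("E_pts", [("pts", 1, 70.0)], {"GLCpts": 24000.0}),
    ("E_glct1", [("glct1", 1, 45.0)], {"GLCt1": 17000.0}),
    ("E_glcabc", [("glcabc", 1, 60.0)], {"GLCabc": 10000.0}),
    ("E_hex", [("hex", 1, 50.0)], {"HEX": 67000.0}),
    ("E_gly", [("gly", 1, 300.0)], {"GLY": 100000.0}),
    ("E_pyk", [("pyk", 1, 55.0)], {"PYK": 67000.0}),
    ("E_ldh", [("ldh", 1, 35.0)], {"LDH": 33000.0}),
    ("E_pfl", [("pfl", 1, 85.0)], {"PFL": 13000.0}),
    ("E_pta", [("pta", 1, 35.0)], {"PTA": 50000.0}),
    ("E_ack", [("ack", 1, 45.0)], {"ACK": 50000.0}),
    ("E_adhe", [("adhe", 1, 95.0)], {"ADHE": 10000.0}),
    ("E_adhe2", [("adhe2", 1, 90.0)], {"ADHE": 10000.0}),
    ("E_pox", [("pox", 1, 65.0)], {"POX": 17000.0}),
    ("E_atps", [("atpsA", 3, 100.0), ("atpsB", 1, 200.0)], {"ATPS": 67000.0}),
    ("E_lact", [("lact", 1, 45.0)], {"LACt": 33000.0}),
    ("E_act", [("act", 1, 45.0)], {"ACt": 33000.0}),
    ("E_fort", [("fort", 1, 45.0)], {"FORt": 33000.0}),
    ("E_argt", [("argt", 1, 50.0)], {"ARGORNt": 5000.0}),
    ("E_argp", [("argp", 1, 60.0)], {"ARGabc": 10000.0}),
    ("E_adi", [("adi", 1, 45.0)], {"ADI": 2300.0}),
    ("E_otc", [("otc", 1, 40.0)], {"OTC": 6700.0}),
    ("E_ck", [("ck", 1, 35.0)], {"CK": 17000.0}),
    ("E_alat", [("alat", 1, 45.0)], {"ALAt": 17000.0}),
    ("E_sert", [("sert", 1, 45.0)], {"SERt": 17000.0}),
    ("E_nmpt", [("nmpt", 1, 45.0)], {"NMPt": 33000.0}),
    ("E_mat", [("mat", 1, 120.0)], {}),
]

#: anaerobic condition: oxygen exchange and pyruvate oxidase blocked, plus
#: one alcohol dehydrogenase isozyme and two glucose transport reactions
DEFAULT_BLOCKED = [
    "EX_o2",
    "EX_o2_rev",
    "POX",
    "ADHE__E_adhe2",
    "GLCt1",
    "GLCabc",
]


def _toy_protein(pid: str, mw: float, k_deg: float) -> ProteinSpec:
    """A protein of roughly the requested mass, with the fixture's standard
    ala/arg/ser composition."""
    avg = sum(_AA_FRACTIONS[aa] * m for aa, m in
              (("ala", 0.07108), ("arg", 0.15619), ("ser", 0.08708)))
    L = max(2, round((mw - 0.018) / avg))
    n_arg = round(_AA_FRACTIONS["arg"] * L)
    n_ser = round(_AA_FRACTIONS["ser"] * L)
    comp = {"ala": L - n_arg - n_ser, "arg": n_arg, "ser": n_ser}
    return ProteinSpec.from_composition(pid, comp, k_deg=k_deg)


def make_toy_network(spec: ToyNetworkSpec | None = None) -> StoichiometricModel:
    """The metabolic layer of the toy organism (pre-split, with enzymes)."""
    spec = spec or ToyNetworkSpec()
    m = StoichiometricModel(id="toy")

    cytosolic = [
        "glc", "g6p", "pep", "pyr", "lac", "coa", "accoa", "for", "ac", "acp",
        "etoh", "atp", "adp", "pi", "h2o", "h", "nad", "nadh", "co2", "o2",
        "h2o2", "nh4", "arg", "orn", "citr", "cbp", "ala", "ser", "biomass",
    ]
    extracellular = [
        "glc", "lac", "ac", "for", "etoh", "co2", "o2", "h2o2", "nh4", "arg",
        "orn", "ala", "ser", "h", "h2o", "pi",
    ]
    if spec.include_expression_layer:
        cytosolic += ["ntp", "nmp"]
        extracellular += ["nmp"]
    for name in cytosolic:
        comp, charge = _SPECIES[name]
        m.add_metabolite(Metabolite(f"{name}_c", name=name, compartment="cytosol",
                                    elemental_composition=dict(comp), charge=charge))
    for name in extracellular:
        comp, charge = _SPECIES[name]
        m.add_metabolite(Metabolite(f"{name}_e", name=name,
                                    compartment="extracellular",
                                    elemental_composition=dict(comp), charge=charge))

    def R(rid, stoich, kind="metabolic", lb=0.0, ub=1000.0, spont=False,
          isozymes=(), name=""):
        m.add_reaction(Reaction(id=rid, stoichiometry=stoich, lower_bound=lb,
                                upper_bound=ub, kind=kind, spontaneous=spont,
                                isozymes=list(isozymes), name=name))

    n_h = spec.atpase_h_per_atp
    # glucose uptake routes; the PTS is the physiological one
    if spec.pts_glucose:
        R("GLCpts", {"glc_e": -1, "pep_c": -1, "g6p_c": 1, "pyr_c": 1},
          kind="transport", name="PTS glucose uptake")
    else:
        R("GLCpts", {"glc_e": -1, "glc_c": 1}, kind="transport",
          name="glucose permease (primary)")
    R("GLCt1", {"glc_e": -1, "glc_c": 1}, kind="transport")
    R("GLCabc", {"glc_e": -1, "atp_c": -1, "h2o_c": -1,
                 "glc_c": 1, "adp_c": 1, "pi_c": 1}, kind="transport")
    R("HEX", {"glc_c": -1, "atp_c": -1, "g6p_c": 1, "adp_c": 1, "h_c": 1})
    # lumped EMP glycolysis, G6P -> 2 PEP (+1 ATP net, +2 NADH)
    R("GLY", {"g6p_c": -1, "nad_c": -2, "adp_c": -1, "pi_c": -2,
              "pep_c": 2, "nadh_c": 2, "atp_c": 1, "h2o_c": 2, "h_c": 5},
      name="glycolysis (lumped)")
    R("PYK", {"pep_c": -1, "adp_c": -1, "h_c": -1, "pyr_c": 1, "atp_c": 1})
    R("LDH", {"pyr_c": -1, "nadh_c": -1, "h_c": -1, "lac_c": 1, "nad_c": 1})
    R("PFL", {"pyr_c": -1, "coa_c": -1, "accoa_c": 1, "for_c": 1})
    R("PTA", {"accoa_c": -1, "pi_c": -1, "acp_c": 1, "coa_c": 1, "h_c": 1})
    R("ACK", {"acp_c": -1, "adp_c": -1, "ac_c": 1, "atp_c": 1})
    R("ADHE", {"accoa_c": -1, "nadh_c": -2, "h_c": -2,
               "etoh_c": 1, "coa_c": 1, "nad_c": 2},
      isozymes=["E_adhe", "E_adhe2"], name="acetaldehyde/alcohol dehydrogenase")
    R("POX", {"pyr_c": -1, "pi_c": -1, "o2_c": -1,
              "acp_c": 1, "co2_c": 1, "h2o2_c": 1}, name="pyruvate oxidase")
    # arginine deiminase pathway: consumes 2 cytosolic protons per arginine
    R("ARGORNt", {"arg_e": -1, "orn_c": -1, "arg_c": 1, "orn_e": 1},
      kind="transport", name="arginine/ornithine antiport")
    R("ARGabc", {"arg_e": -1, "atp_c": -1, "h2o_c": -1,
                 "arg_c": 1, "adp_c": 1, "pi_c": 1}, kind="transport")
    R("ADI", {"arg_c": -1, "h2o_c": -1, "citr_c": 1, "nh4_c": 1},
      name="arginine deiminase")
    R("OTC", {"citr_c": -1, "pi_c": -1, "orn_c": 1, "cbp_c": 1},
      name="ornithine transcarbamylase (catabolic)")
    R("CK", {"cbp_c": -1, "adp_c": -1, "h_c": -2,
             "atp_c": 1, "co2_c": 1, "nh4_c": 1}, name="carbamate kinase")
    # membrane ATP synthase, reversible: n_h protons per ATP
    R("ATPS", {"adp_c": -1, "pi_c": -1, "h_e": -n_h,
               "atp_c": 1, "h2o_c": 1, "h_c": n_h},
      lb=-1000.0, name=f"ATP synthase ({n_h} H+/ATP)")
    # fermentation product export (acids leave with a proton)
    R("LACt", {"lac_c": -1, "h_c": -1, "lac_e": 1, "h_e": 1}, kind="transport")
    R("ACt", {"ac_c": -1, "h_c": -1, "ac_e": 1, "h_e": 1}, kind="transport")
    R("FORt", {"for_c": -1, "h_c": -1, "for_e": 1, "h_e": 1}, kind="transport")
    R("ETOHt", {"etoh_c": -1, "etoh_e": 1}, kind="transport", spont=True)
    R("CO2t", {"co2_c": -1, "co2_e": 1}, kind="transport", spont=True)
    R("O2t", {"o2_e": -1, "o2_c": 1}, kind="transport", spont=True)
    R("H2O2t", {"h2o2_c": -1, "h2o2_e": 1}, kind="transport", spont=True)
    R("NH4t", {"nh4_c": -1, "nh4_e": 1}, kind="transport", spont=True)
    R("H2Ot", {"h2o_c": -1, "h2o_e": 1}, kind="transport", lb=-1000.0, spont=True)
    # medium phosphate: biomass and diluted RNA carry P out of the cell
    R("PIt", {"pi_e": -1, "pi_c": 1}, kind="transport", spont=True)
    R("ALAt", {"ala_e": -1, "ala_c": 1}, kind="transport")
    R("SERt", {"ser_e": -1, "ser_c": 1}, kind="transport")
    # biomass precursor (non-protein, non-RNA biomass) and maintenance
    R("BIOSYN", {"g6p_c": -1, "atp_c": -2, "h2o_c": -2,
                 "biomass_c": 1, "adp_c": 2, "pi_c": 2})
    R("BIODIL", {"biomass_c": -1}, kind="biomass")
    R("MAINT", {"atp_c": -1, "h2o_c": -1, "adp_c": 1, "pi_c": 1},
      kind="maintenance", lb=spec.ngam, name="ATP maintenance")
    if spec.include_expression_layer:
        R("NMPt", {"nmp_e": -1, "nmp_c": 1}, kind="transport")
        R("NTPR", {"nmp_c": -1, "atp_c": -2, "h2o_c": -2, "ntp_c": 1, "adp_c": 2})

    uptakes = ["glc", "arg", "ala", "ser", "h", "h2o", "o2", "pi"]
    if spec.include_expression_layer:
        uptakes.append("nmp")
    exports = ["lac", "ac", "for", "etoh", "co2", "nh4", "orn", "h2o2"]
    for name in uptakes:
        R(f"EX_{name}", {f"{name}_e": -1}, kind="exchange", lb=-1000.0)
    for name in exports:
        R(f"EX_{name}", {f"{name}_e": -1}, kind="exchange", lb=0.0)

    for eid, subunits, catalyzed in _ENZYMES:
        for pid, _count, mw in subunits:
            if pid not in m.proteins:
                m.proteins[pid] = _toy_protein(pid, mw, spec.protein_k_deg)
        relevant = {r: k for r, k in catalyzed.items() if r in m.reactions}
        if not catalyzed or relevant or eid in ("E_adhe", "E_adhe2", "E_mat"):
            m.enzymes[eid] = EnzymeSpec(
                id=eid, subunits={p: c for p, c, _ in subunits}, catalyzed=relevant
            )
    # the isozyme pair is attached through the reaction's isozyme list; their
    # catalyzed maps are keyed by the shared reaction id until the split
    for eid in ("E_adhe", "E_adhe2"):
        m.enzymes[eid].catalyzed["ADHE"] = 10000.0
    # single-isozyme reactions: attach the catalyst directly
    for eid, _, catalyzed in _ENZYMES:
        for rid in catalyzed:
            if rid in m.reactions and rid != "ADHE":
                m.reactions[rid].catalyst_id = eid

    m.check_balances(elements=("C", "H", "N", "O", "P", "S"))
    return m


def make_toy_pcmodel(
    spec: ToyNetworkSpec | None = None,
    calibrate: bool = True,
) -> PCModel:
    """The toy organism as a fully wired proteome-constrained model.

    Runs the whole construction pipeline and, with ``calibrate``, sets the
    glucose-transporter cap to the minimal transporter concentration that
    supports the maximal growth rate on saturating glucose.
    """
    spec = spec or ToyNetworkSpec(include_expression_layer=True)
    base = make_toy_network(spec)
    model = split_reversible(base)
    model = split_isozymes(model)
    model = assign_dummy(model, k_deg=0.0)

    machineries = {
        "ribosome": MachinerySpec("ribosome", catalytic_rate=45000.0,
                                  composition={"rps": 2, "rrna": 1}),
        "rna_polymerase": MachinerySpec("rna_polymerase", catalytic_rate=180000.0,
                                        composition={"rpo": 2}),
    }
    model.proteins["rps"] = _toy_protein("rps", 400.0, 0.0)
    model.proteins["rpo"] = _toy_protein("rpo", 200.0, 0.0)

    budget = ProteomeBudget(
        total_modeled_fraction=spec.total_modeled_fraction,
        unmodeled_fraction=spec.unmodeled_fraction,
        transporter_cap=0.01,  # placeholder; calibrated below
    )
    cfg = ExpressionConfig(maturation_enzyme="E_mat")
    pc = build_expression_layer(model, machineries, budget, cfg)

    pc.biomass_reaction = "BIODIL"
    pc.biomass_coefficient = spec.biomass_coefficient
    pc.growth_pinned["BIODIL"] = spec.biomass_coefficient
    pc.maintenance_reaction = "MAINT"
    pc.glucose_transport_reaction = "GLCpts"
    pc.glucose_transporter = "enz_E_pts"
    pc.kcat_transporter = spec.kcat_transporter
    pc.km_glucose = spec.km_glucose
    pc.blocked_reactions = list(DEFAULT_BLOCKED)
    pc.uptake_bounds = dict(DEFAULT_UPTAKE_BOUNDS)
    pc.uptake_reactions = {aa: f"EX_{aa}_rev" for aa in DEFAULT_UPTAKE_BOUNDS}
    if calibrate:
        pc = calibrate_transporter_cap(pc)
    return pc


def make_micro_model(
    k_cat: float = 24000.0,
    k_m: float = 0.2,
    cap: float = 2e-4,
    ngam: float = 0.5,
    atp_per_growth: float = 15.0,
    atp_per_glucose: float = 2.0,
) -> PCModel:
    """A three-reaction chemostat micro-model with a closed-form minimal
    glucose concentration.

    Transport is Michaelis-Menten-limited (q <= k_cat * cap * S/(K_M + S)),
    catabolism yields ``atp_per_glucose`` ATP per glucose, and the ATP demand
    is ngam + atp_per_growth * mu, so

        sigma_min(mu) = (ngam + atp_per_growth * mu) /
                        (atp_per_glucose * k_cat * cap),
        S_min = K_M * sigma_min / (1 - sigma_min).
    """
    m = PCModel(id="micro")
    for name, comp_name in (("glc_e", "glc"), ("glc_c", "glc"), ("atp_c", "atp"),
                            ("adp_c", "adp"), ("pi_c", "pi"), ("h2o_c", "h2o")):
        comp, charge = _SPECIES[comp_name]
        m.add_metabolite(Metabolite(
            name, compartment="extracellular" if name.endswith("_e") else "cytosol",
            elemental_composition=dict(comp), charge=charge))
    # neutral lactic acid keeps the micro-model proton-free
    m.add_metabolite(Metabolite("lacH_e", compartment="extracellular",
                                elemental_composition=_formula(C=3, H=6, O=3)))
    m.add_reaction(Reaction("GLCt", {"glc_e": -1, "glc_c": 1}, kind="transport"))
    m.add_reaction(Reaction(
        "CATAB",
        {"glc_c": -1, "adp_c": -atp_per_glucose, "pi_c": -atp_per_glucose,
         "lacH_e": 2, "atp_c": atp_per_glucose, "h2o_c": atp_per_glucose},
        spontaneous=True))
    m.add_reaction(Reaction("MAINT", {"atp_c": -1, "h2o_c": -1, "adp_c": 1, "pi_c": 1},
                            kind="maintenance", lower_bound=ngam))
    m.add_reaction(Reaction("GROWTH", {"atp_c": -1, "h2o_c": -1, "adp_c": 1, "pi_c": 1},
                            kind="biomass"))
    m.add_reaction(Reaction("EX_glc", {"glc_e": -1}, kind="exchange",
                            lower_bound=-1000.0))
    m.add_reaction(Reaction("EX_glc_rev", {"glc_e": 1}, kind="exchange"))
    m.add_reaction(Reaction("EX_lacH", {"lacH_e": -1}, kind="exchange"))
    m.growth_pinned["GROWTH"] = atp_per_growth
    m.glucose_transport_reaction = "GLCt"
    m.kcat_transporter = k_cat
    m.km_glucose = k_m
    m.budget = ProteomeBudget(total_modeled_fraction=1.0, transporter_cap=cap)
    return m


def micro_model_s_min(model: PCModel, mu: float) -> float:
    """Closed-form minimal glucose concentration of the micro-model."""
    ngam = model.reactions["MAINT"].lower_bound
    demand = ngam + model.growth_pinned["GROWTH"] * mu
    q = demand / abs(model.reactions["CATAB"].stoichiometry["atp_c"])
    sigma = q / (model.kcat_transporter * model.budget.transporter_cap)
    if sigma >= 1:
        raise ValueError("growth rate unreachable at any glucose concentration")
    return model.km_glucose * sigma / (1 - sigma)


# ---------------------------------------------------------------------------
# chemostat measurement tables


@dataclass
class ChemostatRecord:
    """One steady-state chemostat measurement of one compound."""

    replicate: int
    D: float  # dilution rate, 1/h
    compound: str
    C_medium: float  # mM in the feed
    C_supernatant: float  # mM in the reactor outflow
    X_biomass: float  # gCDW/l

    def __post_init__(self) -> None:
        if self.D <= 0:
            raise ValueError("dilution rate must be > 0")
        if self.X_biomass <= 0:
            raise ValueError("biomass density must be > 0")


def dilution_rate(feed_ml_per_min: float, working_volume_ml: float) -> float:
    """Chemostat dilution rate (1/h) from feed flow and working volume."""
    if working_volume_ml <= 0:
        raise ValueError("working volume must be > 0")
    return feed_ml_per_min * 60.0 / working_volume_ml


#: reference chemostat hardware: 2.25 ml/min into a 270 ml working volume,
#: i.e. D = 0.5/h
REFERENCE_D = dilution_rate(2.25, 270.0)

#: true uptake models of the generator: linear a*mu + b for most amino
#: acids; aspartate/glutamate are saturating (non-linear) negative controls;
#: ornithine is secreted.
_TRUE_UPTAKE = {
    "ala": ("linear", DEFAULT_UPTAKE_BOUNDS["ala"]),
    "arg": ("linear", DEFAULT_UPTAKE_BOUNDS["arg"]),
    "ser": ("linear", DEFAULT_UPTAKE_BOUNDS["ser"]),
    "leu": ("linear", (0.8, 0.04)),
    "asp": ("saturating", (1.2, 0.25)),
    "glu": ("saturating", (1.5, 0.30)),
    "orn": ("secreted", (0.9, 0.1)),
}


def true_uptake(compound: str, mu: float) -> float:
    """Signed true flux (mmol/gCDW/h, uptake negative) of the generator."""
    kind, (a, b) = _TRUE_UPTAKE[compound]
    if kind == "linear":
        return -(a * mu + b)
    if kind == "saturating":
        return -a * mu / (b + mu)
    return a * mu + b  # secreted


@dataclass
class ChemostatProvenance:
    """Ground truth behind a generated dataset, for recovery tests: the
    (slope, intercept) of every linearly consumed compound and the exact
    concentration noise sd (mM) applied per compound."""

    slopes: dict[str, tuple[float, float]]
    noise_sd_mm: dict[str, float]

    def slope_se(self, compound: str, records: list["ChemostatRecord"]) -> float:
        """Exact standard error of the OLS slope estimator for ``compound``:
        the estimator is linear in the (known, Gaussian) concentration
        noise, whose contribution to each flux point is D x sd_C / X."""
        rel = [r for r in records if r.compound == compound]
        d = np.array([r.D for r in rel])
        sd_u = d * self.noise_sd_mm[compound] / np.array(
            [r.X_biomass for r in rel]
        )
        w = (d - d.mean()) / ((d - d.mean()) ** 2).sum()
        return float(np.sqrt((w**2 * sd_u**2).sum()))


def make_chemostat_dataset(
    seed: int,
    n_rates: int = 6,
    noise_sd: float = 0.05,
    n_replicates: int = 1,
    d_range: tuple[float, float] = (0.1, 0.6),
    biomass_per_l: float = 1.0,
    medium_mm: float = 10.0,
) -> tuple[list[ChemostatRecord], ChemostatProvenance]:
    """Simulated chemostat supernatant/medium measurement tables.

    Concentrations are back-computed through q = D (C_sup - C_med)/X and
    perturbed with Gaussian noise whose standard deviation is ``noise_sd``
    times the compound's mean supernatant concentration.  Returns the
    records plus the full provenance (true trend parameters and applied
    noise) for recovery tests.  Output is a pure function of
    (seed, arguments).
    """
    if n_rates < 2:
        raise ValueError("need at least 2 dilution rates")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    rates = np.linspace(d_range[0], d_range[1], n_rates)
    records: list[ChemostatRecord] = []
    slopes = {
        c: params for c, (kind, params) in _TRUE_UPTAKE.items() if kind == "linear"
    }
    # noise sd is 5% (noise_sd) of the compound's mean supernatant
    # concentration across the sweep: one sd per compound, as a calibrated
    # assay would show
    mean_c: dict[str, float] = {}
    for compound in _TRUE_UPTAKE:
        c_med = 0.0 if _TRUE_UPTAKE[compound][0] == "secreted" else medium_mm
        sups = [c_med + true_uptake(compound, D) * biomass_per_l / D for D in rates]
        mean_c[compound] = float(np.mean(sups))
    for rep in range(n_replicates):
        for D in rates:
            X = biomass_per_l
            for compound in _TRUE_UPTAKE:
                q = true_uptake(compound, D)
                c_med = 0.0 if _TRUE_UPTAKE[compound][0] == "secreted" else medium_mm
                c_sup = c_med + q * X / D
                if c_sup < 0:
                    raise ValueError(
                        f"medium concentration {medium_mm} mM exhausted for "
                        f"{compound} at D = {D}"
                    )
                noisy = c_sup + rng.normal(0.0, noise_sd * max(mean_c[compound], 1e-6))
                records.append(
                    ChemostatRecord(
                        replicate=rep,
                        D=float(D),
                        compound=compound,
                        C_medium=float(c_med),
                        C_supernatant=float(max(noisy, 0.0)),
                        X_biomass=float(X),
                    )
                )
    return records, ChemostatProvenance(
        slopes=slopes,
        noise_sd_mm={c: noise_sd * max(mean_c[c], 1e-6) for c in _TRUE_UPTAKE},
    )


def flux_from_chemostat(record: ChemostatRecord, compound: str | None = None) -> float:
    """Exchange flux q = D (C_supernatant - C_medium) / X_biomass in
    mmol/gCDW/h; consumption is negative (storage convention)."""
    if compound is not None and compound != record.compound:
        raise ValueError(f"record is for {record.compound}, not {compound}")
    if record.X_biomass <= 0:
        raise ValueError("biomass density must be > 0")
    return record.D * (record.C_supernatant - record.C_medium) / record.X_biomass


@dataclass
class UptakeFit:
    compound: str
    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    n: int


def fit_uptake_bounds(records: list[ChemostatRecord]) -> dict[str, UptakeFit]:
    """Ordinary least squares of uptake magnitude on growth rate, per
    consumed compound; secreted compounds (mean q > 0) are excluded and a
    negative fitted intercept is clipped at zero.

    The (slope, intercept) pairs feed the simulation layer's growth-rate-
    dependent uptake bounds.
    """
    frame = pd.DataFrame(
        {
            "compound": r.compound,
            "D": r.D,
            "q": flux_from_chemostat(r),
        }
        for r in records
    )
    fits: dict[str, UptakeFit] = {}
    for compound, grp in frame.groupby("compound"):
        if grp["q"].mean() > 0:
            continue  # secreted, no uptake bound
        if grp["D"].nunique() < 2:
            raise ValueError(
                f"{compound}: at least two distinct dilution rates required"
            )
        res = stats.linregress(grp["D"], -grp["q"])
        intercept, ise = res.intercept, res.intercept_stderr
        if intercept < 0:
            intercept = 0.0
        fits[compound] = UptakeFit(
            compound=compound,
            slope=float(res.slope),
            intercept=float(intercept),
            slope_se=float(res.stderr),
            intercept_se=float(ise),
            n=len(grp),
        )
    return fits
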