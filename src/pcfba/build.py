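"""Constructing a proteome-constrained model from a conventional one.

The pipeline mirrors how metabolism-and-expression models are assembled:

1. :func:`split_reversible` — every reversible reaction becomes a forward /
   reverse pair so that each direction can carry its own catalyst cost.
2. :func:`split_isozymes` — a reaction with alternative catalysts becomes one
   copy per isozyme, each coupled to a single enzyme.
3. :func:`assign_dummy` — catalyzed reactions with no gene assignment get a
   shared dummy protein of average amino-acid composition, so that no flux is
   free of proteome cost.
4. :func:`build_expression_layer` — per-gene transcription, mRNA turnover,
   translation, protein turnover, enzyme formation, and dilution reactions
   are added, together with tRNA charging and the machinery (ribosome, RNA
   polymerase, rRNA/tRNA maturation) that catalyzes them.

Compositions of expression-layer species (mRNA, proteins, complexes) are
derived by closing the creating reaction, so every constructed reaction is
elementally balanced by construction; :meth:`StoichiometricModel.check_balances`
verifies this after the build.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field

from .core import (
    AA_FORMULA,
    EnzymeSpec,
    MachinerySpec,
    Metabolite,
    ModelValidationError,
    PCModel,
    ProteinSpec,
    ProteomeBudget,
    Reaction,
    StoichiometricModel,
    average_aa_composition,
    residue_mass,
)

__all__ = [
    "ExpressionConfig",
    "split_reversible",
    "split_isozymes",
    "assign_dummy",
    "protein_cost",
    "build_expression_layer",
    "DUMMY_PROTEIN_ID",
    "DUMMY_ENZYME_ID",
]

DUMMY_PROTEIN_ID = "dummy_protein"
DUMMY_ENZYME_ID = "E_dummy"


@dataclass
class ExpressionConfig:
    """Tunable stoichiometry of the expression layer.

    Energy accounting is in ATP equivalents (GTP consumed by elongation is
    represented by ATP): ``atp_per_elongation`` per residue polymerized,
    ``atp_per_charging`` per tRNA charging event, ``atp_per_degradation`` per
    residue hydrolyzed, ``atp_per_unmodeled_residue`` per residue of the
    unmodeled-protein lump.  Lengths are in residues (protein), nucleotides
    (RNA); ``nt_per_residue`` converts coding length.
    """

    atp_per_elongation: float = 2.0
    atp_per_charging: float = 1.0
    atp_per_degradation: float = 1.0
    atp_per_unmodeled_residue: float = 3.0
    nt_per_residue: int = 3
    trna_length_nt: int = 80
    rrna_length_nt: int = 1500
    mrna_k_deg: float = 10.0  # 1/h, default mRNA decay constant
    default_mrna_rate: float = 1200.0  # translation initiations /mRNA/h
    default_trna_rate: float = 36000.0  # charging events /tRNA/h
    unmodeled_length: int = 300
    dummy_length: int = 300
    # lumped rRNA/tRNA maturation: optional enzyme catalyst and its k_cat
    maturation_enzyme: str | None = None
    maturation_kcat: float = 50000.0
    # metabolite ids in the metabolic layer
    atp: str = "atp_c"
    adp: str = "adp_c"
    pi: str = "pi_c"
    h2o: str = "h2o_c"
    ntp: str = "ntp_c"
    nmp: str = "nmp_c"
    aa_species: dict[str, str] = field(default_factory=dict)  # aa -> metabolite id

    def aa_id(self, aa: str) -> str:
        return self.aa_species.get(aa, f"{aa}_c")


# ---------------------------------------------------------------------------
# metabolic-layer reformulation


def split_reversible(model: StoichiometricModel) -> StoichiometricModel:
    """Split every reversible reaction into an irreversible forward/reverse
    pair; exchange reactions are split too.  The mapping original -> (forward,
    reverse) is stored on the returned model for net-flux reporting."""
    new = model.copy()
    for rid in list(new.reactions):
        rxn = new.reactions[rid]
        if rxn.lower_bound >= 0:
            new.split_map[rid] = (rid, None)
            continue
        rev = Reaction(
            id=f"{rid}_rev",
            stoichiometry={m: -c for m, c in rxn.stoichiometry.items()},
            lower_bound=0.0,
            upper_bound=-rxn.lower_bound,
            kind=rxn.kind,
            catalyst_id=rxn.catalyst_id,
            spontaneous=rxn.spontaneous,
            isozymes=list(rxn.isozymes),
            source_id=rid,
        )
        rxn.lower_bound = 0.0
        new.add_reaction(rev)
        new.split_map[rid] = (rid, rev.id)
        # a catalyst of the original catalyzes both directions at the same rate
        for enz in new.enzymes.values():
            if rid in enz.catalyzed:
                enz.catalyzed[rev.id] = enz.catalyzed[rid]
    return new


def split_isozymes(model: StoichiometricModel) -> StoichiometricModel:
    """Give every reaction with several alternative enzymes one copy per
    isozyme; copies share stoichiometry and bounds and sum to the original
    flux in reports."""
    new = model.copy()
    for rid in list(new.reactions):
        rxn = new.reactions[rid]
        if len(rxn.isozymes) <= 1:
            if len(rxn.isozymes) == 1:
                rxn.catalyst_id = rxn.isozymes[0]
            continue
        copies = []
        for eid in rxn.isozymes:
            cid = f"{rid}__{eid}"
            copy = Reaction(
                id=cid,
                stoichiometry=dict(rxn.stoichiometry),
                lower_bound=rxn.lower_bound,
                upper_bound=rxn.upper_bound,
                kind=rxn.kind,
                catalyst_id=eid,
                spontaneous=rxn.spontaneous,
                source_id=rxn.source_id,
            )
            new.add_reaction(copy)
            copies.append(cid)
            enz = new.enzymes[eid]
            if rid in enz.catalyzed:
                enz.catalyzed[cid] = enz.catalyzed.pop(rid)
        new.isozyme_map[rid] = copies
        del new.reactions[rid]
    return new


def assign_dummy(
    model: StoichiometricModel,
    k_cat: float | None = None,
    length: int = 300,
    k_deg: float = 0.0,
) -> StoichiometricModel:
    """Catalyze every non-spontaneous metabolic/transport reaction that lacks
    a catalyst with a shared dummy protein of average amino-acid composition.

    The dummy k_cat defaults to the median of all enzyme turnover numbers in
    the model, which biases the cost of unannotated reactions neither up nor
    down.
    """
    new = model.copy()
    if k_cat is None:
        kcats = [k for e in new.enzymes.values() for k in e.catalyzed.values()]
        k_cat = statistics.median(kcats) if kcats else 3.6e5
    orphans = [
        r.id
        for r in new.reactions.values()
        if r.kind in ("metabolic", "transport")
        and r.catalyst_id is None
        and not r.isozymes
        and not r.spontaneous
    ]
    if DUMMY_PROTEIN_ID not in new.proteins:
        comp = average_aa_composition(new.proteins.values(), length=length)
        new.proteins[DUMMY_PROTEIN_ID] = ProteinSpec.from_composition(
            DUMMY_PROTEIN_ID, comp, k_deg=k_deg
        )
    if DUMMY_ENZYME_ID not in new.enzymes:
        new.enzymes[DUMMY_ENZYME_ID] = EnzymeSpec(
            id=DUMMY_ENZYME_ID, subunits={DUMMY_PROTEIN_ID: 1}, catalyzed={}
        )
    for rid in orphans:
        new.reactions[rid].catalyst_id = DUMMY_ENZYME_ID
        new.enzymes[DUMMY_ENZYME_ID].catalyzed[rid] = k_cat
    return new


def protein_cost(
    enzyme: EnzymeSpec,
    reaction_id: str,
    proteins: dict[str, ProteinSpec],
) -> float:
    """Protein cost of a reaction: enzyme mass over turnover rate, in
    g protein x h / mmol of flux."""
    kcat = enzyme.catalyzed.get(reaction_id)
    if kcat is None or kcat <= 0:
        raise ModelValidationError(
            f"enzyme {enzyme.id} has no positive k_cat for reaction {reaction_id}"
        )
    return enzyme.mass(proteins) / kcat


# ---------------------------------------------------------------------------
# expression layer


def _derived_species(
    model: StoichiometricModel,
    species_id: str,
    stoich: dict[str, float],
    coeff: float,
    name: str = "",
) -> None:
    """Add ``species_id`` with the composition that closes the elemental and
    charge balance of a reaction producing ``coeff`` of it with the given
    partial stoichiometry."""
    comp: dict[str, float] = {}
    charge = 0.0
    for mid, c in stoich.items():
        met = model.metabolites[mid]
        for elem, n in met.elemental_composition.items():
            comp[elem] = comp.get(elem, 0.0) - c * n / coeff
        charge -= c * met.charge / coeff
    comp = {k: v for k, v in comp.items() if abs(v) > 1e-9}
    if any(v < -1e-9 for v in comp.values()):
        raise ModelValidationError(
            f"species {species_id}: derived composition has negative counts {comp}"
        )
    model.add_metabolite(
        Metabolite(
            id=species_id,
            name=name,
            compartment="cytosol",
            elemental_composition=comp,
            # averaged compositions (dummy, unmodeled) carry fractional charge
            charge=charge if abs(charge - round(charge)) > 1e-9 else round(charge),
        )
    )


def _atp_terms(cfg: ExpressionConfig, n: float) -> dict[str, float]:
    """ATP hydrolysis of n equivalents: atp + h2o -> adp + pi, n times."""
    return {cfg.atp: -n, cfg.h2o: -n, cfg.adp: n, cfg.pi: n}


def _merge(*terms: dict[str, float]) -> dict[str, float]:
    out: dict[str, float] = {}
    for t in terms:
        for k, v in t.items():
            out[k] = out.get(k, 0.0) + v
    return {k: v for k, v in out.items() if abs(v) > 1e-12}


def build_expression_layer(
    model: StoichiometricModel,
    machineries: dict[str, MachinerySpec],
    budget: ProteomeBudget,
    config: ExpressionConfig | None = None,
) -> PCModel:
    """Extend a (split, isozyme-resolved, dummy-assigned) metabolic model with
    the gene-expression layer and return the proteome-constrained model.

    Per protein-coding gene: transcription, mRNA degradation and dilution,
    translation, protein degradation and dilution.  Per amino acid of the
    model's alphabet: tRNA gene (transcription, lumped maturation, dilution)
    and a charging reaction.  Per enzyme: formation from subunits and
    dilution.  Ribosome (rRNA plus ribosomal proteins) and RNA polymerase are
    assembled from the compositions of the corresponding machinery specs.
    A model with zero proteins degenerates to the metabolic layer plus the
    budget.
    """
    cfg = config or ExpressionConfig()
    pc = PCModel(id=model.id + "_pc")
    base = model.copy()
    pc.metabolites = base.metabolites
    pc.reactions = base.reactions
    pc.enzymes = base.enzymes
    pc.proteins = base.proteins
    pc.split_map = base.split_map
    pc.isozyme_map = base.isozyme_map
    pc.machineries = dict(machineries)
    pc.budget = budget

    if not pc.proteins:
        return pc

    for p in pc.proteins.values():
        for aa in p.aa_composition:
            if aa not in AA_FORMULA:
                raise ModelValidationError(
                    f"protein {p.id}: no elemental formula for amino acid {aa!r}"
                )
    alphabet = sorted({aa for p in pc.proteins.values() for aa in p.aa_composition})

    def add_rxn(rid, stoich, kind="expression", catalyst=None, ub=1000.0, name=""):
        pc.add_reaction(
            Reaction(
                id=rid,
                stoichiometry=stoich,
                lower_bound=0.0,
                upper_bound=ub,
                kind=kind,
                catalyst_id=catalyst,
                name=name,
            )
        )
        return rid

    # -- tRNA pools -------------------------------------------------------
    for aa in alphabet:
        mid = f"trna:{aa}"
        if mid not in pc.machineries:
            pc.machineries[mid] = MachinerySpec(
                id=mid, catalytic_rate=cfg.default_trna_rate
            )
        L = cfg.trna_length_nt
        tx_stoich = {cfg.ntp: -L, cfg.pi: 2 * L}
        _derived_species(pc, f"pretrna_{aa}", tx_stoich, 1.0)
        tx_stoich[f"pretrna_{aa}"] = 1.0
        add_rxn(f"TXT_{aa}", tx_stoich, catalyst="rna_polymerase")
        pc.machinery_coupling.setdefault("rna_polymerase", []).append((f"TXT_{aa}", L))
        pre = pc.metabolites[f"pretrna_{aa}"]
        pc.add_metabolite(
            Metabolite(
                id=f"trna_{aa}",
                compartment="cytosol",
                elemental_composition=dict(pre.elemental_composition),
                charge=pre.charge,
            )
        )
        add_rxn(f"MATT_{aa}", {f"pretrna_{aa}": -1.0, f"trna_{aa}": 1.0})
        if cfg.maturation_enzyme:
            pc.enzymes[cfg.maturation_enzyme].catalyzed[f"MATT_{aa}"] = cfg.maturation_kcat
            pc.reactions[f"MATT_{aa}"].catalyst_id = cfg.maturation_enzyme
        add_rxn(f"TDIL_{aa}", {f"trna_{aa}": -1.0}, kind="dilution")
        pc.dilution_of[f"trna_{aa}"] = f"TDIL_{aa}"
        # charged tRNA carries the amino acid
        ch_stoich = _merge(
            {cfg.aa_id(aa): -1.0, f"trna_{aa}": -1.0},
            _atp_terms(cfg, cfg.atp_per_charging),
        )
        _derived_species(pc, f"trnac_{aa}", ch_stoich, 1.0)
        ch_stoich[f"trnac_{aa}"] = 1.0
        add_rxn(f"CH_{aa}", ch_stoich, catalyst=mid)
        pc.machinery_coupling.setdefault(mid, []).append((f"CH_{aa}", 1.0))

    # -- per-gene reactions ----------------------------------------------
    for pid, prot in pc.proteins.items():
        L = prot.length
        Lnt = cfg.nt_per_residue * L
        mid = f"mrna:{pid}"
        if mid not in pc.machineries:
            pc.machineries[mid] = MachinerySpec(
                id=mid, catalytic_rate=cfg.default_mrna_rate, k_deg=cfg.mrna_k_deg
            )
        tx_stoich = {cfg.ntp: -Lnt, cfg.pi: 2 * Lnt}
        _derived_species(pc, f"mrna_{pid}", tx_stoich, 1.0)
        tx_stoich[f"mrna_{pid}"] = 1.0
        add_rxn(f"TX_{pid}", tx_stoich, catalyst="rna_polymerase")
        pc.machinery_coupling.setdefault("rna_polymerase", []).append((f"TX_{pid}", Lnt))
        add_rxn(
            f"MDEG_{pid}",
            {f"mrna_{pid}": -1.0, cfg.nmp: Lnt},
            kind="degradation",
        )
        add_rxn(f"MDIL_{pid}", {f"mrna_{pid}": -1.0}, kind="dilution")
        pc.dilution_of[f"mrna_{pid}"] = f"MDIL_{pid}"
        pc.degradation_of[f"mrna_{pid}"] = f"MDEG_{pid}"
        pc.k_deg_of[f"mrna_{pid}"] = pc.machineries[mid].k_deg

        tl_stoich = _merge(
            {f"trnac_{aa}": -n for aa, n in prot.aa_composition.items()},
            {f"trna_{aa}": n for aa, n in prot.aa_composition.items()},
            _atp_terms(cfg, cfg.atp_per_elongation * L),
            {cfg.h2o: L - 1},
        )
        _derived_species(pc, f"protein_{pid}", tl_stoich, 1.0)
        tl_stoich[f"protein_{pid}"] = 1.0
        add_rxn(f"TL_{pid}", tl_stoich, catalyst="ribosome")
        pc.machinery_coupling.setdefault("ribosome", []).append((f"TL_{pid}", L))
        pc.machinery_coupling.setdefault(mid, []).append((f"TL_{pid}", 1.0))

        deg_stoich = _merge(
            {f"protein_{pid}": -1.0, cfg.h2o: -(L - 1)},
            {cfg.aa_id(aa): n for aa, n in prot.aa_composition.items()},
            _atp_terms(cfg, cfg.atp_per_degradation * L),
        )
        add_rxn(f"PDEG_{pid}", deg_stoich, kind="degradation")
        add_rxn(f"PDIL_{pid}", {f"protein_{pid}": -1.0}, kind="dilution")
        pc.dilution_of[f"protein_{pid}"] = f"PDIL_{pid}"
        pc.degradation_of[f"protein_{pid}"] = f"PDEG_{pid}"
        pc.k_deg_of[f"protein_{pid}"] = prot.k_deg
        pc.protein_mass_of[f"protein_{pid}"] = prot.molecular_weight

    # -- rRNA and machinery complexes ------------------------------------
    for mach_id, species_id, asm_id, dil_id in (
        ("ribosome", "ribosome", "RIBASM", "RIBDIL"),
        ("rna_polymerase", "rnap", "RNAPASM", "RNAPDIL"),
    ):
        mach = pc.machineries.get(mach_id)
        if mach is None:
            raise ModelValidationError(f"machinery {mach_id!r} is required")
        stoich: dict[str, float] = {}
        pmass = 0.0
        for part, n in mach.composition.items():
            if part == "rrna":
                if "rrna" not in pc.metabolites:
                    Lr = cfg.rrna_length_nt
                    txr = {cfg.ntp: -Lr, cfg.pi: 2 * Lr}
                    _derived_species(pc, "prerrna", txr, 1.0)
                    txr["prerrna"] = 1.0
                    add_rxn("TXR", txr, catalyst="rna_polymerase")
                    pc.machinery_coupling.setdefault("rna_polymerase", []).append(
                        ("TXR", Lr)
                    )
                    pre = pc.metabolites["prerrna"]
                    pc.add_metabolite(
                        Metabolite(
                            id="rrna",
                            compartment="cytosol",
                            elemental_composition=dict(pre.elemental_composition),
                            charge=pre.charge,
                        )
                    )
                    add_rxn("MATR", {"prerrna": -1.0, "rrna": 1.0})
                    if cfg.maturation_enzyme:
                        pc.enzymes[cfg.maturation_enzyme].catalyzed[
                            "MATR"
                        ] = cfg.maturation_kcat
                        pc.reactions["MATR"].catalyst_id = cfg.maturation_enzyme
                stoich["rrna"] = -float(n)
            else:
                stoich[f"protein_{part}"] = -float(n)
                pmass += n * pc.proteins[part].molecular_weight
        _derived_species(pc, species_id, stoich, 1.0)
        stoich[species_id] = 1.0
        add_rxn(asm_id, stoich)
        add_rxn(dil_id, {species_id: -1.0}, kind="dilution")
        pc.dilution_of[species_id] = dil_id
        pc.protein_mass_of[species_id] = pmass
        pc.k_deg_of[species_id] = mach.k_deg

    # -- enzymes ----------------------------------------------------------
    for eid, enz in pc.enzymes.items():
        stoich = {f"protein_{pid}": -float(n) for pid, n in enz.subunits.items()}
        _derived_species(pc, f"enz_{eid}", stoich, 1.0)
        stoich[f"enz_{eid}"] = 1.0
        add_rxn(f"FORM_{eid}", stoich)
        add_rxn(f"EDIL_{eid}", {f"enz_{eid}": -1.0}, kind="dilution")
        pc.dilution_of[f"enz_{eid}"] = f"EDIL_{eid}"
        pc.protein_mass_of[f"enz_{eid}"] = enz.mass(pc.proteins)
        for rid, kcat in enz.catalyzed.items():
            if rid in pc.reactions:
                pc.catalytic_coupling[rid] = (f"enz_{eid}", kcat)

    # -- unmodeled protein -------------------------------------------------
    avg = average_aa_composition(
        (p for p in pc.proteins.values() if p.id != DUMMY_PROTEIN_ID),
        length=cfg.unmodeled_length,
    )
    Lu = sum(avg.values())
    mw_unmod = residue_mass(avg)
    un_stoich = _merge(
        {cfg.aa_id(aa): -n for aa, n in avg.items()},
        _atp_terms(cfg, cfg.atp_per_unmodeled_residue * Lu),
        {cfg.h2o: Lu - 1},
    )
    _derived_species(pc, "unmodeled", un_stoich, 1.0)
    un_stoich["unmodeled"] = 1.0
    add_rxn("UNMOD", un_stoich)
    add_rxn("UNMODDIL", {"unmodeled": -1.0}, kind="dilution")
    pc.dilution_of["unmodeled"] = "UNMODDIL"
    if budget.unmodeled_mass > 0:
        pc.growth_pinned["UNMOD"] = budget.unmodeled_mass / mw_unmod

    if DUMMY_PROTEIN_ID in pc.proteins:
        pc.dummy_protein = DUMMY_PROTEIN_ID
        pc.objective_reaction = f"TL_{DUMMY_PROTEIN_ID}"

    pc.check_balances(elements=("C", "N", "H", "P"))
    return pc
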