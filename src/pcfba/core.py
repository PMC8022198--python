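"""Core domain types for two-layer (metabolic + gene expression) models.

A :class:`StoichiometricModel` is the conventional constraint-based layer:
metabolites, reactions with flux bounds, and gene-protein-reaction links
expressed through :class:`EnzymeSpec` objects.  A :class:`PCModel` extends it
with the expression layer (transcription, translation, degradation, dilution
reactions), the catalytic machinery, and a proteome budget, so that metabolic
flux is coupled to the synthesis cost of its own catalysts.

Units follow the conventions of constraint-based modeling of bacteria:
fluxes in mmol/gCDW/h, catalyst concentrations in mmol/gCDW, molecular
weights in g/mmol, and all rate constants (k_cat, k_deg, machinery rates)
in 1/h.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "Metabolite",
    "Reaction",
    "ProteinSpec",
    "EnzymeSpec",
    "MachinerySpec",
    "ProteomeBudget",
    "StoichiometricModel",
    "PCModel",
    "ModelValidationError",
    "AA_RESIDUE_MASS",
    "AA_FORMULA",
    "average_aa_composition",
    "residue_mass",
]

COMPARTMENTS = ("cytosol", "membrane", "extracellular")

REACTION_KINDS = (
    "metabolic",
    "exchange",
    "transport",
    "expression",
    "dilution",
    "degradation",
    "maintenance",
    "biomass",
)

#: Reaction kinds that move mass across the system boundary (medium or
#: daughter cells) and are therefore exempt from elemental-balance checks.
UNBALANCED_KINDS = frozenset({"exchange", "biomass", "dilution"})

#: Average residue masses (g/mmol), monoisotopic-free standard values.
AA_RESIDUE_MASS: dict[str, float] = {
    "ala": 0.07108,
    "arg": 0.15619,
    "asn": 0.11410,
    "asp": 0.11509,
    "cys": 0.10314,
    "gln": 0.12814,
    "glu": 0.12912,
    "gly": 0.05705,
    "his": 0.13714,
    "ile": 0.11316,
    "leu": 0.11316,
    "lys": 0.12817,
    "met": 0.13119,
    "phe": 0.14718,
    "pro": 0.09712,
    "ser": 0.08708,
    "thr": 0.10110,
    "trp": 0.18621,
    "tyr": 0.16318,
    "val": 0.09913,
}

#: Free amino-acid elemental formulas and charges at pH 7 (cationic side
#: chains protonated).  Only the residues used by the bundled fixtures need
#: to appear here; models may extend the table.
AA_FORMULA: dict[str, tuple[dict[str, int], int]] = {
    "ala": ({"C": 3, "H": 7, "N": 1, "O": 2}, 0),
    "arg": ({"C": 6, "H": 15, "N": 4, "O": 2}, 1),
    "ser": ({"C": 3, "H": 7, "N": 1, "O": 3}, 0),
    "leu": ({"C": 6, "H": 13, "N": 1, "O": 2}, 0),
    "gly": ({"C": 2, "H": 5, "N": 1, "O": 2}, 0),
    "lys": ({"C": 6, "H": 15, "N": 2, "O": 2}, 1),
}


class ModelValidationError(ValueError):
    """A model or one of its components violates a structural invariant."""


def residue_mass(aa_composition: Mapping[str, float]) -> float:
    """Protein mass (g/mmol) from a residue-count composition.

    Sums average residue masses and adds one water for the free termini.
    """
    mass = sum(AA_RESIDUE_MASS[aa] * n for aa, n in aa_composition.items())
    return mass + 0.01802


def average_aa_composition(
    proteins: Iterable["ProteinSpec"], length: int = 300
) -> dict[str, float]:
    """Model-wide average amino-acid composition scaled to ``length`` residues.

    Used for the dummy protein, the unmodeled-protein species, and the
    inactive-enzyme sink, all of which the framework represents with average
    composition.
    """
    totals: dict[str, float] = {}
    grand = 0.0
    for p in proteins:
        for aa, n in p.aa_composition.items():
            totals[aa] = totals.get(aa, 0.0) + n
            grand += n
    if grand == 0:
        raise ModelValidationError("cannot average over zero residues")
    return {aa: length * n / grand for aa, n in totals.items()}


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "cytosol"
    elemental_composition: dict[str, float] = field(default_factory=dict)
    charge: int = 0

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise ModelValidationError(
                f"metabolite {self.id}: unknown compartment {self.compartment!r}"
            )
        for elem, n in self.elemental_composition.items():
            if n < 0:
                raise ModelValidationError(
                    f"metabolite {self.id}: negative count for element {elem}"
                )


@dataclass
class Reaction:
    """A reaction over metabolite ids with signed stoichiometric coefficients.

    ``catalyst_id`` names the :class:`EnzymeSpec` or :class:`MachinerySpec`
    that carries the flux; ``spontaneous`` marks reactions that legitimately
    proceed uncatalyzed (and are therefore skipped by dummy-protein
    assignment).  ``isozymes`` lists alternative catalysts prior to isozyme
    splitting.  ``source_id`` tracks the pre-split reaction for net-flux
    reporting.
    """

    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = 1000.0
    kind: str = "metabolic"
    catalyst_id: str | None = None
    spontaneous: bool = False
    isozymes: list[str] = field(default_factory=list)
    source_id: str | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if self.kind not in REACTION_KINDS:
            raise ModelValidationError(f"reaction {self.id}: unknown kind {self.kind!r}")
        if self.lower_bound > self.upper_bound:
            raise ModelValidationError(
                f"reaction {self.id}: lower_bound {self.lower_bound} exceeds "
                f"upper_bound {self.upper_bound}"
            )
        if self.source_id is None:
            self.source_id = self.id

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0

    def imbalance(self, metabolites: Mapping[str, Metabolite]) -> dict[str, float]:
        """Net element (and charge) production of the reaction.

        Returns an empty dict for a balanced reaction.  Exchange, biomass and
        dilution reactions move mass across the system boundary and are
        reported as balanced by convention.
        """
        if self.kind in UNBALANCED_KINDS:
            return {}
        net: dict[str, float] = {}
        for met_id, coeff in self.stoichiometry.items():
            met = metabolites[met_id]
            for elem, n in met.elemental_composition.items():
                net[elem] = net.get(elem, 0.0) + coeff * n
            net["charge"] = net.get("charge", 0.0) + coeff * met.charge
        return {k: v for k, v in net.items() if abs(v) > 1e-9}


@dataclass
class ProteinSpec:
    id: str
    molecular_weight: float  # g/mmol
    aa_composition: dict[str, float]  # residues per molecule
    k_deg: float = 0.0  # 1/h

    def __post_init__(self) -> None:
        if self.molecular_weight <= 0:
            raise ModelValidationError(f"protein {self.id}: molecular_weight must be > 0")
        if self.k_deg < 0:
            raise ModelValidationError(f"protein {self.id}: k_deg must be >= 0")
        expected = residue_mass(self.aa_composition)
        if abs(expected - self.molecular_weight) > 0.05 * expected:
            raise ModelValidationError(
                f"protein {self.id}: molecular_weight {self.molecular_weight:.4f} "
                f"inconsistent with residue-mass sum {expected:.4f} (>5%)"
            )

    @property
    def length(self) -> float:
        return sum(self.aa_composition.values())

    @classmethod
    def from_composition(
        cls, id: str, aa_composition: Mapping[str, float], k_deg: float = 0.0
    ) -> "ProteinSpec":
        comp = dict(aa_composition)
        return cls(id=id, molecular_weight=residue_mass(comp), aa_composition=comp, k_deg=k_deg)


@dataclass
class EnzymeSpec:
    id: str
    subunits: dict[str, int]  # ProteinSpec id -> count
    catalyzed: dict[str, float]  # reaction id -> k_cat (1/h)

    def __post_init__(self) -> None:
        for pid, n in self.subunits.items():
            if not (isinstance(n, (int, np.integer)) and n > 0):
                raise ModelValidationError(
                    f"enzyme {self.id}: subunit count for {pid} must be a positive integer"
                )
        for rid, kcat in self.catalyzed.items():
            if kcat <= 0:
                raise ModelValidationError(
                    f"enzyme {self.id}: k_cat for {rid} must be > 0"
                )

    def mass(self, proteins: Mapping[str, ProteinSpec]) -> float:
        """Enzyme mass in g/mmol: sum of subunit count x molecular weight."""
        return sum(n * proteins[pid].molecular_weight for pid, n in self.subunits.items())


@dataclass
class MachinerySpec:
    """A gene-expression machine: ribosome, RNA polymerase, an mRNA, or a tRNA.

    ``catalytic_rate`` is in events per machine per hour: amino acids
    polymerized (ribosome), nucleotides polymerized (RNA polymerase),
    translation initiations supported (mRNA), or charging events (tRNA).
    """

    id: str
    catalytic_rate: float
    composition: dict[str, float] = field(default_factory=dict)
    k_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.catalytic_rate <= 0:
            raise ModelValidationError(
                f"machinery {self.id}: catalytic_rate must be > 0"
            )
        if self.k_deg < 0:
            raise ModelValidationError(f"machinery {self.id}: k_deg must be >= 0")


@dataclass
class ProteomeBudget:
    total_modeled_fraction: float  # g modeled protein / gCDW
    unmodeled_fraction: float = 0.0  # share of total protein outside the model
    transporter_cap: float = 1.0  # mmol/gCDW cap on the glucose transporter

    def __post_init__(self) -> None:
        if self.total_modeled_fraction <= 0:
            raise ModelValidationError("total_modeled_fraction must be > 0")
        if not 0 <= self.unmodeled_fraction < 1:
            raise ModelValidationError("unmodeled_fraction must be in [0, 1)")
        if self.transporter_cap <= 0:
            raise ModelValidationError("transporter_cap must be > 0")

    @property
    def total_protein(self) -> float:
        """Total protein (g/gCDW) implied by the modeled fraction."""
        return self.total_modeled_fraction / (1.0 - self.unmodeled_fraction)

    @property
    def unmodeled_mass(self) -> float:
        """Unmodeled protein mass (g/gCDW), of average amino-acid composition."""
        return self.total_protein * self.unmodeled_fraction


@dataclass
class StoichiometricModel:
    """The conventional model layer: metabolites, reactions, enzyme links."""

    id: str = "model"
    metabolites: dict[str, Metabolite] = field(default_factory=dict)
    reactions: dict[str, Reaction] = field(default_factory=dict)
    enzymes: dict[str, EnzymeSpec] = field(default_factory=dict)
    proteins: dict[str, ProteinSpec] = field(default_factory=dict)
    #: original reaction id -> (forward id, reverse id or None)
    split_map: dict[str, tuple[str, str | None]] = field(default_factory=dict)
    #: original reaction id -> list of per-isozyme copies
    isozyme_map: dict[str, list[str]] = field(default_factory=dict)

    def add_metabolite(self, met: Metabolite) -> None:
        if met.id in self.metabolites:
            raise ModelValidationError(f"duplicate metabolite id {met.id}")
        self.metabolites[met.id] = met

    def add_reaction(self, rxn: Reaction) -> None:
        if rxn.id in self.reactions:
            raise ModelValidationError(f"duplicate reaction id {rxn.id}")
        missing = [m for m in rxn.stoichiometry if m not in self.metabolites]
        if missing:
            raise ModelValidationError(
                f"reaction {rxn.id}: unknown metabolites {missing}"
            )
        self.reactions[rxn.id] = rxn

    def stoichiometric_matrix(self) -> tuple[np.ndarray, list[str], list[str]]:
        """Dense S matrix plus row (metabolite) and column (reaction) ids."""
        met_ids = list(self.metabolites)
        rxn_ids = list(self.reactions)
        row = {m: i for i, m in enumerate(met_ids)}
        S = np.zeros((len(met_ids), len(rxn_ids)))
        for j, rid in enumerate(rxn_ids):
            for met_id, coeff in self.reactions[rid].stoichiometry.items():
                S[row[met_id], j] = coeff
        return S, met_ids, rxn_ids

    def check_balances(self, elements: tuple[str, ...] = ("C", "N")) -> None:
        """Raise if any non-boundary reaction leaves an element unconserved."""
        problems = []
        for rxn in self.reactions.values():
            bad = {
                k: v
                for k, v in rxn.imbalance(self.metabolites).items()
                if k in elements or k == "charge"
            }
            if bad:
                problems.append(f"{rxn.id}: {bad}")
        if problems:
            raise ModelValidationError(
                "unbalanced reactions:\n  " + "\n  ".join(problems)
            )

    def net_fluxes(self, fluxes: Mapping[str, float]) -> dict[str, float]:
        """Collapse split forward/reverse pairs and isozyme copies back to the
        original reaction ids (net = forward - reverse, sum over isozymes)."""
        net: dict[str, float] = {}
        for rid, v in fluxes.items():
            rxn = self.reactions.get(rid)
            src = rxn.source_id if rxn is not None else rid
            sign = -1.0 if rid.endswith("_rev") else 1.0
            net[src] = net.get(src, 0.0) + sign * v
        return net

    def copy(self) -> "StoichiometricModel":
        new = StoichiometricModel(id=self.id)
        new.metabolites = {k: replace(v) for k, v in self.metabolites.items()}
        new.reactions = {
            k: replace(v, stoichiometry=dict(v.stoichiometry), isozymes=list(v.isozymes))
            for k, v in self.reactions.items()
        }
        new.enzymes = {
            k: replace(v, subunits=dict(v.subunits), catalyzed=dict(v.catalyzed))
            for k, v in self.enzymes.items()
        }
        new.proteins = {
            k: replace(v, aa_composition=dict(v.aa_composition))
            for k, v in self.proteins.items()
        }
        new.split_map = dict(self.split_map)
        new.isozyme_map = {k: list(v) for k, v in self.isozyme_map.items()}
        return new


@dataclass
class PCModel(StoichiometricModel):
    """A proteome-constrained model: metabolic plus expression layer.

    In addition to the :class:`StoichiometricModel` fields it carries the
    machinery specifications, the proteome budget, identifiers of the special
    reactions/species the simulation layer needs, and glucose-transport
    kinetics.  ``protein_mass_of`` maps every protein-containing species id
    (free proteins, enzymes, machinery complexes) to its protein mass in
    g/mmol, and is the basis of proteome accounting.
    """

    machineries: dict[str, MachinerySpec] = field(default_factory=dict)
    budget: ProteomeBudget | None = None

    # special ids wired up by the builder / fixture
    biomass_reaction: str | None = None
    biomass_coefficient: float = 0.0  # mmol biomass species per gCDW
    maintenance_reaction: str | None = None
    dummy_protein: str | None = None
    objective_reaction: str | None = None  # dummy-protein production
    glucose_transport_reaction: str | None = None
    glucose_transporter: str | None = None  # enzyme id under the abundance cap
    kcat_transporter: float = 0.0  # 1/h
    km_glucose: float = 1.0  # mM
    blocked_reactions: list[str] = field(default_factory=list)
    #: amino acid -> (slope, intercept) of the growth-rate-dependent uptake
    #: upper bound, mmol/gCDW/h per unit growth rate and absolute.
    uptake_bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    #: uptake (exchange) reaction id per bounded compound
    uptake_reactions: dict[str, str] = field(default_factory=dict)
    #: species id -> protein mass (g/mmol) counted against the budget
    protein_mass_of: dict[str, float] = field(default_factory=dict)
    #: species id -> dilution reaction id (concentration = v_dil / mu)
    dilution_of: dict[str, str] = field(default_factory=dict)
    #: species id -> degradation reaction id (flux tied to k_deg/mu x dilution)
    degradation_of: dict[str, str] = field(default_factory=dict)
    #: species id -> degradation rate constant (1/h)
    k_deg_of: dict[str, float] = field(default_factory=dict)
    #: reaction id -> (catalyst species id, k_cat) capacity couplings
    catalytic_coupling: dict[str, tuple[str, float]] = field(default_factory=dict)
    #: machinery id -> list of (reaction id, weight) for capacity rows,
    #: e.g. ribosome: (translation reaction, protein length)
    machinery_coupling: dict[str, list[tuple[str, float]]] = field(default_factory=dict)
    #: flux pinned to mu x value (reaction id -> mmol/gCDW per gCDW of cells)
    growth_pinned: dict[str, float] = field(default_factory=dict)

    def copy(self) -> "PCModel":  # type: ignore[override]
        base = StoichiometricModel.copy(self)
        new = PCModel(id=self.id)
        new.__dict__.update(base.__dict__)
        new.machineries = {
            k: replace(v, composition=dict(v.composition))
            for k, v in self.machineries.items()
        }
        new.budget = replace(self.budget) if self.budget else None
        for attr in (
            "biomass_reaction",
            "biomass_coefficient",
            "maintenance_reaction",
            "dummy_protein",
            "objective_reaction",
            "glucose_transport_reaction",
            "glucose_transporter",
            "kcat_transporter",
            "km_glucose",
        ):
            setattr(new, attr, getattr(self, attr))
        new.blocked_reactions = list(self.blocked_reactions)
        new.uptake_bounds = dict(self.uptake_bounds)
        new.uptake_reactions = dict(self.uptake_reactions)
        new.protein_mass_of = dict(self.protein_mass_of)
        new.dilution_of = dict(self.dilution_of)
        new.degradation_of = dict(self.degradation_of)
        new.k_deg_of = dict(self.k_deg_of)
        new.catalytic_coupling = dict(self.catalytic_coupling)
        new.machinery_coupling = {k: list(v) for k, v in self.machinery_coupling.items()}
        new.growth_pinned = dict(self.growth_pinned)
        return new
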