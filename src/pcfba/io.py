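"""Model interchange: a documented JSON schema plus TSV parameter tables.

The JSON document has top-level keys ``metabolites``, ``reactions``,
``proteins``, ``enzymes``, ``machineries`` and ``budget``; identifiers are
ASCII with compartments as suffix tags (_c cytosol, _m membrane, _e
extracellular).  Enzyme kinetic parameters can also be round-tripped as a
TSV table with one row per (enzyme, reaction): reaction id, k_cat (1/h),
enzyme molecular weight (g/mmol), and subunit k_deg (1/h).

The metabolic layer of an SBML (constraint-based dialect) model can be
imported through cobrapy when it is installed; expression-layer constructs
have no SBML counterpart and always travel through the JSON schema.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd

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

__all__ = [
    "model_to_dict",
    "model_from_dict",
    "save_model",
    "load_model",
    "enzyme_table",
    "load_enzyme_table",
    "import_sbml",
    "result_frame",
]

_COMPARTMENT_TAGS = {"c": "cytosol", "m": "membrane", "e": "extracellular"}


def model_to_dict(model: StoichiometricModel) -> dict:
    doc: dict = {
        "id": model.id,
        "metabolites": [dataclasses.asdict(m) for m in model.metabolites.values()],
        "reactions": [dataclasses.asdict(r) for r in model.reactions.values()],
        "proteins": [dataclasses.asdict(p) for p in model.proteins.values()],
        "enzymes": [dataclasses.asdict(e) for e in model.enzymes.values()],
    }
    if isinstance(model, PCModel):
        doc["machineries"] = [
            dataclasses.asdict(m) for m in model.machineries.values()
        ]
        if model.budget is not None:
            doc["budget"] = dataclasses.asdict(model.budget)
        doc["pc"] = {
            k: getattr(model, k)
            for k in (
                "biomass_reaction", "biomass_coefficient", "maintenance_reaction",
                "dummy_protein", "objective_reaction", "glucose_transport_reaction",
                "glucose_transporter", "kcat_transporter", "km_glucose",
                "blocked_reactions", "uptake_bounds", "uptake_reactions",
                "protein_mass_of", "dilution_of", "degradation_of", "k_deg_of",
                "catalytic_coupling", "machinery_coupling", "growth_pinned",
                "split_map", "isozyme_map",
            )
        }
    return doc


def model_from_dict(doc: dict) -> StoichiometricModel:
    cls = PCModel if "pc" in doc or "machineries" in doc else StoichiometricModel
    model = cls(id=doc.get("id", "model"))
    for m in doc.get("metabolites", []):
        model.add_metabolite(Metabolite(**m))
    for r in doc.get("reactions", []):
        model.add_reaction(Reaction(**r))
    for p in doc.get("proteins", []):
        model.proteins[p["id"]] = ProteinSpec(**p)
    for e in doc.get("enzymes", []):
        model.enzymes[e["id"]] = EnzymeSpec(**e)
    if isinstance(model, PCModel):
        for m in doc.get("machineries", []):
            model.machineries[m["id"]] = MachinerySpec(**m)
        if "budget" in doc:
            model.budget = ProteomeBudget(**doc["budget"])
        pc = doc.get("pc", {})
        for k, v in pc.items():
            if k in ("uptake_bounds", "catalytic_coupling", "split_map"):
                v = {kk: tuple(vv) for kk, vv in v.items()}
            elif k == "machinery_coupling":
                v = {kk: [tuple(t) for t in vv] for kk, vv in v.items()}
            setattr(model, k, v)
    return model


def save_model(model: StoichiometricModel, path: str | Path) -> None:
    Path(path).write_text(json.dumps(model_to_dict(model), indent=1))


def load_model(path: str | Path) -> StoichiometricModel:
    return model_from_dict(json.loads(Path(path).read_text()))


def enzyme_table(model: StoichiometricModel) -> pd.DataFrame:
    """One row per (enzyme, reaction): k_cat, enzyme mass, mean subunit
    k_deg."""
    rows = []
    for eid, enz in model.enzymes.items():
        mass = enz.mass(model.proteins)
        kdegs = [model.proteins[p].k_deg for p in enz.subunits]
        for rid, kcat in enz.catalyzed.items():
            rows.append(
                {
                    "enzyme": eid,
                    "reaction": rid,
                    "k_cat_per_h": kcat,
                    "mw_g_per_mmol": mass,
                    "k_deg_per_h": sum(kdegs) / len(kdegs) if kdegs else 0.0,
                }
            )
    return pd.DataFrame(rows)


def load_enzyme_table(model: StoichiometricModel, path: str | Path) -> None:
    """Update k_cat values in place from a TSV written by
    :func:`enzyme_table` (columns enzyme, reaction, k_cat_per_h)."""
    frame = pd.read_csv(path, sep="\t")
    for row in frame.itertuples():
        enz = model.enzymes.get(row.enzyme)
        if enz is not None and row.reaction in enz.catalyzed:
            enz.catalyzed[row.reaction] = float(row.k_cat_per_h)


def import_sbml(path: str | Path) -> StoichiometricModel:
    """Import the metabolic layer of an SBML constraint-based model.

    Requires cobrapy.  Gene associations are flattened: each reaction's
    alternative gene sets become entries of ``Reaction.isozymes`` named
    after the genes; kinetic parameters must be supplied separately.
    """
    try:
        import cobra.io
    except ImportError as exc:  # pragma: no cover
        raise ImportError("SBML import requires the cobra package") from exc
    cb = cobra.io.read_sbml_model(str(path))
    model = StoichiometricModel(id=cb.id or "sbml_model")
    for met in cb.metabolites:
        comp = _COMPARTMENT_TAGS.get(str(met.compartment)[:1].lower(), "cytosol")
        model.add_metabolite(
            Metabolite(
                id=met.id,
                name=met.name or "",
                compartment=comp,
                elemental_composition=dict(met.elements or {}),
                charge=int(met.charge or 0),
            )
        )
    for rxn in cb.reactions:
        kind = "exchange" if rxn.boundary else "metabolic"
        model.add_reaction(
            Reaction(
                id=rxn.id,
                stoichiometry={m.id: c for m, c in rxn.metabolites.items()},
                lower_bound=rxn.lower_bound,
                upper_bound=rxn.upper_bound,
                kind=kind,
                isozymes=[
                    "_and_".join(sorted(g.id for g in gs))
                    for gs in _gene_sets(rxn)
                ],
                name=rxn.name or "",
            )
        )
    return model


def _gene_sets(rxn) -> list[frozenset]:
    """Alternative gene sets (isozymes) of a cobra reaction's GPR."""
    try:
        from cobra.core.gene import GPR  # noqa: F401

        rule = rxn.gene_reaction_rule
    except Exception:  # pragma: no cover
        rule = ""
    if not rule:
        return []
    alts = []
    for clause in rule.replace("(", "").replace(")", "").split(" or "):
        genes = frozenset(
            g for g in (t.strip() for t in clause.split(" and ")) if g
        )
        if genes:
            alts.append({gid: None for gid in sorted(genes)}.keys())
    return [frozenset(a) for a in alts]


def result_frame(result, model: PCModel) -> pd.DataFrame:
    """Tidy per-reaction table of a simulation result: flux, catalyst and
    catalyst concentration; the TSV schema of the command-line tool."""
    rows = []
    for rid, v in result.fluxes.items():
        rxn = model.reactions[rid]
        species = None
        if rid in model.catalytic_coupling:
            species = model.catalytic_coupling[rid][0]
        rows.append(
            {
                "reaction": rid,
                "kind": rxn.kind,
                "flux": v,
                "catalyst": species or "",
                "concentration": result.concentrations.get(species, float("nan"))
                if species
                else float("nan"),
            }
        )
    return pd.DataFrame(rows)
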