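"""Shared fixtures: the toy network, its proteome-constrained form, and
derived pathway parameters are expensive enough to build once per session."""

from __future__ import annotations

import pytest

from pcfba import make_toy_network, make_toy_pcmodel
from pcfba.small_model import estimate_pathway_params


@pytest.fixture(scope="session")
def toy_network():
    """Metabolic layer of the toy fermenter (pre-split, with enzymes)."""
    return make_toy_network()


@pytest.fixture(scope="session")
def toy_pc():
    """Fully built proteome-constrained toy model with calibrated
    glucose-transporter cap."""
    return make_toy_pcmodel(calibrate=True)


@pytest.fixture(scope="session")
def toy_params(toy_network):
    """Small-model pathway parameters estimated from the toy network."""
    return estimate_pathway_params(toy_network)


def cobra_from_model(model):
    """Convert a metabolic StoichiometricModel to a cobra model; used as an
    independent LP oracle (different solver, different code path)."""
    import cobra

    cb = cobra.Model(model.id)
    mets = {
        mid: cobra.Metabolite(mid, compartment=m.compartment[0])
        for mid, m in model.metabolites.items()
    }
    rxns = []
    for rid, r in model.reactions.items():
        rx = cobra.Reaction(rid)
        rx.lower_bound = r.lower_bound
        rx.upper_bound = r.upper_bound if r.upper_bound is not None else 1e6
        rxns.append(rx)
    cb.add_reactions(rxns)
    for rid, r in model.reactions.items():
        cb.reactions.get_by_id(rid).add_metabolites(
            {mets[mid]: c for mid, c in r.stoichiometry.items()}
        )
    return cb
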