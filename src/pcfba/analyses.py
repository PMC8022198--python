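"""Sensitivity machinery for proteome-constrained models.

Three related local analyses, all asking how much the growth rate would
gain from relaxing a constraint:

* scaled reduced costs R = (dmu/dq)(q/mu) for amino-acid uptake bounds,
  probed with a small absolute increase dq (default 0.01 mmol/gCDW/h);
* sensitivity scores S = (dmu/dc)(c/mu) for the two structural
  constraints — the glucose-transporter abundance cap and the modeled
  proteome size — probed with a small relative increase (default 1%);
* a one-at-a-time robustness scan that varies every model parameter
  twofold in both directions and records the resulting growth-rate change.

Perturbed growth rates are recomputed by re-solving (finite differences)
rather than read from solver duals, which is robust to the degeneracy
typical of these LPs; the exact dual of the uptake bound is retained for an
independent cross-check of the finite-difference route.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import pandas as pd

from ._lp import SolverError
from .core import PCModel
from .simulation import (
    GrowthInfeasibleError,
    assemble_lp,
    max_growth_rate,
    solve_at,
)
from ._lp import solve_lp

__all__ = [
    "Condition",
    "ReducedCost",
    "SensitivityScore",
    "scaled_reduced_cost",
    "sensitivity_score",
    "robustness_scan",
    "dual_reduced_cost",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Condition:
    """A reference chemostat condition: fixed extracellular glucose S
    (None = saturating, the rich-medium condition)."""

    S: float | None = None
    label: str = ""


@dataclass
class ReducedCost:
    target: str  # bounded compound (uptake reaction)
    R: float  # dimensionless scaled reduced cost
    delta_q: float
    mu_base: float
    mu_perturbed: float
    q_base: float
    unscaled: bool = False  # q was 0; R holds the unscaled dmu/dq


@dataclass
class SensitivityScore:
    constraint: str
    score: float
    delta_c: float
    mu_base: float
    mu_perturbed: float


def _base_mu(model: PCModel, condition: Condition, tol: float) -> float:
    mu, _ = max_growth_rate(model, condition.S, tol=tol)
    return mu


def scaled_reduced_cost(
    model: PCModel,
    condition: Condition,
    compound: str,
    delta_q: float = 0.01,
    tol: float = 1e-5,
) -> ReducedCost:
    """Scaled reduced cost R = (dmu/dq)(q/mu) of one uptake bound.

    The bound of ``compound`` is raised by the absolute amount ``delta_q``
    above its value at the base optimum and the maximal growth rate is
    re-solved at the condition's glucose setting.
    """
    if compound not in model.uptake_bounds:
        raise ValueError(f"no uptake bound for {compound!r}")
    mu0, res0 = max_growth_rate(model, condition.S, tol=tol)
    slope, intercept = model.uptake_bounds[compound]
    q0 = max(0.0, slope * mu0 + intercept)
    pert = model.copy()
    pert.uptake_bounds[compound] = (slope, intercept + delta_q)
    try:
        mu1, _ = max_growth_rate(pert, condition.S, tol=tol)
    except GrowthInfeasibleError as exc:
        raise GrowthInfeasibleError(f"base condition infeasible: {exc}") from exc
    dmu_dq = (mu1 - mu0) / delta_q
    if q0 <= 0:
        return ReducedCost(compound, dmu_dq, delta_q, mu0, mu1, q0, unscaled=True)
    return ReducedCost(compound, dmu_dq * q0 / mu0, delta_q, mu0, mu1, q0)


def dual_reduced_cost(
    model: PCModel,
    condition: Condition,
    compound: str,
    mu: float | None = None,
    dmu: float = 1e-4,
) -> float:
    """Dual-route estimate of the scaled reduced cost, for cross-checking.

    The growth maximum mu*(q) is the root of g(mu, q) = 0, where g is the
    optimal dummy-protein production at fixed mu (negative means
    infeasible, encoded through the feasibility boundary).  By the implicit
    function theorem dmu/dq = -(dg/dq)/(dg/dmu); dg/dq is the exact LP dual
    of the uptake bound at fixed mu, dg/dmu a central difference of the
    value function.  The q-direction therefore never uses finite
    differences, keeping this estimate independent of
    :func:`scaled_reduced_cost`.
    """
    if mu is None:
        mu = _base_mu(model, condition, tol=1e-6)
    rid = model.uptake_reactions[compound]
    slope, intercept = model.uptake_bounds[compound]
    q0 = max(0.0, slope * mu + intercept)

    def value(mu_probe: float) -> float:
        # hold the uptake bound at its base-mu value so only mu varies
        lp = assemble_lp(
            model, mu_probe, condition.S,
            uptake_overrides={c: max(0.0, s * mu + i)
                              for c, (s, i) in model.uptake_bounds.items()},
        )
        sol = solve_lp(lp)
        if not sol.feasible:
            raise GrowthInfeasibleError(f"infeasible at mu = {mu_probe}")
        return sol.objective, sol

    g0, sol0 = value(mu)
    dg_dq = sol0.reduced_upper[rid]  # marginal of the uptake variable bound
    g_minus, _ = value(mu * (1 - dmu))
    # one-sided toward lower mu: at the growth maximum, mu + dmu is infeasible
    dg_dmu = (g0 - g_minus) / (mu * dmu)
    # the bound itself moves with mu (q_ub = slope mu + intercept), so the
    # total derivative along the feasibility boundary includes slope * dg/dq
    denom = dg_dmu + slope * dg_dq
    if abs(denom) < 1e-30:
        raise ValueError("value function flat in mu; dual estimate undefined")
    return (-dg_dq / denom) * (q0 / mu)


def sensitivity_score(
    model: PCModel,
    condition: Condition,
    constraint: str,
    delta_c: float = 0.01,
    tol: float = 1e-5,
) -> SensitivityScore:
    """Sensitivity score S = (dmu/dc)(c/mu) of a structural constraint.

    ``constraint`` is "glucose_transporter" (the abundance cap) or
    "proteome" (the total modeled proteome); both are perturbed
    multiplicatively by (1 + delta_c), so S = dmu / (mu delta_c).
    A constraint with slack at the optimum scores zero.
    """
    mu0, _ = max_growth_rate(model, condition.S, tol=tol)
    kwargs = {}
    if constraint == "glucose_transporter":
        kwargs["transporter_cap"] = model.budget.transporter_cap * (1 + delta_c)
    elif constraint == "proteome":
        kwargs["budget_fraction"] = model.budget.total_modeled_fraction * (1 + delta_c)
    else:
        raise ValueError(f"unknown constraint {constraint!r}")
    mu1, _ = max_growth_rate(model, condition.S, tol=tol, **kwargs)
    score = (mu1 - mu0) / (mu0 * delta_c)
    return SensitivityScore(constraint, score, delta_c, mu0, mu1)


def scannable_parameters(model: PCModel) -> list[tuple[str, str]]:
    """Every (kind, id) pair the robustness scan varies: enzyme turnover
    numbers, degradation constants, machinery rates, and the budget terms."""
    params: list[tuple[str, str]] = []
    for eid, enz in model.enzymes.items():
        for rid in enz.catalyzed:
            params.append(("k_cat", f"{eid}:{rid}"))
    for species, kdeg in model.k_deg_of.items():
        if kdeg > 0:
            params.append(("k_deg", species))
    for mid in model.machineries:
        params.append(("machinery_rate", mid))
    params.append(("budget", "total_modeled_fraction"))
    params.append(("budget", "transporter_cap"))
    params.append(("kinetics", "kcat_transporter"))
    return params


def _apply(model: PCModel, kind: str, pid: str, factor: float) -> PCModel:
    m = model.copy()
    if kind == "k_cat":
        eid, rid = pid.split(":", 1)
        m.enzymes[eid].catalyzed[rid] *= factor
        if rid in m.catalytic_coupling:
            species, kcat = m.catalytic_coupling[rid]
            m.catalytic_coupling[rid] = (species, kcat * factor)
        if rid == m.glucose_transport_reaction:
            m.kcat_transporter *= factor
    elif kind == "k_deg":
        m.k_deg_of[pid] *= factor
    elif kind == "machinery_rate":
        m.machineries[pid] = dataclasses.replace(
            m.machineries[pid],
            catalytic_rate=m.machineries[pid].catalytic_rate * factor,
            composition=dict(m.machineries[pid].composition),
        )
    elif kind == "budget":
        setattr(m.budget, pid, getattr(m.budget, pid) * factor)
    elif kind == "kinetics":
        m.kcat_transporter *= factor
        if m.glucose_transport_reaction in m.catalytic_coupling:
            species, kcat = m.catalytic_coupling[m.glucose_transport_reaction]
            m.catalytic_coupling[m.glucose_transport_reaction] = (
                species, kcat * factor
            )
    else:
        raise ValueError(kind)
    return m


def robustness_scan(
    model: PCModel,
    conditions: list[Condition],
    factor: float = 2.0,
    threshold: float = 0.01,
    tol: float = 1e-4,
    parameters: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Vary every parameter ``factor``-fold up and down and record the
    relative change of the simulated growth rate per condition.

    Returns a frame with one row per (condition, parameter, direction),
    sorted by |dmu/mu| descending, flagging changes above ``threshold``.
    Solver failures are recorded per row and do not stop the scan.
    """
    params = parameters if parameters is not None else scannable_parameters(model)
    rows = []
    for cond in conditions:
        mu0, _ = max_growth_rate(model, cond.S, tol=tol)
        for kind, pid in params:
            for direction, f in (("x2", factor), ("x0.5", 1.0 / factor)):
                try:
                    pert = _apply(model, kind, pid, f)
                    mu1, _ = max_growth_rate(pert, cond.S, tol=tol)
                    rel = (mu1 - mu0) / mu0
                    err = ""
                except (GrowthInfeasibleError, SolverError) as exc:
                    mu1, rel, err = float("nan"), float("nan"), str(exc)
                rows.append(
                    {
                        "condition": cond.label or str(cond.S),
                        "parameter": f"{kind}:{pid}",
                        "direction": direction,
                        "mu_reference": mu0,
                        "mu_perturbed": mu1,
                        "rel_change": rel,
                        "flagged": abs(rel) > threshold if rel == rel else False,
                        "error": err,
                    }
                )
    frame = pd.DataFrame(rows)
    return frame.reindex(
        frame["rel_change"].abs().sort_values(ascending=False, na_position="last").index
    ).reset_index(drop=True)
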