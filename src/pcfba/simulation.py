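"""Growth simulations with a proteome-constrained model.

At a fixed specific growth rate mu the model is a linear program over
reaction fluxes: catalyst concentrations are eliminated through the
steady-state relation [X] = v_dilution(X) / mu, which makes every coupling
constraint (v <= k_cat [E], machinery capacities, the proteome budget)
linear in the fluxes.  Glucose-limited chemostat conditions are found by a
binary search for the minimal extracellular glucose concentration S at
which the LP is feasible, with uptake bounded by Michaelis-Menten
transporter kinetics q_S = k_cat [E] S/(K_M + S) under a cap on the
transporter abundance [E].

The feasibility objective maximizes production of the dummy protein, as is
conventional for this model class; a second, flux-minimizing LP at the fixed
optimum removes futile cycles and simultaneous forward/reverse flux from
reported solutions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from ._lp import LinearProgram, LPSolution, SolverError, solve_lp
from .core import PCModel

__all__ = [
    "GlucoseKinetics",
    "SimulationResult",
    "GrowthInfeasibleError",
    "SolverError",
    "assemble_lp",
    "solve_at",
    "feasible",
    "min_glucose_concentration",
    "max_growth_rate",
    "calibrate_transporter_cap",
    "inactive_enzyme",
    "audit_solution",
]

log = logging.getLogger(__name__)

INACTIVE_VAR = "_inactive"

#: glucose concentration treated as saturating ("rich") when S is None
RICH_S = None


class GrowthInfeasibleError(RuntimeError):
    """No feasible solution exists for the requested growth rate."""


@dataclass
class GlucoseKinetics:
    """Michaelis-Menten kinetics of the glucose transporter."""

    k_cat: float  # 1/h
    k_m: float  # mM
    transporter_cap: float  # mmol/gCDW

    def saturation(self, S: float | None) -> float:
        """sigma = S/(K_M + S); saturating medium (S None) gives 1."""
        if S is None:
            return 1.0
        if S < 0:
            raise ValueError("glucose concentration must be >= 0")
        return S / (self.k_m + S)

    def max_uptake(self, S: float | None) -> float:
        return self.k_cat * self.transporter_cap * self.saturation(S)


@dataclass
class SimulationResult:
    mu: float
    S: float | None
    sigma: float
    objective: float
    fluxes: dict[str, float]
    concentrations: dict[str, float] = field(default_factory=dict)
    inactive_enzyme: float = 0.0
    lp: LPSolution | None = None

    def net_fluxes(self, model: PCModel) -> dict[str, float]:
        return model.net_fluxes(self.fluxes)

    def exchange_fluxes(self, model: PCModel) -> dict[str, float]:
        """Net boundary flux per extracellular metabolite: secretion > 0,
        uptake < 0 (the storage convention; reports mirror magnitudes)."""
        out: dict[str, float] = {}
        for rid, v in self.fluxes.items():
            rxn = model.reactions.get(rid)
            if rxn is None or rxn.kind != "exchange":
                continue
            for met, coeff in rxn.stoichiometry.items():
                # exchange stoichiometry {met_e: -1}: forward flux drains the
                # medium species produced by secretion; the split reverse
                # supplies it for uptake
                out[met] = out.get(met, 0.0) - coeff * v
        return out

    def trna_charging(self, model: PCModel) -> dict[str, float]:
        return {
            rid[3:]: v for rid, v in self.fluxes.items() if rid.startswith("CH_")
        }


def _machinery_species(machinery_id: str) -> str:
    if machinery_id == "ribosome":
        return "ribosome"
    if machinery_id == "rna_polymerase":
        return "rnap"
    if machinery_id.startswith("mrna:"):
        return "mrna_" + machinery_id[5:]
    if machinery_id.startswith("trna:"):
        return "trna_" + machinery_id[5:]
    return machinery_id


def assemble_lp(
    model: PCModel,
    mu: float,
    S: float | None = RICH_S,
    *,
    uptake_overrides: dict[str, float] | None = None,
    transporter_cap: float | None = None,
    budget_fraction: float | None = None,
    objective: dict[str, float] | None = None,
) -> LinearProgram:
    """Assemble the growth-rate-parameterized LP over flux variables.

    ``uptake_overrides`` replaces the growth-rate-dependent uptake upper
    bound of named compounds with an absolute value (used by the
    reduced-cost machinery); ``transporter_cap`` and ``budget_fraction``
    override the corresponding budget terms for sensitivity analyses.
    """
    if mu <= 0:
        raise ValueError("mu must be > 0 (coupling coefficients are 1/mu)")
    if S is not None and S < 0:
        raise ValueError("glucose concentration must be >= 0")

    kin = GlucoseKinetics(
        model.kcat_transporter or 1.0,
        model.km_glucose,
        transporter_cap
        if transporter_cap is not None
        else (model.budget.transporter_cap if model.budget else math.inf),
    )
    sigma = kin.saturation(S)

    lp = LinearProgram(variables=list(model.reactions) + [INACTIVE_VAR])
    lp.set_bounds(INACTIVE_VAR, 0.0, None)

    # flux bounds
    for rid, rxn in model.reactions.items():
        lb, ub = rxn.lower_bound, rxn.upper_bound
        if rid in model.blocked_reactions:
            lb, ub = 0.0, 0.0
        lp.set_bounds(rid, lb, ub)
    for rid, coeff in model.growth_pinned.items():
        lp.set_bounds(rid, mu * coeff, mu * coeff)

    # growth-rate-dependent uptake bounds (linear trendlines, clipped at 0)
    overrides = uptake_overrides or {}
    for compound, (slope, intercept) in model.uptake_bounds.items():
        rid = model.uptake_reactions[compound]
        bound = overrides.get(compound, max(0.0, slope * mu + intercept))
        lp.set_bounds(rid, 0.0, bound)

    # species mass balance
    by_species: dict[str, dict[str, float]] = {m: {} for m in model.metabolites}
    for rid, rxn in model.reactions.items():
        for met, coeff in rxn.stoichiometry.items():
            by_species[met][rid] = by_species[met].get(rid, 0.0) + coeff
    for met, coeffs in by_species.items():
        if coeffs:
            lp.add_eq(f"mb_{met}", coeffs, 0.0)

    # Coupling rows are scaled so the dilution-flux coefficient is -1: raw
    # 1/mu coefficients span many orders of magnitude and defeat the
    # floating-point solver on these (notoriously ill-conditioned) problems.

    # degradation flux tied to the diluting pool: v_deg = (k_deg/mu) v_dil
    for species, deg_rid in model.degradation_of.items():
        dil_rid = model.dilution_of[species]
        kdeg = model.k_deg_of.get(species, 0.0)
        if kdeg > 0:
            lp.add_eq(f"deg_{species}", {deg_rid: mu / kdeg, dil_rid: -1.0}, 0.0)
        else:
            lp.add_eq(f"deg_{species}", {deg_rid: 1.0}, 0.0)

    # catalytic capacity: v <= k_cat [E] = (k_cat/mu) v_dil(E); the glucose
    # transporter works at k_cat * sigma
    for rid, (species, kcat) in model.catalytic_coupling.items():
        if species not in model.dilution_of:
            continue
        keff = kcat * sigma if rid == model.glucose_transport_reaction else kcat
        if keff <= 0:
            lp.set_bounds(rid, 0.0, 0.0)
            continue
        lp.add_ub(
            f"cap_{rid}", {rid: mu / keff, model.dilution_of[species]: -1.0}, 0.0
        )

    # machinery capacities (ribosome, RNA polymerase, mRNAs, tRNAs)
    for mid, terms in model.machinery_coupling.items():
        mach = model.machineries[mid]
        species = _machinery_species(mid)
        coeffs: dict[str, float] = {}
        scale = mu / mach.catalytic_rate
        for rid, weight in terms:
            coeffs[rid] = coeffs.get(rid, 0.0) + weight * scale
        coeffs[model.dilution_of[species]] = -1.0
        lp.add_ub(f"mach_{mid}", coeffs, 0.0)

    # transporter abundance cap: [E_T] = v_dil/mu <= cap
    if model.glucose_transport_reaction is not None:
        tsp = model.glucose_transporter
        if tsp is not None and tsp in model.dilution_of:
            dil = model.dilution_of[tsp]
            cur = lp.upper.get(dil)
            cap_v = mu * kin.transporter_cap
            lp.set_bounds(dil, lp.lower.get(dil, 0.0),
                          cap_v if cur is None else min(cur, cap_v))
        else:
            # no expressed transporter species: bound the flux directly
            rid = model.glucose_transport_reaction
            cur = lp.upper.get(rid)
            bound = kin.max_uptake(S)
            lp.set_bounds(rid, lp.lower.get(rid, 0.0),
                          bound if cur is None else min(cur, bound))

    # total modeled proteome: sum mass x [X] + inactive = budget
    if model.budget is not None and model.protein_mass_of:
        frac = (
            budget_fraction
            if budget_fraction is not None
            else model.budget.total_modeled_fraction
        )
        # scaled by mu: sum mass v_dil + mu inactive = mu frac
        coeffs = {INACTIVE_VAR: mu}
        for species, mass in model.protein_mass_of.items():
            dil = model.dilution_of[species]
            coeffs[dil] = coeffs.get(dil, 0.0) + mass
        lp.add_eq("proteome", coeffs, mu * frac)

    if objective is not None:
        lp.objective = dict(objective)
    elif model.objective_reaction is not None:
        lp.objective = {model.objective_reaction: 1.0}
    return lp


def _result_from(
    model: PCModel, mu: float, S: float | None, sol: LPSolution
) -> SimulationResult:
    kin_sigma = GlucoseKinetics(
        model.kcat_transporter or 1.0, model.km_glucose, 1.0
    ).saturation(S)
    conc = {
        species: sol.values[dil] / mu for species, dil in model.dilution_of.items()
    }
    fluxes = {rid: sol.values[rid] for rid in model.reactions}
    return SimulationResult(
        mu=mu,
        S=S,
        sigma=kin_sigma,
        objective=sol.objective,
        fluxes=fluxes,
        concentrations=conc,
        inactive_enzyme=sol.values.get(INACTIVE_VAR, 0.0),
        lp=sol,
    )


def solve_at(
    model: PCModel,
    mu: float,
    S: float | None = RICH_S,
    parsimonious: bool = True,
    **kwargs,
) -> SimulationResult | None:
    """Solve the LP at (mu, S); None if infeasible.

    With ``parsimonious`` a second LP minimizes total flux at the fixed
    optimum, suppressing futile cycles and simultaneous forward/reverse
    flux (the returned solution is otherwise degenerate).
    """
    lp = assemble_lp(model, mu, S, **kwargs)
    sol = solve_lp(lp)
    if not sol.feasible:
        return None
    if parsimonious:
        if len(lp.objective) == 1:
            # pin the attained optimum (within solver slack), then clean up
            obj_var = next(iter(lp.objective))
            lo = lp.lower.get(obj_var, 0.0)
            lp.set_bounds(
                obj_var,
                max(lo, sol.values[obj_var] - 1e-9 - 1e-6 * abs(sol.values[obj_var])),
                lp.upper.get(obj_var, None),
            )
        lp.objective = {rid: -1.0 for rid in model.reactions}
        sol2 = solve_lp(lp)
        if sol2.feasible:
            sol2 = LPSolution(
                True,
                sol.objective,
                sol2.values,
                sol2.duals_eq,
                sol2.duals_ub,
                sol2.reduced_lower,
                sol2.reduced_upper,
                sol2.status,
                sol2.message,
            )
            return _result_from(model, mu, S, sol2)
    return _result_from(model, mu, S, sol)


def feasible(
    model: PCModel, mu: float, S: float | None = RICH_S, **kwargs
) -> tuple[bool, SimulationResult | None]:
    """Whether growth at rate mu is supportable at glucose concentration S."""
    res = solve_at(model, mu, S, parsimonious=False, **kwargs)
    return (res is not None), res


def min_glucose_concentration(
    model: PCModel,
    mu: float,
    tol: float = 1e-6,
    s_max: float = 1000.0,
    **kwargs,
) -> tuple[float, SimulationResult]:
    """Binary search for the minimal extracellular glucose concentration at
    which growth rate mu is feasible (the chemostat operating point).

    Since uptake is monotone in the transporter saturation sigma =
    S/(K_M + S), searching S is equivalent to searching the lowest feasible
    saturation.  ``tol`` is relative on S.
    """
    ok, _ = feasible(model, mu, s_max, **kwargs)
    if not ok:
        raise GrowthInfeasibleError(
            f"growth rate {mu}/h unreachable even at S = {s_max} mM"
        )
    ok0, _ = feasible(model, mu, 0.0, **kwargs)
    if ok0:
        res = solve_at(model, mu, 0.0, **kwargs)
        return 0.0, res
    lo, hi = 0.0, s_max
    it = 0
    while (hi - lo) > tol * max(hi, 1e-12):
        mid = 0.5 * (lo + hi)
        ok, _ = feasible(model, mu, mid, **kwargs)
        log.info("bisection S: [%g, %g] mid %g %s", lo, hi, mid,
                 "feasible" if ok else "infeasible")
        if ok:
            hi = mid
        else:
            lo = mid
        it += 1
        if it > 200:
            break
    res = solve_at(model, mu, hi, **kwargs)
    return hi, res


def max_growth_rate(
    model: PCModel,
    S: float | None = RICH_S,
    tol: float = 1e-4,
    mu_lo: float = 1e-3,
    mu_cap: float = 64.0,
    **kwargs,
) -> tuple[float, SimulationResult]:
    """Binary search for the maximal feasible growth rate at fixed S."""
    ok, _ = feasible(model, mu_lo, S, **kwargs)
    if not ok:
        raise GrowthInfeasibleError(f"infeasible even at mu = {mu_lo}/h")
    lo = mu_lo
    hi = 2 * mu_lo
    while hi < mu_cap:
        ok, _ = feasible(model, hi, S, **kwargs)
        if not ok:
            break
        lo = hi
        hi *= 2.0
    else:
        raise GrowthInfeasibleError(f"growth rate unbounded above {mu_cap}/h?")
    while (hi - lo) > tol * max(lo, 1e-12):
        mid = 0.5 * (lo + hi)
        ok, _ = feasible(model, mid, S, **kwargs)
        log.info("bisection mu: [%g, %g] mid %g %s", lo, hi, mid,
                 "feasible" if ok else "infeasible")
        if ok:
            lo = mid
        else:
            hi = mid
    res = solve_at(model, lo, S, **kwargs)
    return lo, res


def calibrate_transporter_cap(
    model: PCModel, S: float | None = RICH_S, tol: float = 1e-4
) -> PCModel:
    """Set the glucose-transporter abundance cap the way the framework
    prescribes: the minimal transporter concentration that still supports
    the maximal growth rate (found with the cap unbounded)."""
    probe = model.copy()
    probe.budget.transporter_cap = 1e6
    mu_max, _ = max_growth_rate(probe, S, tol=tol)
    tsp = probe.glucose_transporter
    if tsp is None or tsp not in probe.dilution_of:
        raise ValueError("model has no expressed glucose transporter to calibrate")
    dil = probe.dilution_of[tsp]
    res = solve_at(
        probe, mu_max, S, parsimonious=False, objective={dil: -1.0}
    )
    if res is None:
        raise GrowthInfeasibleError("calibration LP infeasible at mu_max")
    cap = res.fluxes[dil] / mu_max
    out = model.copy()
    out.budget.transporter_cap = cap
    return out


def inactive_enzyme(result: SimulationResult) -> float:
    """Slack of the total-proteome budget: modeled proteome mass not needed
    for catalysis, of average amino-acid composition.  Zero exactly when the
    proteome constraint is active."""
    return result.inactive_enzyme


def audit_solution(
    model: PCModel, result: SimulationResult, rel_tol: float = 1e-6, abs_tol: float = 1e-6
) -> list[str]:
    """Re-check every coupling row of a returned solution.

    Floating-point LPs on metabolism-and-expression problems are
    ill-conditioned; this post-solve audit verifies v <= k_cat [E], the
    machinery capacities, nonnegative concentrations, and proteome closure,
    and returns a list of violations (empty when clean).
    """
    bad: list[str] = []
    mu = result.mu
    for rid, (species, kcat) in model.catalytic_coupling.items():
        if species not in model.dilution_of:
            continue
        keff = kcat * result.sigma if rid == model.glucose_transport_reaction else kcat
        v = result.fluxes[rid]
        cap = keff * result.concentrations[species]
        if v > cap * (1 + rel_tol) + abs_tol:
            bad.append(f"capacity violated for {rid}: {v} > {cap}")
    for mid, terms in model.machinery_coupling.items():
        mach = model.machineries[mid]
        used = sum(w * result.fluxes[rid] for rid, w in terms)
        cap = mach.catalytic_rate * result.concentrations[_machinery_species(mid)]
        if used > cap * (1 + rel_tol) + abs_tol:
            bad.append(f"machinery capacity violated for {mid}: {used} > {cap}")
    for species, conc in result.concentrations.items():
        if conc < -abs_tol:
            bad.append(f"negative concentration for {species}: {conc}")
    if model.budget is not None and model.protein_mass_of:
        total = result.inactive_enzyme + sum(
            mass * result.concentrations[species]
            for species, mass in model.protein_mass_of.items()
        )
        if abs(total - model.budget.total_modeled_fraction) > max(
            abs_tol, rel_tol * model.budget.total_modeled_fraction
        ):
            bad.append(
                f"proteome accounting open: {total} != "
                f"{model.budget.total_modeled_fraction}"
            )
    for species, deg_rid in model.degradation_of.items():
        kdeg = model.k_deg_of.get(species, 0.0)
        want = kdeg * result.concentrations[species]
        got = result.fluxes[deg_rid]
        if abs(got - want) > max(abs_tol, rel_tol * abs(want)):
            bad.append(f"degradation tie broken for {species}: {got} != {want}")
    return bad
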