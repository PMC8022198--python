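"""The three-pathway ATP allocation model.

The full proteome-constrained model's switching behavior is captured by a
tiny linear program over three ATP-producing pathways: (1) glycolysis with
mixed-acid fermentation, (2) glycolysis with lactate formation, and (3)
arginine catabolism.  Each pathway i is summarized by its ATP yield Y_i
(mol ATP per mol substrate), protein cost p_i (g protein per unit substrate
flux), and protein efficiency e_i = Y_i / p_i.  The LP maximizes total ATP
production

    J_ATP = sum_i Y_i J_i

subject to J_1 + J_2 = J_glc (all glucose is consumed), the proteome cap
p_1 J_1 + p_2 J_2 + p_3 J_3 <= P, and an arginine bound
0 <= J_3 <= alpha J_glc + beta reflecting the experimentally observed
linear correlation between arginine and glucose uptake.

Scanning J_glc produces three phases: (A) proteome slack — mixed acid plus
maximal arginine catabolism; (B) proteome bound — arginine catabolism
(lowest protein efficiency) is shed first; (C) arginine exhausted — mixed
acid is traded for lactate (higher protein efficiency, lower yield).  The
analytic piecewise solution (greedy allocation by marginal ATP per unit of
proteome) is implemented independently of the LP and serves as its oracle.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._lp import LinearProgram, solve_lp
from .core import StoichiometricModel
from .build import protein_cost

__all__ = [
    "PathwayParams",
    "PhaseProfile",
    "estimate_pathway_params",
    "solve_small_model",
    "solve_small_model_analytic",
    "phase_scan",
    "small_model_sensitivity",
    "substrate_level_arginine_yield",
]

PATHWAYS = ("mixed_acid", "lactate", "arginine")


@dataclass
class PathwayParams:
    """Per-pathway parameters: index 0 = glycolysis + mixed acid,
    1 = glycolysis + lactate, 2 = arginine catabolism."""

    atp_yield: tuple[float, float, float]  # Y_i, mol ATP / mol substrate
    protein_cost: tuple[float, float, float]  # p_i, g/gCDW per mmol/gCDW/h
    proteome_cap: float = 0.30  # P, g/gCDW allocated to the three pathways
    arg_slope: float = 0.3  # alpha of J_3 <= alpha J_glc + beta
    arg_intercept: float = 0.0  # beta, mmol/gCDW/h
    #: flux distributions (per unit substrate) that produced the costs
    flux_profiles: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(y <= 0 for y in self.atp_yield):
            raise ValueError("ATP yields must be > 0")
        if any(p <= 0 for p in self.protein_cost):
            raise ValueError("protein costs must be > 0")
        if self.proteome_cap <= 0:
            raise ValueError("proteome cap must be > 0")

    @property
    def efficiency(self) -> tuple[float, float, float]:
        """Protein efficiency e_i = Y_i / p_i, mmol ATP / g protein / h."""
        return tuple(y / p for y, p in zip(self.atp_yield, self.protein_cost))

    def arg_bound(self, j_glc: float) -> float:
        return self.arg_slope * j_glc + self.arg_intercept


def _fba(
    model: StoichiometricModel,
    objective: dict[str, float],
    fixed: dict[str, float],
    blocked: tuple[str, ...] = (),
    free_species: tuple[str, ...] = (),
    parsimonious: bool = True,
):
    """Plain FBA on the metabolic layer: max objective s.t. S v = 0.

    ``free_species`` drops the mass-balance rows of the named metabolites
    (they become unconstrained sources/sinks)."""
    lp = LinearProgram(variables=list(model.reactions))
    for rid, rxn in model.reactions.items():
        lp.set_bounds(rid, rxn.lower_bound, rxn.upper_bound)
    for rid in blocked:
        if rid in model.reactions:
            lp.set_bounds(rid, 0.0, 0.0)
    for rid, value in fixed.items():
        lp.set_bounds(rid, value, value)
    by_species: dict[str, dict[str, float]] = {}
    for rid, rxn in model.reactions.items():
        for met, coeff in rxn.stoichiometry.items():
            by_species.setdefault(met, {})[rid] = coeff
    for met, coeffs in by_species.items():
        if met not in free_species:
            lp.add_eq(f"mb_{met}", coeffs, 0.0)
    lp.objective = dict(objective)
    sol = solve_lp(lp)
    if not sol.feasible:
        return None
    if parsimonious:
        for rid, w in objective.items():
            v = sol.values[rid]
            pad = 1e-9 + 1e-9 * abs(v)
            if w > 0:
                lp.set_bounds(rid, max(lp.lower.get(rid, 0.0), v - pad),
                              lp.upper.get(rid))
            else:
                lp.set_bounds(rid, lp.lower.get(rid, 0.0),
                              min(lp.upper.get(rid, v) or v + pad, v + pad))
        lp.objective = {
            rid: (-1.0 if model.reactions[rid].lower_bound >= 0 else 0.0)
            for rid in model.reactions
        }
        sol2 = solve_lp(lp)
        if sol2.feasible:
            return sol2
    return sol


def _pathway_cost(model: StoichiometricModel, fluxes: dict[str, float]) -> float:
    """Total protein cost of a flux distribution: sum over catalyzed
    reactions of (enzyme mass / k_cat) x |flux|."""
    total = 0.0
    for rid, v in fluxes.items():
        if abs(v) < 1e-9:
            continue
        rxn = model.reactions[rid]
        eid = rxn.catalyst_id or (rxn.isozymes[0] if rxn.isozymes else None)
        if eid is None:
            continue
        enz = model.enzymes[eid]
        kcat = enz.catalyzed.get(rid)
        if kcat is None:
            continue
        total += abs(v) * protein_cost(enz, rid, model.proteins)
    return total


def estimate_pathway_params(
    model: StoichiometricModel,
    proteome_cap: float = 0.30,
    arg_slope: float = 0.3,
    arg_intercept: float = 0.0,
    blocked: tuple[str, ...] = ("POX", "GLCt1", "GLCabc", "EX_o2"),
) -> PathwayParams:
    """Estimate Y, p, e for the three pathways from a metabolic model.

    Pathway flux distributions come from three LPs with the ATP maintenance
    bound set free: mixed acid maximizes the maintenance flux at a glucose
    uptake fixed to 1 mmol/gCDW/h; lactate maximizes lactate production at
    glucose 1 and maintenance fixed to 2; arginine maximizes maintenance at
    an arginine uptake of 1.  The yield is the maintenance flux over the
    substrate uptake, the protein cost sums enzyme mass over turnover times
    flux, and the efficiency is their ratio.
    """
    free_maint = {"MAINT": (0.0, None)}

    def run(objective, fixed, label):
        lp_fixed = dict(fixed)
        m = model.copy()
        for rid, (lb, ub) in free_maint.items():
            m.reactions[rid].lower_bound = lb
            m.reactions[rid].upper_bound = ub if ub is not None else 1e6
        sol = _fba(m, objective, lp_fixed, blocked=blocked)
        if sol is None:
            raise RuntimeError(f"pathway LP infeasible: {label}")
        return sol

    zero_aa = {"EX_ala": 0.0, "EX_ser": 0.0}

    sol1 = run({"MAINT": 1.0}, {"EX_glc": -1.0, "EX_arg": 0.0, **zero_aa},
               "mixed acid fermentation")
    y1 = sol1.values["MAINT"] / 1.0

    m2 = model.copy()
    m2.reactions["MAINT"].lower_bound = 0.0
    m2.reactions["MAINT"].upper_bound = 1e6
    sol2 = _fba(m2, {"EX_lac": 1.0},
                {"EX_glc": -1.0, "EX_arg": 0.0, "MAINT": 2.0, **zero_aa},
                blocked=blocked)
    if sol2 is None:
        raise RuntimeError("pathway LP infeasible: lactate fermentation")
    y2 = sol2.values["MAINT"] / 1.0

    sol3 = run({"MAINT": 1.0}, {"EX_glc": 0.0, "EX_arg": -1.0, **zero_aa},
               "arginine catabolism")
    y3 = sol3.values["MAINT"] / 1.0

    costs = tuple(_pathway_cost(model, s.values) for s in (sol1, sol2, sol3))
    return PathwayParams(
        atp_yield=(y1, y2, y3),
        protein_cost=costs,
        proteome_cap=proteome_cap,
        arg_slope=arg_slope,
        arg_intercept=arg_intercept,
        flux_profiles={
            "mixed_acid": sol1.values,
            "lactate": sol2.values,
            "arginine": sol3.values,
        },
    )


def substrate_level_arginine_yield(
    model: StoichiometricModel,
    blocked: tuple[str, ...] = ("POX", "GLCt1", "GLCabc", "EX_o2"),
) -> float:
    """Arginine-pathway ATP yield with proton balancing decoupled from ATP:
    the proton-translocating ATP synthase is removed, leaving only
    substrate-level phosphorylation (the carbamate kinase ATP)."""
    m = model.copy()
    m.reactions["MAINT"].lower_bound = 0.0
    m.reactions["MAINT"].upper_bound = 1e6
    # cytosolic protons become a free sink/source; the synthase is blocked so
    # that the decoupled protons cannot be turned into ATP
    sol = _fba(
        m,
        {"MAINT": 1.0},
        {"EX_glc": 0.0, "EX_arg": -1.0, "EX_ala": 0.0, "EX_ser": 0.0},
        blocked=blocked + ("ATPS",),
        free_species=("h_c",),
    )
    if sol is None:
        raise RuntimeError("decoupled arginine LP infeasible")
    return sol.values["MAINT"]


# ---------------------------------------------------------------------------
# the 3-variable LP and its analytic oracle


def solve_small_model(
    params: PathwayParams, j_glc: float
) -> tuple[float, float, float, float]:
    """LP optimum (J_1, J_2, J_3, J_ATP) at total glucose uptake j_glc.

    Raises ValueError with the maximum sustainable glucose flux if even the
    all-lactate allocation violates the proteome cap.
    """
    if j_glc < 0:
        raise ValueError("glucose uptake must be >= 0")
    y, p = params.atp_yield, params.protein_cost
    lp = LinearProgram(variables=["J1", "J2", "J3"])
    lp.objective = {"J1": y[0], "J2": y[1], "J3": y[2]}
    lp.add_eq("glc", {"J1": 1.0, "J2": 1.0}, j_glc)
    lp.add_ub("proteome", {"J1": p[0], "J2": p[1], "J3": p[2]},
              params.proteome_cap)
    lp.set_bounds("J1", 0.0, None)
    lp.set_bounds("J2", 0.0, None)
    lp.set_bounds("J3", 0.0, params.arg_bound(j_glc))
    sol = solve_lp(lp)
    if not sol.feasible:
        j_max = params.proteome_cap / min(p[0], p[1])
        raise ValueError(
            f"glucose uptake {j_glc} infeasible under the proteome cap; "
            f"maximum sustainable J_glc = {j_max:.6g}"
        )
    j1, j2, j3 = (sol.values[k] for k in ("J1", "J2", "J3"))
    return j1, j2, j3, sol.objective


def solve_small_model_analytic(
    params: PathwayParams, j_glc: float
) -> tuple[float, float, float, float]:
    """Hand-derived piecewise solution of the three-pathway LP.

    Assumes the fermentative trade-off orientation Y_1 > Y_2 and p_1 > p_2
    (mixed acid yields more ATP but costs more protein than lactate).  All
    glucose is first routed through lactate (the cheapest way to satisfy
    J_1 + J_2 = J_glc), then the remaining proteome budget is spent greedily
    on the two "upgrades" — moving glucose from lactate to mixed acid
    (marginal gain (Y_1 - Y_2)/(p_1 - p_2) per gram) and arginine catabolism
    (marginal gain Y_3/p_3) — in order of decreasing marginal gain.
    """
    y, p = params.atp_yield, params.protein_cost
    if not (y[0] > y[1] and p[0] > p[1]):
        raise ValueError("analytic solution assumes Y1 > Y2 and p1 > p2")
    budget = params.proteome_cap - p[1] * j_glc
    if budget < -1e-12:
        raise ValueError("infeasible: even all-lactate exceeds the cap")
    budget = max(budget, 0.0)
    u3 = params.arg_bound(j_glc)
    rate1 = (y[0] - y[1]) / (p[0] - p[1])
    rate3 = y[2] / p[2]
    alloc = {"up1": 0.0, "J3": 0.0}
    items = [("up1", rate1, p[0] - p[1], j_glc), ("J3", rate3, p[2], u3)]
    for name, _, weight, limit in sorted(items, key=lambda t: -t[1]):
        take = min(limit, budget / weight) if weight > 0 else limit
        alloc[name] = take
        budget -= take * weight
    j1 = alloc["up1"]
    j2 = j_glc - j1
    j3 = alloc["J3"]
    return j1, j2, j3, y[0] * j1 + y[1] * j2 + y[2] * j3


@dataclass
class PhaseProfile:
    """Solution of the small model along a glucose-uptake grid."""

    j_glc: np.ndarray
    j1: np.ndarray
    j2: np.ndarray
    j3: np.ndarray
    j_atp: np.ndarray
    inactive: np.ndarray  # P - sum_i p_i J_i, g/gCDW
    labels: list[str]  # per grid interval; "A", "B" or "C"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "J_glc": self.j_glc,
                "J1": self.j1,
                "J2": self.j2,
                "J3": self.j3,
                "J_ATP": self.j_atp,
                "inactive": self.inactive,
                "phase": self.labels + [self.labels[-1]] if self.labels else [],
            }
        )

    def phase_blocks(self) -> list[tuple[str, int, int]]:
        """Contiguous (label, start, end) runs over the grid intervals."""
        blocks: list[tuple[str, int, int]] = []
        for i, lab in enumerate(self.labels):
            if blocks and blocks[-1][0] == lab:
                blocks[-1] = (lab, blocks[-1][1], i)
            else:
                blocks.append((lab, i, i))
        return blocks


def phase_scan(
    params: PathwayParams,
    j_glc_grid: np.ndarray | list[float],
    slope_tol_scale: float = 1e-9,
) -> PhaseProfile:
    """Solve the small model along an increasing glucose grid and label the
    phases from the signs of the flux slopes: A while both mixed acid and
    arginine increase, B while arginine declines, C once mixed acid
    declines in favor of lactate."""
    grid = np.asarray(j_glc_grid, dtype=float)
    if grid.ndim != 1 or len(grid) < 2 or np.any(np.diff(grid) <= 0):
        raise ValueError("j_glc_grid must be strictly increasing")
    sols = np.array([solve_small_model(params, g) for g in grid])
    j1, j2, j3, j_atp = sols.T
    p = params.protein_cost
    inactive = params.proteome_cap - (p[0] * j1 + p[1] * j2 + p[2] * j3)
    tol = slope_tol_scale * max(1.0, float(np.max(np.abs(sols))))
    labels: list[str] = []
    for i in range(len(grid) - 1):
        d1 = j1[i + 1] - j1[i]
        d3 = j3[i + 1] - j3[i]
        if d1 < -tol:
            labels.append("C")
        elif d3 < -tol:
            labels.append("B")
        else:
            labels.append("A")
    return PhaseProfile(grid, j1, j2, j3, j_atp, inactive, labels)


def small_model_sensitivity(
    params: PathwayParams,
    j_glc: float,
    constraint: str,
    delta_c: float = 0.01,
) -> float:
    """Scaled sensitivity S = (dJ_ATP/dc)(c/J_ATP) of the ATP optimum to a
    constraint, by a relative finite difference of size ``delta_c``.

    ``constraint`` is "glucose" (total glucose uptake), "proteome" (the cap
    P), or "arginine" (the arginine bound evaluated at the base glucose
    uptake, perturbed independently of J_glc).
    """
    base = solve_small_model(params, j_glc)[3]
    if base <= 0:
        raise ValueError("base ATP production is zero; score undefined")
    if constraint == "glucose":
        pert = solve_small_model_fixed_arg_bound(
            params, j_glc * (1 + delta_c), params.arg_bound(j_glc)
        )[3]
    elif constraint == "proteome":
        p2 = dataclasses.replace(
            params, proteome_cap=params.proteome_cap * (1 + delta_c),
            flux_profiles=params.flux_profiles,
        )
        pert = solve_small_model(p2, j_glc)[3]
    elif constraint == "arginine":
        pert = solve_small_model_fixed_arg_bound(
            params, j_glc, params.arg_bound(j_glc) * (1 + delta_c)
        )[3]
    else:
        raise ValueError(f"unknown constraint {constraint!r}")
    return (pert - base) / (base * delta_c)


def solve_small_model_fixed_arg_bound(
    params: PathwayParams, j_glc: float, arg_bound: float
) -> tuple[float, float, float, float]:
    """Small-model LP with the arginine bound fixed to an absolute value
    (decoupled from J_glc); used by the sensitivity machinery."""
    y, p = params.atp_yield, params.protein_cost
    lp = LinearProgram(variables=["J1", "J2", "J3"])
    lp.objective = {"J1": y[0], "J2": y[1], "J3": y[2]}
    lp.add_eq("glc", {"J1": 1.0, "J2": 1.0}, j_glc)
    lp.add_ub("proteome", {"J1": p[0], "J2": p[1], "J3": p[2]},
              params.proteome_cap)
    lp.set_bounds("J1", 0.0, None)
    lp.set_bounds("J2", 0.0, None)
    lp.set_bounds("J3", 0.0, arg_bound)
    sol = solve_lp(lp)
    if not sol.feasible:
        raise ValueError("small model infeasible at the perturbed constraint")
    return sol.values["J1"], sol.values["J2"], sol.values["J3"], sol.objective
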