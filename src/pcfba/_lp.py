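"""Thin wrapper around scipy's HiGHS interface for the model LPs.

Keeps named variables and rows so callers can read fluxes and dual values
without tracking indices, and distinguishes infeasibility from solver
failure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

__all__ = ["LinearProgram", "LPSolution", "SolverError", "solve_lp"]


class SolverError(RuntimeError):
    """The LP solver failed for a reason other than infeasibility."""


@dataclass
class LinearProgram:
    """maximize c @ x  s.t.  A_eq x = b_eq,  A_ub x <= b_ub,  lb <= x <= ub."""

    variables: list[str]
    objective: dict[str, float] = field(default_factory=dict)
    eq_rows: list[tuple[str, dict[str, float], float]] = field(default_factory=list)
    ub_rows: list[tuple[str, dict[str, float], float]] = field(default_factory=list)
    lower: dict[str, float] = field(default_factory=dict)
    upper: dict[str, float] = field(default_factory=dict)

    def set_bounds(self, var: str, lb: float, ub: float) -> None:
        self.lower[var] = lb
        self.upper[var] = ub

    def add_eq(self, name: str, coeffs: dict[str, float], rhs: float) -> None:
        self.eq_rows.append((name, coeffs, rhs))

    def add_ub(self, name: str, coeffs: dict[str, float], rhs: float) -> None:
        self.ub_rows.append((name, coeffs, rhs))


@dataclass
class LPSolution:
    feasible: bool
    objective: float
    values: dict[str, float]
    #: dual values (marginals) keyed by row name
    duals_eq: dict[str, float]
    duals_ub: dict[str, float]
    #: marginals of the variable bounds
    reduced_lower: dict[str, float]
    reduced_upper: dict[str, float]
    status: int
    message: str


def solve_lp(lp: LinearProgram) -> LPSolution:
    n = len(lp.variables)
    idx = {v: j for j, v in enumerate(lp.variables)}
    c = np.zeros(n)
    for v, w in lp.objective.items():
        c[idx[v]] = -w  # linprog minimizes

    def build(rows):
        A = np.zeros((len(rows), n))
        b = np.zeros(len(rows))
        for i, (_, coeffs, rhs) in enumerate(rows):
            for v, w in coeffs.items():
                A[i, idx[v]] = w
            b[i] = rhs
        return A, b

    A_eq, b_eq = build(lp.eq_rows) if lp.eq_rows else (None, None)
    A_ub, b_ub = build(lp.ub_rows) if lp.ub_rows else (None, None)
    bounds = [(lp.lower.get(v, 0.0), lp.upper.get(v, None)) for v in lp.variables]
    res = linprog(
        c,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=bounds,
        method="highs",
        # ME-type LPs are ill-conditioned; run the simplex at its tightest
        # feasibility tolerance so coupling rows hold after unscaling
        options={
            "primal_feasibility_tolerance": 1e-10,
            "dual_feasibility_tolerance": 1e-9,
        },
    )
    if res.status == 2:
        return LPSolution(False, np.nan, {}, {}, {}, {}, {}, res.status, res.message)
    if res.status != 0:
        raise SolverError(f"LP solver failed (status {res.status}): {res.message}")
    values = {v: float(res.x[j]) for v, j in idx.items()}
    duals_eq = (
        {name: -float(m) for (name, _, _), m in zip(lp.eq_rows, res.eqlin.marginals)}
        if lp.eq_rows
        else {}
    )
    duals_ub = (
        {name: -float(m) for (name, _, _), m in zip(lp.ub_rows, res.ineqlin.marginals)}
        if lp.ub_rows
        else {}
    )
    red_lo = {v: float(res.lower.marginals[j]) for v, j in idx.items()}
    red_up = {v: -float(res.upper.marginals[j]) for v, j in idx.items()}
    return LPSolution(
        True,
        -float(res.fun),
        values,
        duals_eq,
        duals_ub,
        red_lo,
        red_up,
        res.status,
        res.message,
    )
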