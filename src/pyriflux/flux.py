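"""Flux balance analysis, flux variability analysis and differential flux.

FBA solves ``max c'v  s.t.  S v = 0, lb <= v <= ub`` for the biomass
objective.  FVA then minimizes and maximizes every reaction flux with biomass
held at a fraction alpha of its optimum::

    min / max v_i
    s.t.  c'v = alpha * f_max   (or >= with biomass_relaxed)
          S v = 0
          lb_i <= v_i <= ub_i

All LPs are solved with scipy's HiGHS interface in deterministic declaration
order.  Differential flux compares two FVA results (treated vs control) by
the fold change of the per-reaction interval midpoints.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .network import MetabolicModel, stoichiometric_matrix

__all__ = [
    "FBASolution",
    "FVAResult",
    "DifferentialFluxTable",
    "InfeasibleModelError",
    "optimize_biomass",
    "flux_variability",
    "flux_fold_change",
    "default_eps",
]

LP_TOL = 1e-9


class InfeasibleModelError(RuntimeError):
    """Raised when an LP stage has no feasible solution."""


@dataclass(frozen=True)
class FBASolution:
    fmax: float
    flux_vector: Mapping[str, float]
    status: str  # optimal | infeasible | unbounded

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


@dataclass(frozen=True)
class FVAResult:
    """Per-reaction [vmin, vmax] flux ranges at biomass fraction alpha."""

    ranges: Mapping[str, tuple[float, float]]
    alpha: float
    fmax_used: float

    def midpoints(self) -> dict[str, float]:
        return {rid: 0.5 * (lo + hi) for rid, (lo, hi) in self.ranges.items()}

    def to_frame(self, prefix: str = "") -> pd.DataFrame:
        rows = {rid: {f"{prefix}vmin": lo, f"{prefix}vmax": hi}
                for rid, (lo, hi) in self.ranges.items()}
        df = pd.DataFrame.from_dict(rows, orient="index")
        df.index.name = "reaction_id"
        return df


@dataclass(frozen=True)
class DifferentialFluxTable:
    """Treated-vs-control flux fold changes on FVA interval midpoints."""

    table: pd.DataFrame  # reaction_id index; control_mid, treated_mid, fold_change, log2_fc, flag

    def ranked(self) -> pd.DataFrame:
        """Entries usable for ranking (flag == ok), sorted by |log2_fc| descending."""
        ok = self.table[self.table["flag"] == "ok"].copy()
        return ok.reindex(ok["log2_fc"].abs().sort_values(ascending=False).index)


def _lp_arrays(model: MetabolicModel):
    S = stoichiometric_matrix(model)
    lb = np.array([r.lb for r in model.reactions])
    ub = np.array([r.ub for r in model.reactions])
    for r in model.reactions:
        if r.lb > r.ub:
            raise ValueError(f"reaction {r.id!r}: lb > ub")
    return S, lb, ub


def _solve(c, A_eq, b_eq, lb, ub, A_ub=None, b_ub=None):
    res = linprog(
        c,
        A_eq=A_eq,
        b_eq=b_eq,
        A_ub=A_ub,
        b_ub=b_ub,
        bounds=np.column_stack([lb, ub]),
        method="highs",
        options={"primal_feasibility_tolerance": LP_TOL,
                 "dual_feasibility_tolerance": LP_TOL},
    )
    return res


def optimize_biomass(model: MetabolicModel) -> FBASolution:
    """Maximize the objective reaction's flux under steady state and bounds."""
    S, lb, ub = _lp_arrays(model)
    obj_idx = model.reaction_ids.index(model.objective_reaction_id)
    c = np.zeros(len(model.reactions))
    c[obj_idx] = -1.0  # linprog minimizes
    res = _solve(c, S, np.zeros(S.shape[0]), lb, ub)
    if res.status == 2:
        return FBASolution(math.nan, {}, "infeasible")
    if res.status == 3:
        return FBASolution(math.inf, {}, "unbounded")
    if not res.success:  # pragma: no cover - defensive
        raise InfeasibleModelError(f"FBA solver failure: {res.message}")
    flux = dict(zip(model.reaction_ids, res.x))
    return FBASolution(-res.fun, flux, "optimal")


def flux_variability(
    model: MetabolicModel,
    alpha: float = 1.0,
    biomass_relaxed: bool = False,
) -> FVAResult:
    """Per-reaction min/max flux with biomass fixed at ``alpha * fmax``.

    With ``biomass_relaxed`` the biomass constraint becomes
    ``c'v >= alpha * fmax`` (the common practical relaxation); the default is
    the strict equality.  At alpha = 1 the two coincide because the optimum
    cannot be exceeded.
    """
    if not 0 < alpha <= 1:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    fba = optimize_biomass(model)
    if not fba.optimal:
        raise InfeasibleModelError(f"cannot run FVA: biomass LP is {fba.status}")
    S, lb, ub = _lp_arrays(model)
    n = len(model.reactions)
    obj_idx = model.reaction_ids.index(model.objective_reaction_id)
    target = alpha * fba.fmax
    crow = np.zeros(n)
    crow[obj_idx] = 1.0
    if biomass_relaxed:
        A_eq, b_eq = S, np.zeros(S.shape[0])
        A_ub, b_ub = -crow[None, :], np.array([-target])
    else:
        A_eq = np.vstack([S, crow])
        b_eq = np.append(np.zeros(S.shape[0]), target)
        A_ub = b_ub = None
    ranges: dict[str, tuple[float, float]] = {}
    for i, rid in enumerate(model.reaction_ids):
        c = np.zeros(n)
        c[i] = 1.0
        lo = _solve(c, A_eq, b_eq, lb, ub, A_ub, b_ub)
        hi = _solve(-c, A_eq, b_eq, lb, ub, A_ub, b_ub)
        if not (lo.success and hi.success):
            raise InfeasibleModelError(
                f"FVA infeasible for reaction {rid!r} at alpha={alpha} "
                f"(biomass target {target:g})"
            )
        vmin, vmax = lo.fun, -hi.fun
        if vmin > vmax:  # numerical jitter only
            vmin, vmax = vmax, vmin
        ranges[rid] = (vmin, vmax)
    return FVAResult(ranges, alpha, fba.fmax)


def default_eps(model: MetabolicModel) -> float:
    """Fold-change guard: 1e-6 times the largest absolute bound in the model."""
    biggest = max(max(abs(r.lb), abs(r.ub)) for r in model.reactions)
    return 1e-6 * (biggest if biggest > 0 else 1.0)


def flux_fold_change(
    treated: FVAResult, control: FVAResult, eps: float = 1e-6
) -> DifferentialFluxTable:
    """Fold change of FVA midpoints, treated over control.

    Entries with |control midpoint| < eps are flagged ``near-zero-denominator``
    and excluded from ranking; entries whose ratio would be non-positive
    (sign change between conditions) are flagged ``sign-change``.  A sign
    guard ``eps * sign(control_mid)`` keeps well-behaved ratios from blowing
    up near the guard threshold.
    """
    if set(treated.ranges) != set(control.ranges):
        raise ValueError("treated and control FVA results cover different reactions")
    rows = {}
    for rid in control.ranges:
        c_lo, c_hi = control.ranges[rid]
        t_lo, t_hi = treated.ranges[rid]
        c_mid = 0.5 * (c_lo + c_hi)
        t_mid = 0.5 * (t_lo + t_hi)
        if abs(c_mid) < eps:
            fc, l2, flag = math.nan, math.nan, "near-zero-denominator"
        else:
            s = 1.0 if c_mid > 0 else -1.0
            fc = (t_mid + eps * s) / (c_mid + eps * s)
            if fc <= 0:
                fc, l2, flag = fc, math.nan, "sign-change"
            else:
                l2, flag = math.log2(fc), "ok"
        rows[rid] = {
            "control_vmin": c_lo, "control_vmax": c_hi, "control_mid": c_mid,
            "treated_vmin": t_lo, "treated_vmax": t_hi, "treated_mid": t_mid,
            "fold_change": fc, "log2_fc": l2, "flag": flag,
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "reaction_id"
    return DifferentialFluxTable(table)
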