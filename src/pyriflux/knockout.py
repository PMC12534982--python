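"""Gene-knockout flux prediction (MOMA) and transformation scoring.

MOMA (minimization of metabolic adjustment) predicts the flux state after a
knockout as the feasible point closest (in squared Euclidean distance) to a
reference flux distribution::

    min  sum_i (v_i - ref_i)^2
    s.t. S v = 0,  lb <= v <= ub,  v_i = 0 for disabled reactions

The transformation score ranks knockouts by how much they move a *source*
metabolic state (treated) toward a *target* state (control): each reaction
contributes a weighted success when the knockout flux moves in the desired
direction, and a weighted violation when it moves against it.  The robust
score takes the worst case over two prediction engines (quadratic MOMA and
plain FBA), a simplified form of the worst-case principle used by robust
metabolic transformation analysis (simplified-rMTA); the published bTS/wTS
weighting machinery is deliberately not reproduced.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .expression import IntegrationConfig
from .flux import FBASolution, FVAResult, InfeasibleModelError, optimize_biomass
from .network import MetabolicModel, stoichiometric_matrix

__all__ = [
    "KnockoutPrediction",
    "TransformationScore",
    "gene_knockout_reactions",
    "knockout_bounds",
    "moma_knockout",
    "fba_knockout",
    "mta_score",
    "rank_gene_knockouts",
    "default_tau",
    "scores_to_frame",
]


@dataclass(frozen=True)
class KnockoutPrediction:
    gene: str
    disabled_reactions: frozenset[str]
    flux_vector: Mapping[str, float]
    distance: float

    def __post_init__(self):
        object.__setattr__(self, "flux_vector", dict(self.flux_vector))


@dataclass(frozen=True)
class TransformationScore:
    gene: str
    ts_moma: float
    ts_fba: float
    robust_score: float
    n_success: int
    n_violation: int
    disabled_reactions: frozenset[str] = frozenset()


def gene_knockout_reactions(model: MetabolicModel, gene: str) -> set[str]:
    """Reactions whose GPR evaluates false when ``gene`` is knocked out.

    All other genes are assumed present; reactions without a GPR are never
    disabled.
    """
    if gene not in model.genes:
        raise KeyError(f"unknown gene {gene!r}")
    active = lambda g: g != gene
    return {r.id for r in model.reactions
            if r.gpr is not None and not r.gpr.evaluate_bool(active)}


def knockout_bounds(model: MetabolicModel, disabled: Iterable[str]) -> MetabolicModel:
    """Copy of the model with disabled reactions clamped to zero flux."""
    disabled = set(disabled)
    unknown = disabled - set(model.reaction_ids)
    if unknown:
        raise KeyError(f"unknown reactions: {sorted(unknown)}")
    return model.with_bounds({rid: (0.0, 0.0) for rid in disabled})


def _kkt_polish(S, lb, ub, ref, v, tol=1e-6):
    """Refine a near-optimal QP solution by solving the KKT system with the
    detected active bound set fixed.  Returns the polished point or None."""
    n = len(ref)
    at_lb = np.abs(v - lb) <= tol
    at_ub = np.abs(v - ub) <= tol
    fixed = at_lb | at_ub
    fixed_val = np.where(at_ub, ub, lb)
    free = ~fixed
    out = np.where(fixed, fixed_val, 0.0)
    if free.any():
        b = -S[:, fixed] @ fixed_val[fixed] if fixed.any() else np.zeros(S.shape[0])
        Sf = S[:, free]
        # min ||v_f - ref_f||^2 s.t. Sf v_f = b  ->  v_f = ref_f - Sf' mu
        G = Sf @ Sf.T
        rhs = Sf @ ref[free] - b
        mu, *_ = np.linalg.lstsq(G, rhs, rcond=None)
        vf = ref[free] - Sf.T @ mu
        out[free] = vf
    feas_tol = 1e-7 * max(1.0, np.max(np.abs(ub - lb)))
    if np.any(out < lb - feas_tol) or np.any(out > ub + feas_tol):
        return None
    if np.max(np.abs(S @ out)) > 1e-7:
        return None
    return np.clip(out, lb, ub)


def moma_knockout(
    model: MetabolicModel,
    reference: Mapping[str, float],
    disabled: Iterable[str],
    gene: str = "",
) -> KnockoutPrediction:
    """Quadratic MOMA prediction for a set of disabled reactions.

    ``reference`` must be a feasible flux vector of the un-knocked model
    (e.g. an FBA solution of the source condition).
    """
    disabled = frozenset(disabled)
    rids = model.reaction_ids
    missing = set(rids) - set(reference)
    if missing:
        raise ValueError(f"reference does not cover reactions: {sorted(missing)}")
    S = stoichiometric_matrix(model)
    lb = np.array([r.lb for r in model.reactions], dtype=float)
    ub = np.array([r.ub for r in model.reactions], dtype=float)
    for i, rid in enumerate(rids):
        if rid in disabled:
            lb[i] = ub[i] = 0.0
    ref = np.array([reference[rid] for rid in rids], dtype=float)

    x0 = np.clip(ref, lb, ub)
    if np.max(np.abs(S @ x0)) < 1e-9 and np.allclose(x0, ref):
        # reference already satisfies the knocked-out constraints
        return KnockoutPrediction(gene, disabled, dict(zip(rids, ref)), 0.0)

    res = minimize(
        lambda v: float(np.sum((v - ref) ** 2)),
        x0,
        jac=lambda v: 2.0 * (v - ref),
        bounds=np.column_stack([lb, ub]),
        constraints=[{"type": "eq", "fun": lambda v: S @ v, "jac": lambda v: S}],
        method="SLSQP",
        options={"maxiter": 500, "ftol": 1e-12},
    )
    if not res.success or np.max(np.abs(S @ res.x)) > 1e-6:
        # SLSQP can fail from a poor start; retry from zero (always feasible
        # when 0 is within bounds) before declaring infeasibility.
        z0 = np.clip(np.zeros_like(ref), lb, ub)
        res = minimize(
            lambda v: float(np.sum((v - ref) ** 2)),
            z0,
            jac=lambda v: 2.0 * (v - ref),
            bounds=np.column_stack([lb, ub]),
            constraints=[{"type": "eq", "fun": lambda v: S @ v, "jac": lambda v: S}],
            method="SLSQP",
            options={"maxiter": 500, "ftol": 1e-12},
        )
    if not res.success or np.max(np.abs(S @ res.x)) > 1e-6:
        raise InfeasibleModelError(
            f"MOMA infeasible after disabling {sorted(disabled)}: {res.message}"
        )
    v = res.x
    polished = _kkt_polish(S, lb, ub, ref, v)
    if polished is not None and np.sum((polished - ref) ** 2) <= np.sum((v - ref) ** 2) + 1e-9:
        v = polished
    v = np.where(np.abs(v) < 1e-10, 0.0, v)
    for i, rid in enumerate(rids):
        if rid in disabled:
            v[i] = 0.0
    return KnockoutPrediction(gene, disabled, dict(zip(rids, v)),
                              float(np.sum((v - ref) ** 2)))


def fba_knockout(
    model: MetabolicModel, disabled: Iterable[str], gene: str = ""
) -> KnockoutPrediction:
    """FBA prediction after knockout: re-maximize biomass on the clamped model."""
    disabled = frozenset(disabled)
    knocked = knockout_bounds(model, disabled)
    sol = optimize_biomass(knocked)
    if not sol.optimal:
        raise InfeasibleModelError(
            f"FBA infeasible after disabling {sorted(disabled)} ({sol.status})"
        )
    return KnockoutPrediction(gene, disabled, sol.flux_vector, math.nan)


def default_tau(model: MetabolicModel) -> float:
    """Dead-band for transformation scoring: 1e-3 x largest absolute bound."""
    biggest = max(max(abs(r.lb), abs(r.ub)) for r in model.reactions)
    return 1e-3 * (biggest if biggest > 0 else 1.0)


def _directional_ts(
    source_mid: Mapping[str, float],
    target_mid: Mapping[str, float],
    flux: Mapping[str, float],
    tau: float,
) -> tuple[float, int, int]:
    rids = sorted(source_mid)
    delta = {rid: target_mid[rid] - source_mid[rid] for rid in rids}
    moving = [rid for rid in rids if abs(delta[rid]) > tau]
    steady = [rid for rid in rids if abs(delta[rid]) <= tau]
    total = sum(abs(delta[rid]) for rid in moving)
    n = len(rids)
    ts = 0.0
    n_success = n_violation = 0
    for rid in rids:
        a = flux[rid] - source_mid[rid]
        if rid in steady:
            w = 1.0 / n
            if abs(a) < tau:
                ts += w
                n_success += 1
            continue
        d = 1.0 if delta[rid] > 0 else -1.0
        w = abs(delta[rid]) / total
        if abs(a) >= tau and math.copysign(1.0, a) == d:
            ts += w
            n_success += 1
        elif abs(a) >= tau and math.copysign(1.0, a) == -d:
            ts -= w
            n_violation += 1
    return ts, n_success, n_violation


def mta_score(
    source: FVAResult,
    target: FVAResult,
    prediction: KnockoutPrediction,
    tau: float,
    fba_prediction: KnockoutPrediction | None = None,
) -> TransformationScore:
    """Score a knockout by how far it moves the source state toward the target.

    Per reaction, the desired change is the sign of (target - source)
    midpoint difference with dead-band tau; the achieved change is the
    prediction flux minus the source midpoint.  Successes add and violations
    subtract normalized weights |target - source| / sum|.| (steady reactions
    weigh 1/n).  The robust score is the minimum of the MOMA-based and
    FBA-based scores when an FBA prediction is supplied.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    rid_sets = {frozenset(source.ranges), frozenset(target.ranges),
                frozenset(prediction.flux_vector)}
    if fba_prediction is not None:
        rid_sets.add(frozenset(fba_prediction.flux_vector))
    if len(rid_sets) != 1:
        raise ValueError("source, target and prediction cover different reaction sets")
    s_mid = source.midpoints()
    t_mid = target.midpoints()
    ts_moma, n_s, n_v = _directional_ts(s_mid, t_mid, prediction.flux_vector, tau)
    if fba_prediction is not None:
        ts_fba, _, _ = _directional_ts(s_mid, t_mid, fba_prediction.flux_vector, tau)
    else:
        ts_fba = ts_moma
    return TransformationScore(
        gene=prediction.gene,
        ts_moma=ts_moma,
        ts_fba=ts_fba,
        robust_score=min(ts_moma, ts_fba),
        n_success=n_s,
        n_violation=n_v,
        disabled_reactions=prediction.disabled_reactions,
    )


def rank_gene_knockouts(
    model: MetabolicModel,
    source_fva: FVAResult,
    target_fva: FVAResult,
    reference: Mapping[str, float] | None = None,
    candidate_genes: Sequence[str] | None = None,
    tau: float | None = None,
) -> tuple[list[TransformationScore], list[str]]:
    """Score every candidate gene knockout on the source model and rank them.

    ``model`` should carry the *source* (treated) condition bounds;
    ``reference`` defaults to its FBA flux vector.  Returns the ranked list
    (robust score descending, ties broken by gene id) and the list of genes
    whose knockout left the model infeasible.
    """
    if candidate_genes is None:
        candidate_genes = sorted(model.genes)
    else:
        unknown = set(candidate_genes) - model.genes
        if unknown:
            raise KeyError(f"unknown candidate genes: {sorted(unknown)}")
        candidate_genes = sorted(candidate_genes)
    if tau is None:
        tau = default_tau(model)
    if reference is None:
        sol = optimize_biomass(model)
        if not sol.optimal:
            raise InfeasibleModelError(f"source model FBA is {sol.status}")
        reference = sol.flux_vector
    scores: list[TransformationScore] = []
    infeasible: list[str] = []
    for gene in candidate_genes:
        disabled = gene_knockout_reactions(model, gene)
        try:
            moma = moma_knockout(model, reference, disabled, gene=gene)
            fba = fba_knockout(model, disabled, gene=gene)
        except InfeasibleModelError:
            infeasible.append(gene)
            continue
        scores.append(mta_score(source_fva, target_fva, moma, tau, fba_prediction=fba))
    scores.sort(key=lambda s: (-s.robust_score, s.gene))
    return scores, infeasible


def scores_to_frame(scores: Sequence[TransformationScore],
                    infeasible: Sequence[str] = ()) -> pd.DataFrame:
    rows = [
        {
            "gene": s.gene,
            "ts_moma": s.ts_moma,
            "ts_fba": s.ts_fba,
            "robust_score": s.robust_score,
            "n_success": s.n_success,
            "n_violation": s.n_violation,
            "disabled_reactions": ";".join(sorted(s.disabled_reactions)),
        }
        for s in scores
    ]
    rows += [
        {"gene": g, "ts_moma": -math.inf, "ts_fba": -math.inf,
         "robust_score": -math.inf, "n_success": 0, "n_violation": 0,
         "disabled_reactions": ""}
        for g in infeasible
    ]
    df = pd.DataFrame(rows, columns=["gene", "ts_moma", "ts_fba", "robust_score",
                                     "n_success", "n_violation", "disabled_reactions"])
    return df
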