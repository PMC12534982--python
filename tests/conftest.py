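import numpy as np
import pytest

from pyriflux.network import MetabolicModel, Metabolite, Reaction


@pytest.fixture
def chain_model():
    """src -> A -> B -> drn, all capacities 10, objective = terminal drain."""
    return MetabolicModel(
        [Metabolite("A"), Metabolite("B")],
        [
            Reaction("r1", {"A": 1}, 0, 10),
            Reaction("r2", {"A": -1, "B": 1}, 0, 10),
            Reaction("r3", {"B": -1}, 0, 10),
        ],
        "r3",
    )


@pytest.fixture
def diamond_model():
    """A->B->D / A->C->D with uptake ub 10 and export objective."""
    return MetabolicModel(
        [Metabolite("A"), Metabolite("B"), Metabolite("C"), Metabolite("D")],
        [
            Reaction("up", {"A": 1}, 0, 10),
            Reaction("ab", {"A": -1, "B": 1}, 0, 10),
            Reaction("ac", {"A": -1, "C": 1}, 0, 10),
            Reaction("bd", {"B": -1, "D": 1}, 0, 10),
            Reaction("cd", {"C": -1, "D": 1}, 0, 10),
            Reaction("ex", {"D": -1}, 0, 10),
        ],
        "ex",
    )


def naive_fva(model, alpha=1.0):
    """Independent per-reaction LP oracle built directly on scipy.linprog."""
    from scipy.optimize import linprog

    from pyriflux.network import stoichiometric_matrix

    S = stoichiometric_matrix(model)
    n = len(model.reactions)
    bounds = [(r.lb, r.ub) for r in model.reactions]
    obj = model.reaction_ids.index(model.objective_reaction_id)
    c = np.zeros(n)
    c[obj] = -1
    base = linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=bounds, method="highs")
    assert base.success
    fmax = -base.fun
    crow = np.zeros(n)
    crow[obj] = 1
    A_eq = np.vstack([S, crow])
    b_eq = np.append(np.zeros(S.shape[0]), alpha * fmax)
    ranges = {}
    for i, rid in enumerate(model.reaction_ids):
        ci = np.zeros(n)
        ci[i] = 1
        lo = linprog(ci, A_eq=A_eq, b_eq=b_eq, bounds=bounds, method="highs")
        hi = linprog(-ci, A_eq=A_eq, b_eq=b_eq, bounds=bounds, method="highs")
        assert lo.success and hi.success
        ranges[rid] = (lo.fun, -hi.fun)
    return fmax, ranges
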