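"""Independent test oracles: tiny-model builder and brute-force LP solver."""

import itertools

import numpy as np

from twocellfba import MetabolicModel, Metabolite, Reaction


def _net(reactions):
    """Small-model helper: reactions as (id, stoich, lo, hi)."""
    mids = sorted({m for _, s, _, _ in reactions for m in s})
    mets = [Metabolite(m, m.rsplit("_", 1)[0], "cytoplasm") for m in mids]
    rxns = [Reaction(rid, s, lo, hi, reversible=lo < 0) for rid, s, lo, hi in reactions]
    return MetabolicModel(metabolites=mets, reactions=rxns)


def brute_force_fba(model, objective_id):
    """Enumerate basic feasible solutions of the flux polytope.

    Every vertex of {S v = 0, lb <= v <= ub} has (n - rank S) variables at
    a bound; the optimum of a bounded feasible LP is attained at a vertex,
    so exhaustive enumeration is an independent oracle for small networks.
    """
    S = model.stoichiometric_matrix().toarray()
    n = S.shape[1]
    lb = np.array([r.lower_bound for r in model.reactions])
    ub = np.array([r.upper_bound for r in model.reactions])
    c = np.array([1.0 if r.id == objective_id else 0.0 for r in model.reactions])
    rank = np.linalg.matrix_rank(S)
    best = -np.inf
    for basic in itertools.combinations(range(n), rank):
        B = S[:, basic]
        if np.linalg.matrix_rank(B) < rank:
            continue
        nonbasic = [j for j in range(n) if j not in basic]
        for choice in itertools.product(*[(lb[j], ub[j]) for j in nonbasic]):
            x = np.zeros(n)
            x[nonbasic] = choice
            sol, *_ = np.linalg.lstsq(B, -S[:, nonbasic] @ np.array(choice), rcond=None)
            x[list(basic)] = sol
            if np.max(np.abs(S @ x)) > 1e-7:
                continue
            if np.any(x < lb - 1e-9) or np.any(x > ub + 1e-9):
                continue
            best = max(best, float(c @ x))
    return best
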