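"""Linear programs for constraint-based analysis.

Formulates and solves, with scipy's HiGHS backend:

* FBA — maximize an objective flux subject to S.v = b and bounds,
* FVA — per-reaction flux ranges at a fraction of the optimum,
* L1 (Manhattan-norm) minimal flux distributions at fixed objective values,
  used for all reported flux distributions to avoid solution degeneracy,
* 2-D robustness scans (objective re-optimized over a grid of two fixed
  fluxes), and
* metabolite turnover (total production = consumption at steady state).

Every solve returns a :class:`FluxSolution` carrying primal fluxes, the
dual value (shadow price) of every equality row, and reduced costs.  Extra
linear equality rows beyond the metabolite balances — the photon-sharing
and biomass-coupling rows of the two-cell model and the per-gene expression
rows of the regulated model — are expressed as :class:`LinearConstraint`
objects; inequalities are written as equalities with an explicit
non-negative slack variable, and their duals are read from the equality
rows, matching the slack formulation used throughout.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .model_io import (
    COMPARISON_TOL,
    MetabolicModel,
    ModelError,
)

INFEASIBLE = "infeasible"
OPTIMAL = "optimal"
UNBOUNDED = "unbounded"

_STATUS = {0: OPTIMAL, 1: "iteration_limit", 2: INFEASIBLE, 3: UNBOUNDED, 4: "numerical"}


@dataclass(frozen=True)
class LinearConstraint:
    """An equality row  sum_i coeffs_i * v_i (+ slack) = rhs.

    When ``slack`` is a name, a dedicated variable with bounds
    ``slack_bounds`` (default non-negative) is appended, turning an
    original <= row into an equality; its dual is read off the row.
    """

    name: str
    coeffs: Mapping[str, float]
    rhs: float
    slack: str | None = None
    slack_bounds: tuple[float, float] = (0.0, np.inf)


@dataclass
class FluxSolution:
    status: str
    objective_value: float
    fluxes: dict[str, float] = field(default_factory=dict)
    duals: dict[str, float] = field(default_factory=dict)
    reduced_costs: dict[str, float] = field(default_factory=dict)
    slacks: dict[str, float] = field(default_factory=dict)
    raw_fluxes: dict[str, float] | None = None  # expanded-model fluxes, if any

    @property
    def optimal(self) -> bool:
        return self.status == OPTIMAL


# ---------------------------------------------------------------------------
# model-like protocol
# ---------------------------------------------------------------------------


def lp_parts(model_like) -> tuple[MetabolicModel, list[LinearConstraint]]:
    """Accept a bare MetabolicModel or any wrapper with .model/.constraints."""
    if isinstance(model_like, MetabolicModel):
        return model_like, []
    return model_like.model, list(model_like.constraints)


def expand_overrides(
    model_like, overrides: Mapping[str, tuple[float, float]] | None
) -> dict[str, tuple[float, float]]:
    """Translate bound overrides keyed by original reaction ids.

    Wrappers over an irreversible-split model implement
    ``translate_overrides``; for plain models the mapping is the identity.
    """
    if not overrides:
        return {}
    if hasattr(model_like, "translate_overrides"):
        return model_like.translate_overrides(dict(overrides))
    return dict(overrides)


def _default_objective(model: MetabolicModel, objective_id: str | None) -> str:
    obj = objective_id or model.objective_id
    if obj is None:
        raise ModelError("no objective reaction given and model has none")
    if obj not in set(model.reaction_ids):
        raise ModelError(f"objective reaction {obj!r} not in model")
    return obj


# ---------------------------------------------------------------------------
# core solver
# ---------------------------------------------------------------------------


def _assemble(
    model: MetabolicModel,
    constraints: Sequence[LinearConstraint],
    overrides: Mapping[str, tuple[float, float]],
):
    rids = model.reaction_ids
    ridx = {r: j for j, r in enumerate(rids)}
    slack_names = [c.slack for c in constraints if c.slack is not None]
    nvar = len(rids) + len(slack_names)
    slack_idx = {s: len(rids) + k for k, s in enumerate(slack_names)}

    S = model.stoichiometric_matrix()
    rows, cols, vals = [], [], []
    for i, con in enumerate(constraints):
        for rid, coef in con.coeffs.items():
            if rid not in ridx:
                raise ModelError(f"constraint {con.name!r} references unknown id {rid!r}")
            rows.append(len(model.metabolites) + i)
            cols.append(ridx[rid])
            vals.append(coef)
        if con.slack is not None:
            rows.append(len(model.metabolites) + i)
            cols.append(slack_idx[con.slack])
            vals.append(1.0)
    extra = sparse.csr_matrix(
        (vals, (rows, cols)), shape=(len(model.metabolites) + len(constraints), nvar)
    )
    A = sparse.vstack(
        [sparse.hstack([S, sparse.csr_matrix((S.shape[0], len(slack_names)))]), extra[S.shape[0]:]]
    ).tocsc()
    b = np.concatenate([model.b, [c.rhs for c in constraints]])

    bounds = []
    for r in model.reactions:
        lo, hi = overrides.get(r.id, (r.lower_bound, r.upper_bound))
        bounds.append((lo, hi))
    for c in constraints:
        if c.slack is not None:
            bounds.append(c.slack_bounds)
    row_names = model.metabolite_ids + [c.name for c in constraints]
    var_names = rids + slack_names
    return A, b, bounds, row_names, var_names


def _solve(
    model: MetabolicModel,
    constraints: Sequence[LinearConstraint],
    objective: Mapping[str, float],
    maximize: bool,
    overrides: Mapping[str, tuple[float, float]],
) -> FluxSolution:
    A, b, bounds, row_names, var_names = _assemble(model, constraints, overrides)
    vidx = {v: j for j, v in enumerate(var_names)}
    c = np.zeros(len(var_names))
    for vid, coef in objective.items():
        c[vidx[vid]] = coef
    sign = -1.0 if maximize else 1.0
    res = linprog(sign * c, A_eq=A, b_eq=b, bounds=bounds, method="highs")
    status = _STATUS.get(res.status, "failed")
    if status != OPTIMAL:
        return FluxSolution(status=status, objective_value=np.nan)
    x = res.x
    nrxn = len(model.reactions)
    fluxes = {v: float(x[j]) for v, j in vidx.items() if j < nrxn}
    slacks = {v: float(x[j]) for v, j in vidx.items() if j >= nrxn}
    # HiGHS marginals are d(min objective)/d(rhs); negate for a maximization
    duals = {
        name: float(sign * res.eqlin.marginals[i]) for i, name in enumerate(row_names)
    }
    rc = sign * (res.lower.marginals + res.upper.marginals)
    reduced = {v: float(rc[j]) for v, j in vidx.items() if j < nrxn}
    return FluxSolution(
        status=OPTIMAL,
        objective_value=float(sign * res.fun) if maximize else float(res.fun),
        fluxes=fluxes,
        duals=duals,
        reduced_costs=reduced,
        slacks=slacks,
    )


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def fba(
    model_like,
    objective_id: str | None = None,
    maximize: bool = True,
    overrides: Mapping[str, tuple[float, float]] | None = None,
) -> FluxSolution:
    """Flux balance analysis: optimize one reaction flux at steady state.

    Infeasible or unbounded problems are reported through the status flag,
    never as exceptions.
    """
    model, constraints = lp_parts(model_like)
    obj = _default_objective(model, objective_id)
    ov = expand_overrides(model_like, overrides)
    objective = _objective_vector(model_like, obj)
    return _solve(model, constraints, objective, maximize, ov)


def _objective_vector(model_like, objective_id: str) -> dict[str, float]:
    """Objective as coefficients over model columns (wrapper-aware)."""
    if hasattr(model_like, "translate_objective"):
        return model_like.translate_objective(objective_id)
    return {objective_id: 1.0}


def fva(
    model_like,
    reaction_ids: Sequence[str] | None = None,
    fraction_of_optimum: float = 1.0,
    objective_id: str | None = None,
    overrides: Mapping[str, tuple[float, float]] | None = None,
) -> dict[str, tuple[float, float]]:
    """Flux variability: per-reaction min/max at >= fraction * optimum."""
    if not 0.0 <= fraction_of_optimum <= 1.0:
        raise ValueError("fraction_of_optimum must be in [0, 1]")
    model, constraints = lp_parts(model_like)
    obj = _default_objective(model, objective_id)
    base = fba(model_like, obj, overrides=overrides)
    if not base.optimal:
        raise ModelError(f"base FBA problem is {base.status}; cannot run FVA")
    floor = fraction_of_optimum * base.objective_value
    constraints = list(constraints) + [
        # objective >= floor, written as objective + s = floor with s <= 0
        LinearConstraint(
            name="__fva_objective_floor",
            coeffs=_objective_vector(model_like, obj),
            rhs=floor,
            slack="__fva_obj_slack",
            slack_bounds=(-np.inf, 0.0),
        )
    ]
    ov = expand_overrides(model_like, overrides)
    if reaction_ids is None:
        reaction_ids = model.reaction_ids
    out: dict[str, tuple[float, float]] = {}
    for rid in reaction_ids:
        coeffs = _objective_vector(model_like, rid)
        lo = _solve(model, constraints, coeffs, maximize=False, overrides=ov)
        hi = _solve(model, constraints, coeffs, maximize=True, overrides=ov)
        if not (lo.optimal and hi.optimal):
            raise ModelError(f"FVA subproblem for {rid!r} was not optimal")
        out[rid] = (lo.objective_value, hi.objective_value)
    return out


def l1_minimal_solution(
    model_like,
    fixed: Mapping[str, float | tuple[float, float]] | None = None,
) -> FluxSolution:
    """Minimize the Manhattan norm sum_i |v_i| under the given fixings.

    Each flux is split into non-negative forward/backward parts; the
    reported distribution is feasible for the original problem and its
    norm is the global minimum under the fixings.  Used for all reported
    flux distributions, to avoid the degeneracy of plain FBA optima.
    """
    model, constraints = lp_parts(model_like)
    overrides: dict[str, tuple[float, float]] = {}
    for rid, v in (fixed or {}).items():
        overrides[rid] = (v, v) if np.isscalar(v) else (v[0], v[1])
    ov = expand_overrides(model_like, overrides)

    rids = model.reaction_ids
    slack_names = [c.slack for c in constraints if c.slack is not None]
    S = model.stoichiometric_matrix()
    m = len(model.metabolites)
    nr = len(rids)

    # columns: p_i (forward), q_i (backward), then constraint slacks
    blocks = [S, -S]
    rows, cols, vals = [], [], []
    for i, con in enumerate(constraints):
        for rid, coef in con.coeffs.items():
            j = rids.index(rid)
            rows.append(i)
            cols.append(j)
            vals.append(coef)
            rows.append(i)
            cols.append(nr + j)
            vals.append(-coef)
        if con.slack is not None:
            rows.append(i)
            cols.append(2 * nr + slack_names.index(con.slack))
            vals.append(1.0)
    extra = sparse.csr_matrix((vals, (rows, cols)), shape=(len(constraints), 2 * nr + len(slack_names)))
    top = sparse.hstack([S, -S, sparse.csr_matrix((m, len(slack_names)))])
    A = sparse.vstack([top, extra]).tocsc()
    b = np.concatenate([model.b, [c.rhs for c in constraints]])

    bounds: list[tuple[float, float]] = []
    for r in model.reactions:
        lo, hi = ov.get(r.id, (r.lower_bound, r.upper_bound))
        bounds.append((max(0.0, lo), max(0.0, hi)))  # p
    for r in model.reactions:
        lo, hi = ov.get(r.id, (r.lower_bound, r.upper_bound))
        bounds.append((max(0.0, -hi), max(0.0, -lo)))  # q
    for c in constraints:
        if c.slack is not None:
            bounds.append(c.slack_bounds)

    cost = np.concatenate([np.ones(2 * nr), np.zeros(len(slack_names))])
    res = linprog(cost, A_eq=A, b_eq=b, bounds=bounds, method="highs")
    status = _STATUS.get(res.status, "failed")
    if status != OPTIMAL:
        return FluxSolution(status=status, objective_value=np.nan)
    p, q = res.x[:nr], res.x[nr : 2 * nr]
    fluxes = {rid: float(p[j] - q[j]) for j, rid in enumerate(rids)}
    slacks = {s: float(res.x[2 * nr + k]) for k, s in enumerate(slack_names)}
    duals = {
        name: float(res.eqlin.marginals[i])
        for i, name in enumerate(model.metabolite_ids + [c.name for c in constraints])
    }
    return FluxSolution(
        status=OPTIMAL,
        objective_value=float(res.fun),  # the L1 norm
        fluxes=fluxes,
        duals=duals,
        slacks=slacks,
    )


def robustness_2d(
    model_like,
    rxn_a: str,
    grid_a: Sequence[float],
    rxn_b: str,
    grid_b: Sequence[float],
    objective_id: str | None = None,
    overrides: Mapping[str, tuple[float, float]] | None = None,
) -> np.ndarray:
    """Objective optimum over a grid of two fixed fluxes.

    Entry (i, j) fixes rxn_a = grid_a[i] and rxn_b = grid_b[j]; infeasible
    cells are encoded as NaN (zero growth and infeasible are distinct).
    """
    out = np.full((len(grid_a), len(grid_b)), np.nan)
    for i, va in enumerate(grid_a):
        for j, vb in enumerate(grid_b):
            ov = dict(overrides or {})
            ov[rxn_a] = (va, va)
            ov[rxn_b] = (vb, vb)
            sol = fba(model_like, objective_id, overrides=ov)
            if sol.optimal:
                out[i, j] = sol.objective_value
    return out


def metabolite_turnover(model_like, solution: FluxSolution, metabolite_id: str) -> float:
    """Total production rate of a metabolite (= total consumption).

    Sums max(0, coeff * v) over all reactions; for wrappers the solution's
    raw (column-level) fluxes are used when present.
    """
    model, _ = lp_parts(model_like)
    if metabolite_id not in set(model.metabolite_ids):
        raise KeyError(f"unknown metabolite {metabolite_id!r}")
    fluxes = solution.raw_fluxes if solution.raw_fluxes is not None else solution.fluxes
    total = 0.0
    for r in model.reactions:
        coef = r.stoichiometry.get(metabolite_id)
        if coef and r.id in fluxes:
            total += max(0.0, coef * fluxes[r.id])
    return total
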