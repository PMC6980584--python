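"""Transcription-regulated FBA (TRFBA-style expression integration).

The metabolic model is first rewritten in irreversible, "without OR" form:
reversible reactions are split into forward/backward columns, and any
reaction whose GPR contains an OR is duplicated so that each copy carries
exactly one OR-alternative (a conjunction of genes), obtained from the
disjunctive normal form of the GPR tree.  For every measured metabolic
gene j (per cell copy) one equality row

    sum_{i in K_j} v_i + a_j = E_j * C,    a_j >= 0

bounds the summed flux of the reactions the gene supports by its
expression level E_j times the conversion constant C (mmol/gDCW/h per
expression unit).  C is calibrated by a sensitivity scan against an
observed growth rate, and the dual value of a gene's row is its shadow
price — the sensitivity of growth to the right-hand side E_j * C; the
paper-style per-expression-unit price is dual * C.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .fba_core import (
    FluxSolution,
    LinearConstraint,
    fba,
    lp_parts,
)
from .model_io import (
    COMPARISON_TOL,
    ExpressionDataset,
    MetabolicModel,
    ModelError,
    Reaction,
    gpr_genes,
    gpr_to_string,
    parse_gpr,
)
from .twocell import HETEROCYST, TwoCellModel, VEGETATIVE

logger = logging.getLogger("twocellfba")

#: default C grid for the sensitivity scan (log-spaced; the calibrated
#: optimum reported for the organism, 0.05 mmol/gDCW/h, sits mid-range)
DEFAULT_C_GRID = tuple(np.logspace(-4, 0, 25))


def gpr_dnf(rule: str) -> list[tuple[str, ...]]:
    """OR-alternatives of a GPR as sorted gene conjunctions (DNF)."""
    node = parse_gpr(rule)
    if node is None:
        return []

    def walk(n) -> list[frozenset[str]]:
        if isinstance(n, str):
            return [frozenset({n})]
        op, children = n
        child_alts = [walk(c) for c in children]
        if op == "or":
            out: list[frozenset[str]] = []
            for alts in child_alts:
                out.extend(alts)
            return out
        # AND: cartesian product of the children's alternatives
        out = []
        for combo in itertools.product(*child_alts):
            out.append(frozenset().union(*combo))
        return out

    seen: set[frozenset[str]] = set()
    alts: list[tuple[str, ...]] = []
    for alt in walk(node):
        if alt not in seen:
            seen.add(alt)
            alts.append(tuple(sorted(alt)))
    return alts


@dataclass
class ExpandedModel:
    """Irreversible, without-OR expansion of a (possibly two-cell) model.

    ``mapping`` sends each expanded column to (original id, direction,
    isozyme index); ``K`` maps each gene to the expanded columns it
    supports.  Carries the coupling rows of the source model remapped onto
    the expanded columns, so it is directly solvable.
    """

    model: MetabolicModel
    mapping: dict[str, tuple[str, int, int]]
    K: dict[str, tuple[str, ...]]
    constraints: list[LinearConstraint] = field(default_factory=list)
    source: TwoCellModel | None = None

    def columns_of(self, original_id: str) -> list[tuple[str, int]]:
        return [
            (eid, direction)
            for eid, (oid, direction, _) in self.mapping.items()
            if oid == original_id
        ]

    def translate_overrides(
        self, overrides: Mapping[str, tuple[float, float]]
    ) -> dict[str, tuple[float, float]]:
        """Bound overrides by original reaction id -> expanded columns.

        Only defined for reactions without isozyme duplicates (a bound on
        a sum of parallel copies is not a column bound).
        """
        out: dict[str, tuple[float, float]] = {}
        for rid, (lo, hi) in overrides.items():
            cols = self.columns_of(rid)
            if not cols:
                raise ModelError(f"override target {rid!r} not in expansion")
            n_iso = len({self.mapping[eid][2] for eid, _ in cols})
            if n_iso > 1:
                raise ModelError(
                    f"cannot translate a bound on {rid!r}: it has isozyme copies"
                )
            for eid, direction in cols:
                if direction > 0:
                    out[eid] = (max(0.0, lo), max(0.0, hi))
                else:
                    out[eid] = (max(0.0, -hi), max(0.0, -lo))
        return out

    def translate_objective(self, original_id: str) -> dict[str, float]:
        cols = self.columns_of(original_id)
        if not cols:
            raise ModelError(f"objective {original_id!r} not in expansion")
        return {eid: float(direction) for eid, direction in cols}

    def map_fluxes_back(self, fluxes: Mapping[str, float]) -> dict[str, float]:
        out: dict[str, float] = {}
        for eid, (oid, direction, _) in self.mapping.items():
            out[oid] = out.get(oid, 0.0) + direction * fluxes.get(eid, 0.0)
        return out


def _remap_constraint(
    con: LinearConstraint, columns_of: Mapping[str, list[tuple[str, int]]]
) -> LinearConstraint:
    coeffs: dict[str, float] = {}
    for rid, coef in con.coeffs.items():
        for eid, direction in columns_of[rid]:
            coeffs[eid] = coeffs.get(eid, 0.0) + coef * direction
    return LinearConstraint(
        name=con.name, coeffs=coeffs, rhs=con.rhs, slack=con.slack,
        slack_bounds=con.slack_bounds,
    )


def to_irreversible_no_or(model_like) -> ExpandedModel:
    """Expand a model (or TwoCellModel) to irreversible, without-OR form.

    The expanded feasible set reproduces the original flux space through
    ``mapping`` (forward minus backward, summed over isozyme copies); the
    FBA optimum is unchanged.
    """
    model, constraints = lp_parts(model_like)
    source = model_like if isinstance(model_like, TwoCellModel) else None

    metabolites = list(model.metabolites)
    reactions: list[Reaction] = []
    mapping: dict[str, tuple[str, int, int]] = {}
    K: dict[str, set[str]] = {}
    columns_of: dict[str, list[tuple[str, int]]] = {}

    for r in model.reactions:
        alts = gpr_dnf(r.gpr) if r.gpr else []
        copies: list[tuple[int, tuple[str, ...]]] = (
            list(enumerate(alts)) if len(alts) > 1 else [(0, alts[0] if alts else ())]
        )
        columns_of[r.id] = []
        for iso, genes in copies:
            base_id = r.id if len(copies) == 1 else f"{r.id}__iso{iso + 1}"
            gpr = " and ".join(genes)
            fwd_lo, fwd_hi = max(0.0, r.lower_bound), max(0.0, r.upper_bound)
            reactions.append(
                Reaction(
                    id=base_id,
                    stoichiometry=dict(r.stoichiometry),
                    lower_bound=fwd_lo,
                    upper_bound=fwd_hi,
                    gpr=gpr,
                    reversible=False,
                    subsystem=r.subsystem,
                )
            )
            mapping[base_id] = (r.id, +1, iso)
            columns_of[r.id].append((base_id, +1))
            for g in genes:
                K.setdefault(g, set()).add(base_id)
            if r.lower_bound < 0:
                rev_id = f"{base_id}__rev"
                reactions.append(
                    Reaction(
                        id=rev_id,
                        stoichiometry={m: -c for m, c in r.stoichiometry.items()},
                        lower_bound=max(0.0, -r.upper_bound),
                        upper_bound=-r.lower_bound,
                        gpr=gpr,
                        reversible=False,
                        subsystem=r.subsystem,
                    )
                )
                mapping[rev_id] = (r.id, -1, iso)
                columns_of[r.id].append((rev_id, -1))
                for g in genes:
                    K.setdefault(g, set()).add(rev_id)

    expanded = MetabolicModel(
        metabolites=metabolites,
        reactions=reactions,
        objective_id=None,  # objectives are translated per call
        id=f"{model.id}_irrev",
    )
    remapped = [_remap_constraint(c, columns_of) for c in constraints]
    return ExpandedModel(
        model=expanded,
        mapping=mapping,
        K={g: tuple(sorted(v)) for g, v in K.items()},
        constraints=remapped,
        source=source,
    )


# ---------------------------------------------------------------------------
# regulation layer
# ---------------------------------------------------------------------------


def gene_row_name(cell: str, gene: str) -> str:
    return f"{cell}_{gene}" if cell else gene


@dataclass
class RegulatedModel:
    """Expanded model plus one expression row (and slack a_j) per gene/cell."""

    expanded: ExpandedModel
    C: float
    expression: ExpressionDataset
    gene_rows: list[LinearConstraint]
    cells: tuple[str, ...] = (VEGETATIVE, HETEROCYST)
    n_added_variables: int = 0
    n_added_equations: int = 0

    @property
    def model(self) -> MetabolicModel:
        return self.expanded.model

    @property
    def constraints(self) -> list[LinearConstraint]:
        return list(self.expanded.constraints) + list(self.gene_rows)

    @property
    def source(self) -> TwoCellModel | None:
        return self.expanded.source

    def translate_overrides(self, overrides):
        return self.expanded.translate_overrides(overrides)

    def translate_objective(self, objective_id):
        return self.expanded.translate_objective(objective_id)

    def map_fluxes_back(self, fluxes):
        return self.expanded.map_fluxes_back(fluxes)


def add_expression_constraints(
    expanded: ExpandedModel,
    expr: ExpressionDataset,
    C: float,
    cells: Sequence[str] = (VEGETATIVE, HETEROCYST),
) -> RegulatedModel:
    """Add the per-gene equality rows  sum_{i in K_j} v_i + a_j = E_j * C.

    Vegetative rows use E_veg, heterocyst rows E_het; rows and slacks are
    named with the gene id and the cell prefix.  Genes that support no
    reaction in a copy are skipped with a logged warning.
    """
    if C <= 0:
        raise ModelError("C must be positive")
    expr.validate()
    levels = {VEGETATIVE: expr.E_veg, HETEROCYST: expr.E_het}
    rows: list[LinearConstraint] = []
    skipped: list[str] = []
    for cell in cells:
        table = levels.get(cell, expr.E_veg)
        for gene in expr.genes:
            key = f"{cell}_{gene}" if cell else gene
            cols = expanded.K.get(key, ())
            if not cols:
                skipped.append(key)
                continue
            rows.append(
                LinearConstraint(
                    name=gene_row_name(cell, gene),
                    coeffs={eid: 1.0 for eid in cols},
                    rhs=table[gene] * C,
                    slack=f"a_{gene_row_name(cell, gene)}",
                )
            )
    if skipped:
        logger.warning(
            "%d measured genes support no reaction and were skipped (e.g. %s)",
            len(skipped), ", ".join(skipped[:5]),
        )
    return RegulatedModel(
        expanded=expanded,
        C=C,
        expression=expr,
        gene_rows=rows,
        cells=tuple(cells),
        n_added_variables=len(rows),
        n_added_equations=len(rows),
    )


def regulated_fba(
    rm: RegulatedModel,
    objective_id: str | None = None,
    overrides: Mapping[str, tuple[float, float]] | None = None,
) -> FluxSolution:
    """FBA on the expanded, gene-constrained LP.

    The returned fluxes are mapped back to original reaction ids; the
    expanded column values are kept in ``raw_fluxes`` and the gene-row
    duals (shadow-price inputs) in ``duals``.
    """
    obj = objective_id
    if obj is None and rm.source is not None:
        obj = rm.source.model.objective_id
    if obj is None:
        raise ModelError("no objective given")
    sol = fba(rm, obj, overrides=overrides)
    if sol.optimal:
        sol.raw_fluxes = dict(sol.fluxes)
        sol.fluxes = rm.map_fluxes_back(sol.raw_fluxes)
    return sol


def regulate_two_cell(
    tc: TwoCellModel, expr: ExpressionDataset, C: float
) -> RegulatedModel:
    """Convenience: expand a two-cell model and add its expression rows."""
    return add_expression_constraints(to_irreversible_no_or(tc), expr, C)


def scan_C(
    expanded: ExpandedModel,
    expr: ExpressionDataset,
    objective_id: str,
    c_grid: Sequence[float] = DEFAULT_C_GRID,
    observed_growth: float = 0.0,
    growth_factor: float = 1.1,
) -> tuple[float, list[tuple[float, float]]]:
    """Sensitivity scan of the growth-prediction error over C values.

    For each C the regulated optimum (scaled by ``growth_factor`` to a
    total filament growth) is compared with the observed growth; returns
    (argmin C, [(C, relative error), ...]).  Ties break to the smallest C.
    """
    if observed_growth <= 0:
        raise ModelError("observed growth must be positive")
    if not len(c_grid):
        raise ModelError("empty C grid")
    curve: list[tuple[float, float]] = []
    for C in sorted(c_grid):
        if C <= 0:
            raise ModelError("C grid values must be positive")
        rm = add_expression_constraints(expanded, expr, C)
        sol = regulated_fba(rm, objective_id)
        predicted = growth_factor * sol.objective_value if sol.optimal else np.nan
        error = abs(predicted - observed_growth) / observed_growth
        curve.append((float(C), float(error)))
    feasible = [(C, e) for C, e in curve if np.isfinite(e)]
    if not feasible:
        raise ModelError("regulated model infeasible over the whole C grid")
    best = min(feasible, key=lambda ce: (round(ce[1], 12), ce[0]))
    return best[0], curve


def gene_shadow_prices(
    rm: RegulatedModel, solution: FluxSolution, slack_tol: float = 1e-6
) -> dict[tuple[str, str], tuple[float, float]]:
    """Per-gene shadow prices from the expression-row duals.

    Returns {(cell, gene): (dual, per_expression_unit)} where dual is the
    sensitivity of the objective to the row's right-hand side E_j * C and
    per_expression_unit = dual * C (the effect of one unit of expression).
    Rows whose slack a_j exceeds ``slack_tol`` are unbinding and get 0 by
    complementary slackness.
    """
    if not solution.duals:
        raise ModelError("solution carries no dual values")
    out: dict[tuple[str, str], tuple[float, float]] = {}
    for row in rm.gene_rows:
        cell, gene = row.name.split("_", 1)
        dual = solution.duals.get(row.name, 0.0)
        if solution.slacks.get(row.slack, 0.0) > slack_tol:
            dual = 0.0
        out[(cell, gene)] = (dual, dual * rm.C)
    return out
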