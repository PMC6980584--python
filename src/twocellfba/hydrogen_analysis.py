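"""Hydrogen-production analyses on the (regulated) two-cell model.

* per-cell H2 x O2 double-robustness surfaces (growth re-optimized over a
  grid of the named cell's hydrogen and oxygen exchange fluxes),
* maximal/minimal H2 secretion at a fixed fraction (default 90%) of the
  optimal growth rate, with Manhattan-norm-minimal flux distributions at
  each extreme,
* differential flux classification (which reactions go up or down between
  the minimal- and maximal-H2 states) and the fraction of hydrogen made by
  the bidirectional Hox hydrogenase,
* in-silico knockouts (uptake hydrogenase, Hox) and their effect on the
  attainable H2 maximum.

Hydrogen production is measured at the H2 exchange flux (secretion), not
at enzyme level.  Knockouts are implemented by zero-bounding the listed
reactions, which is LP-equivalent to removing the columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .fba_core import (
    FluxSolution,
    fba,
    l1_minimal_solution,
    lp_parts,
    robustness_2d,
)
from .model_io import ModelError
from .twocell import HETEROCYST, VEGETATIVE

#: classification threshold for up/down flux changes (solver-noise floor)
FLUX_CHANGE_THRESHOLD = 1e-6


@dataclass
class H2Experiment:
    """Configuration of a hydrogen-production experiment on a cell type."""

    cell: str = HETEROCYST
    growth_fraction: float = 0.90
    h2_exchange_id: str = ""  # defaults to <cell>_EX_h2_c
    o2_exchange_id: str = ""
    hox_ids: tuple[str, ...] = ()
    hup_ids: tuple[str, ...] = ()
    nitrogenase_ids: tuple[str, ...] = ()
    flux_change_threshold: float = FLUX_CHANGE_THRESHOLD

    def __post_init__(self) -> None:
        if not 0.0 < self.growth_fraction <= 1.0:
            raise ModelError("growth_fraction must be in (0, 1]")
        if not self.h2_exchange_id:
            self.h2_exchange_id = f"{self.cell}_EX_h2_c"
        if not self.o2_exchange_id:
            self.o2_exchange_id = f"{self.cell}_EX_o2_c"
        if not self.hox_ids:
            self.hox_ids = (f"{self.cell}_HOX",)
        if not self.hup_ids:
            self.hup_ids = (f"{self.cell}_HUP",)
        if not self.nitrogenase_ids and self.cell == HETEROCYST:
            self.nitrogenase_ids = (f"{self.cell}_NIT",)


@dataclass
class DifferentialFluxReport:
    """Reactions whose fluxes rise/fall from the min-H2 to the max-H2 state."""

    up: list[tuple[str, float, float]] = field(default_factory=list)
    down: list[tuple[str, float, float]] = field(default_factory=list)
    unchanged: int = 0
    hox_fraction_max: float | None = None


def _objective_id(model_like) -> str:
    model, _ = lp_parts(model_like)
    src = getattr(model_like, "source", None)
    if model.objective_id:
        return model.objective_id
    if src is not None:
        return src.model.objective_id
    raise ModelError("model has no objective reaction")


def _check_ids(model_like, ids: Sequence[str]) -> None:
    model, _ = lp_parts(model_like)
    known = set(model.reaction_ids)
    wrapper = getattr(model_like, "expanded", model_like)
    if hasattr(wrapper, "mapping"):
        # expansions address reactions by their original ids too
        known |= {oid for (oid, _, _) in wrapper.mapping.values()}
    missing = [i for i in ids if i not in known]
    if missing:
        raise ModelError(f"unknown reaction ids: {missing}")


def h2_o2_surface(
    model_like,
    cell: str = HETEROCYST,
    h2_grid: Sequence[float] = (),
    o2_grid: Sequence[float] = (),
    experiment: H2Experiment | None = None,
) -> np.ndarray:
    """Growth optimum over a grid of fixed H2 and O2 exchange fluxes.

    Rows follow h2_grid, columns o2_grid; infeasible cells are NaN.  The
    objective is the vegetative biomass reaction, as in the filament model.
    """
    exp = experiment or H2Experiment(cell=cell)
    _check_ids(model_like, [exp.h2_exchange_id, exp.o2_exchange_id])
    return robustness_2d(
        model_like,
        exp.h2_exchange_id,
        list(h2_grid),
        exp.o2_exchange_id,
        list(o2_grid),
        objective_id=_objective_id(model_like),
    )


def h2_range_at_suboptimal_growth(
    model_like,
    exp: H2Experiment | None = None,
    overrides: Mapping[str, tuple[float, float]] | None = None,
) -> tuple[float, float, FluxSolution, FluxSolution]:
    """Min and max H2 secretion at growth_fraction x optimal growth.

    Growth is pinned to the fraction of the model's own optimum, H2
    secretion is minimized then maximized, and each extreme is reported as
    the Manhattan-norm-minimal flux distribution at its (growth, H2)
    fixing.  Returns (h2_min, h2_max, sol_min, sol_max).
    """
    exp = exp or H2Experiment()
    obj = _objective_id(model_like)
    _check_ids(model_like, [exp.h2_exchange_id])
    base = fba(model_like, obj, overrides=overrides)
    if not base.optimal:
        raise ModelError(f"growth optimization is {base.status}")
    target = exp.growth_fraction * base.objective_value
    ov = dict(overrides or {})
    ov[obj] = (target, target)

    extremes = {}
    for label, maximize in (("min", False), ("max", True)):
        sol = fba(model_like, exp.h2_exchange_id, maximize=maximize, overrides=ov)
        if not sol.optimal:
            raise ModelError(f"H2 {label}imization at fixed growth is {sol.status}")
        h2 = sol.objective_value
        fixed = dict(ov)
        fixed[exp.h2_exchange_id] = (h2, h2)
        l1 = l1_minimal_solution(model_like, fixed=fixed)
        if not l1.optimal:
            raise ModelError(f"L1 minimization at the H2 {label}imum failed")
        if hasattr(model_like, "map_fluxes_back"):
            l1.raw_fluxes = dict(l1.fluxes)
            l1.fluxes = model_like.map_fluxes_back(l1.raw_fluxes)
        extremes[label] = (h2, l1)

    h2_min, sol_min = extremes["min"]
    h2_max, sol_max = extremes["max"]
    return h2_min, h2_max, sol_min, sol_max


def hox_fraction(model_like, solution: FluxSolution, exp: H2Experiment) -> float:
    """Fraction of total H2 production catalyzed by the Hox hydrogenase.

    Computed on stoichiometric H2 production (sum of positive H2-making
    rates) in the given distribution, so the value lies in [0, 1] even
    when part of the hydrogen is internally recycled.
    """
    model, _ = lp_parts(model_like)
    ex_rxn = model.reaction(exp.h2_exchange_id) if exp.h2_exchange_id in set(
        model.reaction_ids
    ) else None
    if ex_rxn is None:
        # wrapper: resolve through the source two-cell model
        src = getattr(model_like, "source", None)
        if src is None:
            raise ModelError(f"H2 exchange {exp.h2_exchange_id!r} not found")
        ex_rxn = src.model.reaction(exp.h2_exchange_id)
        model = src.model
    (h2_met,) = ex_rxn.stoichiometry.keys()

    fluxes = solution.fluxes
    total = 0.0
    via_hox = 0.0
    for r in model.reactions:
        coef = r.stoichiometry.get(h2_met)
        if not coef:
            continue
        made = max(0.0, coef * fluxes.get(r.id, 0.0))
        total += made
        if r.id in exp.hox_ids:
            via_hox += made
    return via_hox / total if total > 0 else 0.0


def differential_flux(
    sol_min: FluxSolution,
    sol_max: FluxSolution,
    threshold: float = FLUX_CHANGE_THRESHOLD,
    model_like=None,
    experiment: H2Experiment | None = None,
) -> DifferentialFluxReport:
    """Classify reactions by their flux change from min-H2 to max-H2.

    Up if flux_max - flux_min > threshold, down if < -threshold, else
    unchanged.  When a model and experiment are given, the Hox share of
    hydrogen production in the max-H2 state is attached.
    """
    if set(sol_min.fluxes) != set(sol_max.fluxes):
        raise ModelError("solutions cover different reaction sets")
    report = DifferentialFluxReport()
    for rid in sorted(sol_min.fluxes):
        lo, hi = sol_min.fluxes[rid], sol_max.fluxes[rid]
        if hi - lo > threshold:
            report.up.append((rid, lo, hi))
        elif hi - lo < -threshold:
            report.down.append((rid, lo, hi))
        else:
            report.unchanged += 1
    if model_like is not None and experiment is not None:
        report.hox_fraction_max = hox_fraction(model_like, sol_max, experiment)
    return report


def knockout_h2(
    model_like,
    exp: H2Experiment | None = None,
    knockout_ids: Sequence[str] = (),
) -> tuple[float, float]:
    """Max H2 at suboptimal growth before and after deleting reactions.

    The knockout model's own (possibly lower) growth optimum defines its
    90% target, so removing a growth-promoting recycler such as the uptake
    hydrogenase can raise the attainable H2 maximum.
    Returns (h2_max_wildtype, h2_max_knockout).
    """
    exp = exp or H2Experiment()
    if not knockout_ids:
        raise ModelError("no knockout ids given")
    _check_ids(model_like, knockout_ids)
    obj = _objective_id(model_like)
    if obj in set(knockout_ids):
        raise ModelError("cannot delete the objective reaction")
    h2_wt = h2_range_at_suboptimal_growth(model_like, exp)[1]
    ko = {rid: (0.0, 0.0) for rid in knockout_ids}
    h2_ko = h2_range_at_suboptimal_growth(model_like, exp, overrides=ko)[1]
    return h2_wt, h2_ko
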