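"""Two-cell (vegetative + heterocyst) model composition.

Two prefixed copies of a base model are merged; cell-specific reactions
are removed as columns (nitrogenase from the vegetative copy; PSII,
RuBisCO/Calvin, carbonic anhydrase and Fd-GOGAT from the heterocyst copy);
three reversible periplasm-to-periplasm shuttles (sucrose, glutamate,
glutamine) link the copies; and two coupling rows close the model:

* photon sharing — uptake_V + uptake_H + slack = photon_max, slack >= 0,
* biomass coupling — v_growth,H = f * v_growth,V with heterocyst fraction
  f = 0.10 by default.

Reported total growth is total_growth_factor (default 1.1) times the
vegetative growth rate.  Bicarbonate uptake is enabled only for the
vegetative copy and dinitrogen uptake only for the heterocyst copy;
condition presets (diazotrophic / nitrate autotrophy, heterotrophy on
fructose) adjust the exchange bounds and the photon budget.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .fba_core import FluxSolution, LinearConstraint, fba
from .model_io import (
    MetabolicModel,
    Metabolite,
    ModelError,
    Reaction,
    prefix_gpr,
)
from . import synthetic_model as _syn

VEGETATIVE = "Vegetative"
HETEROCYST = "Heterocyst"

PHOTON_ROW = "photon_budget"
PHOTON_SLACK = "photon_slack"
COUPLING_ROW = "biomass_coupling"

CONDITIONS = ("diazotrophic_auto", "nitrate_auto", "heterotrophic")


@dataclass
class CellSpec:
    """Per-cell-type composition spec: id prefix and removed reactions."""

    prefix: str
    removed_reactions: tuple[str, ...] = ()
    allowed_uptakes: dict[str, float] = field(default_factory=dict)


def vegetative_spec() -> CellSpec:
    return CellSpec(prefix=VEGETATIVE, removed_reactions=tuple(_syn.VEGETATIVE_REMOVED))


def heterocyst_spec() -> CellSpec:
    return CellSpec(prefix=HETEROCYST, removed_reactions=tuple(_syn.HETEROCYST_REMOVED))


@dataclass
class ShuttleSpec:
    """Intercellular metabolite shuttle through the continuous periplasm."""

    shuttle_metabolites: tuple[str, ...] = ("suc_p", "glu_p", "gln_p")
    bounds: tuple[float, float] = (-1000.0, 1000.0)
    glutamine_glutamate_ratio_fixed: bool = False  # ref-model variant, off here


@dataclass
class TwoCellModel:
    """Merged, prefixed model plus the shuttle and coupling structure."""

    model: MetabolicModel
    photon_max: float
    veg: CellSpec
    het: CellSpec
    shuttle: ShuttleSpec
    heterocyst_fraction: float = 0.10
    total_growth_factor: float = 1.1
    photon_exchange_id: str = "EX_photon_e"
    base_n_reactions: int = 0
    base_n_metabolites: int = 0

    @property
    def veg_biomass(self) -> str:
        return f"{VEGETATIVE}_{self.base_objective}"

    @property
    def het_biomass(self) -> str:
        return f"{HETEROCYST}_{self.base_objective}"

    base_objective: str = "BIOMASS"

    @property
    def constraints(self) -> list[LinearConstraint]:
        return [
            LinearConstraint(
                name=PHOTON_ROW,
                coeffs={
                    f"{VEGETATIVE}_{self.photon_exchange_id}": -1.0,
                    f"{HETEROCYST}_{self.photon_exchange_id}": -1.0,
                },
                rhs=self.photon_max,
                slack=PHOTON_SLACK,
            ),
            LinearConstraint(
                name=COUPLING_ROW,
                coeffs={
                    self.het_biomass: 1.0,
                    self.veg_biomass: -self.heterocyst_fraction,
                },
                rhs=0.0,
            ),
        ]

    def copy(self) -> "TwoCellModel":
        new = _copy.copy(self)
        new.model = self.model.copy()
        return new

    def set_bounds(self, rid: str, lo: float, hi: float) -> None:
        r = self.model.reaction(rid)
        r.lower_bound, r.upper_bound = lo, hi


def _prefixed_copy(base: MetabolicModel, spec: CellSpec) -> tuple[list[Metabolite], list[Reaction]]:
    removed = set(spec.removed_reactions)
    unknown = removed - set(base.reaction_ids)
    if unknown:
        raise ModelError(f"{spec.prefix}: removed reactions not in base model: {sorted(unknown)}")
    if base.objective_id in removed:
        raise ModelError(f"{spec.prefix}: cannot remove the objective reaction")
    p = spec.prefix
    mets = [replace(m, id=f"{p}_{m.id}", name=f"{p} {m.name}") for m in base.metabolites]
    rxns = []
    for r in base.reactions:
        if r.id in removed:
            continue
        rxns.append(
            Reaction(
                id=f"{p}_{r.id}",
                stoichiometry={f"{p}_{mid}": c for mid, c in r.stoichiometry.items()},
                lower_bound=r.lower_bound,
                upper_bound=r.upper_bound,
                gpr=prefix_gpr(r.gpr, f"{p}_") if r.gpr else "",
                reversible=r.reversible,
                subsystem=r.subsystem,
            )
        )
    return mets, rxns


def compose_two_cell(
    base: MetabolicModel,
    veg: CellSpec | None = None,
    het: CellSpec | None = None,
    shuttle: ShuttleSpec | None = None,
    photon_max: float = 20.0,
    heterocyst_fraction: float = 0.10,
    total_growth_factor: float = 1.1,
    photon_exchange_id: str = "EX_photon_e",
    hco3_exchange_id: str = "EX_hco3_e",
    n2_exchange_id: str = "EX_n2_e",
) -> TwoCellModel:
    """Compose the vegetative + heterocyst model from one base model."""
    veg = veg or vegetative_spec()
    het = het or heterocyst_spec()
    shuttle = shuttle or ShuttleSpec()
    if veg.prefix == het.prefix:
        raise ModelError("cell prefixes must be distinct")
    if base.objective_id is None:
        raise ModelError("base model needs an objective (biomass) reaction")
    if photon_exchange_id not in set(base.reaction_ids):
        raise ModelError(f"photon exchange {photon_exchange_id!r} not in base model")

    mets_v, rxns_v = _prefixed_copy(base, veg)
    mets_h, rxns_h = _prefixed_copy(base, het)
    reactions = rxns_v + rxns_h
    metabolites = mets_v + mets_h

    met_ids = {m.id for m in metabolites}
    shuttles = []
    for mid in shuttle.shuttle_metabolites:
        a, b = f"{veg.prefix}_{mid}", f"{het.prefix}_{mid}"
        if a not in met_ids or b not in met_ids:
            raise ModelError(f"shuttle metabolite {mid!r} missing from a cell copy")
        shuttles.append(
            Reaction(
                id=f"SHUTTLE_{mid}",
                stoichiometry={a: -1.0, b: 1.0},
                lower_bound=shuttle.bounds[0],
                upper_bound=shuttle.bounds[1],
                reversible=shuttle.bounds[0] < 0,
                subsystem="Intercellular shuttle",
            )
        )
    reactions += shuttles

    merged = MetabolicModel(
        metabolites=metabolites,
        reactions=reactions,
        objective_id=f"{veg.prefix}_{base.objective_id}",
        id=f"{base.id}_twocell",
    )
    tc = TwoCellModel(
        model=merged,
        photon_max=photon_max,
        veg=veg,
        het=het,
        shuttle=shuttle,
        heterocyst_fraction=heterocyst_fraction,
        total_growth_factor=total_growth_factor,
        photon_exchange_id=photon_exchange_id,
        base_objective=base.objective_id,
        base_n_reactions=len(base.reactions),
        base_n_metabolites=len(base.metabolites),
    )
    # cell-exclusive uptakes: bicarbonate only vegetative, dinitrogen only heterocyst
    rid_set = set(merged.reaction_ids)
    for rid, cell_open in (
        (hco3_exchange_id, veg.prefix),
        (n2_exchange_id, het.prefix),
    ):
        for p in (veg.prefix, het.prefix):
            full = f"{p}_{rid}"
            if full not in rid_set:
                continue
            r = merged.reaction(full)
            if p != cell_open:
                r.lower_bound = 0.0
            elif rid == n2_exchange_id:
                r.lower_bound = -1000.0  # HCO3 keeps its base (limited) uptake
    # individual photon caps are replaced by the shared budget row
    for p in (veg.prefix, het.prefix):
        full = f"{p}_{photon_exchange_id}"
        if full in rid_set:
            merged.reaction(full).lower_bound = -1000.0
    for rid, cap in {**veg.allowed_uptakes}.items():
        merged.reaction(f"{veg.prefix}_{rid}").lower_bound = -abs(cap)
    for rid, cap in {**het.allowed_uptakes}.items():
        merged.reaction(f"{het.prefix}_{rid}").lower_bound = -abs(cap)
    return tc


def set_condition(
    tc: TwoCellModel,
    condition: str,
    fructose_uptake: float = 1.0,
    fructose_exchange_id: str = "EX_fru_e",
    hco3_exchange_id: str = "EX_hco3_e",
    no3_exchange_id: str = "EX_no3_e",
    hco3_uptake: float | None = None,
    photon_max: float | None = None,
) -> TwoCellModel:
    """Return a copy of the two-cell model under a named condition preset.

    * diazotrophic_auto — nitrate closed, N2 open (heterocyst), HCO3 open
      (vegetative), photon budget active.
    * nitrate_auto — as above with nitrate uptake open in both cells.
    * heterotrophic — fructose (<= 1 mmol/gDCW/h) for the vegetative cell
      replaces bicarbonate and photons.
    """
    if condition not in CONDITIONS:
        raise ModelError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")
    new = tc.copy()
    rid_set = set(new.model.reaction_ids)

    def set_lo(prefix: str, rid: str, lo: float) -> None:
        full = f"{prefix}_{rid}"
        if full in rid_set:
            new.model.reaction(full).lower_bound = lo

    for p in (VEGETATIVE, HETEROCYST):
        set_lo(p, no3_exchange_id, 0.0)
        set_lo(p, fructose_exchange_id, 0.0)
    if condition == "nitrate_auto":
        for p in (VEGETATIVE, HETEROCYST):
            set_lo(p, no3_exchange_id, -10.0)
    if condition == "heterotrophic":
        set_lo(VEGETATIVE, fructose_exchange_id, -abs(fructose_uptake))
        set_lo(VEGETATIVE, hco3_exchange_id, 0.0)
        set_lo(HETEROCYST, hco3_exchange_id, 0.0)
        new.photon_max = 0.0
    else:
        if hco3_uptake is not None:
            set_lo(VEGETATIVE, hco3_exchange_id, -abs(hco3_uptake))
        if photon_max is not None:
            new.photon_max = photon_max
    return new


def total_growth(solution: FluxSolution, tc: TwoCellModel) -> float:
    """Reported filament growth: total_growth_factor * vegetative growth."""
    if not solution.optimal:
        raise ModelError(f"solution is {solution.status}")
    fluxes = solution.fluxes
    return tc.total_growth_factor * fluxes[tc.veg_biomass]


def model_dimensions(tc: TwoCellModel) -> tuple[int, int]:
    """(variable count, equality-row count) of the composed LP.

    Variables: both cells' reaction fluxes, the three shuttles, and the
    photon-budget slack.  Equalities: both cells' metabolite balances plus
    the photon-sharing and biomass-coupling rows.
    """
    n_vars = len(tc.model.reactions) + sum(1 for c in tc.constraints if c.slack)
    n_rows = len(tc.model.metabolites) + len(tc.constraints)
    return n_vars, n_rows


def without_shuttles(tc: TwoCellModel) -> TwoCellModel:
    """Close the intercellular shuttles (used to show growth collapses)."""
    new = tc.copy()
    for mid in tc.shuttle.shuttle_metabolites:
        new.set_bounds(f"SHUTTLE_{mid}", 0.0, 0.0)
    return new


# ---------------------------------------------------------------------------
# single-cell mixotrophic evaluation
# ---------------------------------------------------------------------------


def relative_growth(
    model: MetabolicModel,
    carbon_source: str,
    reference: str = "EX_hco3_e",
    uptake_rate: float = 1.0,
) -> float:
    """Mixotrophic growth on (photon + HCO3 + carbon source), divided by
    autotrophic growth on bicarbonate alone."""
    for rid in (carbon_source, reference):
        if rid not in set(model.reaction_ids):
            raise ModelError(f"exchange {rid!r} not in model")
    if carbon_source == reference:
        # "mixotrophy" on the reference itself: extra availability on top
        base_lo = model.reaction(reference).lower_bound
        auto_ov, mixo_lo = None, base_lo - abs(uptake_rate)
    else:
        auto_ov, mixo_lo = {carbon_source: (0.0, 1000.0)}, -abs(uptake_rate)
    auto = fba(model, overrides=auto_ov)
    if not auto.optimal or auto.objective_value <= 0:
        raise ModelError("autotrophic growth on the reference source is zero")
    mixo = fba(model, overrides={carbon_source: (mixo_lo, 1000.0)})
    if not mixo.optimal:
        raise ModelError(f"mixotrophic problem is {mixo.status}")
    return mixo.objective_value / auto.objective_value


def pearson_relative_growth(
    model: MetabolicModel,
    observed: Mapping[str, float],
    uptake_rate: float = 1.0,
    reference: str = "EX_hco3_e",
) -> tuple[float, float]:
    """Pearson r (and p-value) between predicted and observed relative
    mixotrophic growth rates over a table of carbon-source exchanges."""
    sources = list(observed)
    predicted = [
        relative_growth(model, s, reference=reference, uptake_rate=uptake_rate)
        for s in sources
    ]
    r, p = stats.pearsonr(predicted, [observed[s] for s in sources])
    return float(r), float(p)
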