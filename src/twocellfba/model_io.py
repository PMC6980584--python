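"""Stoichiometric model I/O, bound policies, and biomass assembly.

This module holds the in-memory representation of a constraint-based
metabolic model (metabolites, reactions with bounds and gene-protein-reaction
rules, and the implied stoichiometric matrix) together with

* a strict tabular (TSV) dialect with an explicit reaction-equation grammar
  ``"coef met[comp] + ... -> ..."`` (``<->`` marks reversibility),
* SBML Level 3 / FBC read-write via cobrapy,
* the standard cyanobacterial bound policy (+-1000 mmol/gDCW/h for
  intracellular reactions, export-only exchanges except a free set of
  inorganic species and a rate-limited set for bicarbonate, nitrate and
  photons), and
* a parameterized biomass-objective builder that turns macromolecular
  weight fractions and monomer tables into a drain reaction in mmol/gDCW.

All fluxes and bounds are in mmol/gDCW/h; biomass coefficients in mmol/gDCW.
"""

from __future__ import annotations

import json
import logging
import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse

logger = logging.getLogger("twocellfba")

#: numerical tolerances used package-wide (LP-standard values)
FEASIBILITY_TOL = 1e-9
OPTIMALITY_TOL = 1e-8
COMPARISON_TOL = 1e-6

#: compartment code -> canonical name (the four compartments of the organism)
COMPARTMENTS = {
    "c": "cytoplasm",
    "t": "thylakoid",
    "p": "periplasm",
    "e": "extracellular",
}
COMPARTMENT_CODES = {v: k for k, v in COMPARTMENTS.items()}


class ModelError(ValueError):
    """Raised for malformed or inconsistent model content."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str
    compartment: str  # one of COMPARTMENTS.values()
    formula: str | None = None  # elemental composition, e.g. "C6O9P"
    charge: int | None = None

    def elements(self) -> dict[str, float]:
        return parse_formula(self.formula) if self.formula else {}


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float]  # metabolite id -> signed coefficient
    lower_bound: float
    upper_bound: float
    gpr: str = ""  # boolean AND/OR expression over gene ids
    reversible: bool = False
    subsystem: str = ""

    @property
    def is_exchange(self) -> bool:
        return len(self.stoichiometry) == 1

    def genes(self) -> set[str]:
        return gpr_genes(parse_gpr(self.gpr)) if self.gpr else set()

    def with_bounds(self, lo: float, hi: float) -> "Reaction":
        return replace(self, lower_bound=lo, upper_bound=hi)


@dataclass
class MetabolicModel:
    """A stoichiometric model; steady state S.v = b with bounds on v."""

    metabolites: list[Metabolite]
    reactions: list[Reaction]
    objective_id: str | None = None
    id: str = "model"

    def __post_init__(self) -> None:
        self.validate()

    # -- bookkeeping --------------------------------------------------------

    @property
    def genes(self) -> list[str]:
        out: set[str] = set()
        for r in self.reactions:
            out |= r.genes()
        return sorted(out)

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def metabolite(self, mid: str) -> Metabolite:
        try:
            return next(m for m in self.metabolites if m.id == mid)
        except StopIteration:
            raise KeyError(f"unknown metabolite {mid!r}") from None

    def reaction(self, rid: str) -> Reaction:
        try:
            return next(r for r in self.reactions if r.id == rid)
        except StopIteration:
            raise KeyError(f"unknown reaction {rid!r}") from None

    def stoichiometric_matrix(self) -> sparse.csr_matrix:
        """S as an m x n sparse matrix (metabolite rows, reaction columns)."""
        midx = {m: i for i, m in enumerate(self.metabolite_ids)}
        rows, cols, vals = [], [], []
        for j, rxn in enumerate(self.reactions):
            for mid, coef in rxn.stoichiometry.items():
                rows.append(midx[mid])
                cols.append(j)
                vals.append(coef)
        return sparse.csr_matrix(
            (vals, (rows, cols)), shape=(len(self.metabolites), len(self.reactions))
        )

    @property
    def b(self) -> np.ndarray:
        """Right-hand side of the steady-state balance (all zero)."""
        return np.zeros(len(self.metabolites))

    def validate(self) -> None:
        mids = self.metabolite_ids
        if len(set(mids)) != len(mids):
            dup = sorted({m for m in mids if mids.count(m) > 1})
            raise ModelError(f"duplicate metabolite ids: {dup}")
        rids = self.reaction_ids
        if len(set(rids)) != len(rids):
            dup = sorted({r for r in rids if rids.count(r) > 1})
            raise ModelError(f"duplicate reaction ids: {dup}")
        known = set(mids)
        for m in self.metabolites:
            if m.compartment not in COMPARTMENT_CODES:
                raise ModelError(
                    f"metabolite {m.id!r}: unknown compartment {m.compartment!r}"
                )
        for r in self.reactions:
            if r.lower_bound > r.upper_bound:
                raise ModelError(f"reaction {r.id!r}: lower bound above upper bound")
            missing = set(r.stoichiometry) - known
            if missing:
                raise ModelError(
                    f"reaction {r.id!r} references unknown metabolites {sorted(missing)}"
                )
            if not r.stoichiometry:
                raise ModelError(f"reaction {r.id!r} has empty stoichiometry")
            if r.gpr:
                parse_gpr(r.gpr)  # raises on malformed rules
        if self.objective_id is not None and self.objective_id not in set(rids):
            raise ModelError(f"objective reaction {self.objective_id!r} not in model")

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            metabolites=list(self.metabolites),
            reactions=[replace(r, stoichiometry=dict(r.stoichiometry)) for r in self.reactions],
            objective_id=self.objective_id,
            id=self.id,
        )


@dataclass
class BoundPolicy:
    """The default flux-bound policy for a photoautotroph.

    Intracellular reversible reactions get (-1000, 1000) and irreversible
    ones (0, 1000).  Exchanges default to export-only (0, 1000) except a
    free set of inorganic species (lower bound -1000) and a rate-limited
    set (bicarbonate, nitrate, photon; lower bound -10, overridable per
    condition).  All values in mmol/gDCW/h.
    """

    intracellular_reversible: tuple[float, float] = (-1000.0, 1000.0)
    intracellular_irreversible: tuple[float, float] = (0.0, 1000.0)
    exchange_default: tuple[float, float] = (0.0, 1000.0)
    free_exchange_ids: frozenset[str] = frozenset(
        {"EX_h_e", "EX_h2o_e", "EX_k_e", "EX_so4_e", "EX_pi_e"}
    )
    limited_exchange: dict[str, float] = field(
        default_factory=lambda: {
            "EX_hco3_e": -10.0,
            "EX_no3_e": -10.0,
            "EX_photon_e": -10.0,
        }
    )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "intracellular_reversible": list(self.intracellular_reversible),
            "intracellular_irreversible": list(self.intracellular_irreversible),
            "exchange_default": list(self.exchange_default),
            "free_exchange_ids": sorted(self.free_exchange_ids),
            "limited_exchange": self.limited_exchange,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "BoundPolicy":
        d = json.loads(Path(path).read_text())
        return cls(
            intracellular_reversible=tuple(d["intracellular_reversible"]),
            intracellular_irreversible=tuple(d["intracellular_irreversible"]),
            exchange_default=tuple(d["exchange_default"]),
            free_exchange_ids=frozenset(d["free_exchange_ids"]),
            limited_exchange=dict(d["limited_exchange"]),
        )


@dataclass
class BiomassComposition:
    """Macromolecular biomass composition in dry-weight percent.

    ``monomer_table`` maps each macromolecule class to a list of
    ``(monomer metabolite id, mole fraction, molecular weight g/mmol)``.
    ``gam_atp`` is the growth-associated ATP maintenance (mmol ATP/gDCW)
    and ``ngam_atp`` the non-growth-associated demand (mmol ATP/gDCW/h).
    """

    weight_percent: dict[str, float]
    monomer_table: dict[str, list[tuple[str, float, float]]]
    gam_atp: float = 0.0
    ngam_atp: float = 0.0

    def validate(self) -> None:
        for k, v in self.weight_percent.items():
            if v < 0:
                raise ModelError(f"negative weight percent for {k!r}")
        total = sum(self.weight_percent.values())
        if abs(total - 100.0) > 0.5:
            raise ModelError(f"weight percents sum to {total}, expected ~100")
        for macro, rows in self.monomer_table.items():
            if macro not in self.weight_percent:
                raise ModelError(f"monomer table entry {macro!r} has no weight percent")
            frac = sum(f for _, f, _ in rows)
            if abs(frac - 1.0) > 1e-6:
                raise ModelError(f"mole fractions for {macro!r} sum to {frac}, not 1")
            for mid, _, mw in rows:
                if mw <= 0:
                    raise ModelError(f"monomer {mid!r} has non-positive molecular weight")


# ---------------------------------------------------------------------------
# GPR parsing (boolean AND/OR trees over gene ids)
# ---------------------------------------------------------------------------

GprNode = object  # str leaf | ("and"| "or", list[GprNode])

_GPR_TOKEN = re.compile(r"\(|\)|\band\b|\bor\b|[^\s()]+", re.IGNORECASE)


def parse_gpr(rule: str) -> GprNode | None:
    """Parse a GPR string into a nested ("and"/"or", children) tree.

    Returns None for an empty rule; raises ModelError on malformed input.
    """
    tokens = _GPR_TOKEN.findall(rule)
    if not tokens:
        return None
    pos = 0

    def peek() -> str | None:
        return tokens[pos] if pos < len(tokens) else None

    def parse_or():
        nonlocal pos
        parts = [parse_and()]
        while peek() is not None and peek().lower() == "or":
            pos += 1
            parts.append(parse_and())
        return parts[0] if len(parts) == 1 else ("or", parts)

    def parse_and():
        nonlocal pos
        parts = [parse_atom()]
        while peek() is not None and peek().lower() == "and":
            pos += 1
            parts.append(parse_atom())
        return parts[0] if len(parts) == 1 else ("and", parts)

    def parse_atom():
        nonlocal pos
        tok = peek()
        if tok is None:
            raise ModelError(f"malformed GPR {rule!r}: unexpected end")
        if tok == "(":
            pos += 1
            node = parse_or()
            if peek() != ")":
                raise ModelError(f"malformed GPR {rule!r}: unbalanced parentheses")
            pos += 1
            return node
        if tok == ")" or tok.lower() in ("and", "or"):
            raise ModelError(f"malformed GPR {rule!r}: unexpected {tok!r}")
        pos += 1
        return tok

    node = parse_or()
    if pos != len(tokens):
        raise ModelError(f"malformed GPR {rule!r}: trailing tokens")
    return node


def gpr_genes(node: GprNode | None) -> set[str]:
    if node is None:
        return set()
    if isinstance(node, str):
        return {node}
    _, children = node
    out: set[str] = set()
    for c in children:
        out |= gpr_genes(c)
    return out


def gpr_to_string(node: GprNode | None) -> str:
    if node is None:
        return ""
    if isinstance(node, str):
        return node
    op, children = node
    parts = []
    for c in children:
        s = gpr_to_string(c)
        if not isinstance(c, str) and c[0] != op:
            s = f"({s})"
        parts.append(s)
    return f" {op} ".join(parts)


def prefix_gpr(rule: str, prefix: str) -> str:
    """Prefix every gene id in a GPR string (used for the two-cell copies)."""

    def walk(node):
        if node is None:
            return None
        if isinstance(node, str):
            return f"{prefix}{node}"
        op, children = node
        return (op, [walk(c) for c in children])

    return gpr_to_string(walk(parse_gpr(rule)))


# ---------------------------------------------------------------------------
# formulas and equations
# ---------------------------------------------------------------------------

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*\.?\d*)")


def parse_formula(formula: str) -> dict[str, float]:
    out: dict[str, float] = {}
    for elem, count in _FORMULA_RE.findall(formula):
        out[elem] = out.get(elem, 0.0) + (float(count) if count else 1.0)
    return out


_TERM_RE = re.compile(
    r"^(?:(\d+(?:\.\d+)?(?:[eE][+-]?\d+)?)\s+)?([A-Za-z0-9_]+)\[([a-z])\]$"
)


def parse_equation(equation: str, rxn_id: str = "?") -> tuple[dict[str, float], bool, dict[str, str]]:
    """Parse ``"2 h[c] + 0.5 o2[c] -> h2o[c]"`` into a stoichiometry map.

    Metabolite ids are formed as ``name_compartmentcode``.  Returns
    (stoichiometry, reversible, {metabolite id: compartment name}).
    """
    if "<->" in equation:
        lhs, rhs = equation.split("<->", 1)
        reversible = True
    elif "->" in equation:
        lhs, rhs = equation.split("->", 1)
        reversible = False
    else:
        raise ModelError(f"reaction {rxn_id!r}: equation has no '->' or '<->' arrow")

    stoich: dict[str, float] = {}
    comps: dict[str, str] = {}

    def add_side(side: str, sign: float) -> None:
        side = side.strip()
        if not side:
            return
        for term in side.split("+"):
            term = term.strip()
            if not term:
                raise ModelError(f"reaction {rxn_id!r}: empty term in equation")
            m = _TERM_RE.match(term)
            if not m:
                raise ModelError(
                    f"reaction {rxn_id!r}: cannot parse equation term {term!r}"
                )
            coef_s, name, comp = m.groups()
            if comp not in COMPARTMENTS:
                raise ModelError(
                    f"reaction {rxn_id!r}: unknown compartment suffix {comp!r}"
                )
            coef = float(coef_s) if coef_s else 1.0
            mid = f"{name}_{comp}"
            stoich[mid] = stoich.get(mid, 0.0) + sign * coef
            comps[mid] = COMPARTMENTS[comp]
        return

    add_side(lhs, -1.0)
    add_side(rhs, +1.0)
    stoich = {k: v for k, v in stoich.items() if v != 0.0}
    if not stoich:
        raise ModelError(f"reaction {rxn_id!r}: equation cancels to nothing")
    return stoich, reversible, comps


def format_equation(rxn: Reaction, model: MetabolicModel) -> str:
    """Inverse of parse_equation for the tabular writer."""

    def side(items: list[tuple[str, float]]) -> str:
        parts = []
        for mid, coef in items:
            met = model.metabolite(mid)
            tok = f"{met.name}[{COMPARTMENT_CODES[met.compartment]}]"
            coef = abs(coef)
            parts.append(tok if coef == 1.0 else f"{coef:.17g} {tok}")
        return " + ".join(parts)

    subs = sorted((m, c) for m, c in rxn.stoichiometry.items() if c < 0)
    prods = sorted((m, c) for m, c in rxn.stoichiometry.items() if c > 0)
    arrow = "<->" if rxn.reversible else "->"
    return f"{side(subs)} {arrow} {side(prods)}".strip()


# ---------------------------------------------------------------------------
# load / write
# ---------------------------------------------------------------------------

TABULAR_COLUMNS = ["reaction_id", "equation", "lower_bound", "upper_bound", "gpr", "subsystem"]


def load_model(path: str | Path, format: str = "tabular") -> MetabolicModel:
    """Read a model from the tabular TSV dialect or from SBML L3/FBC."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tabular":
        return _load_tabular(path)
    if format == "sbml":
        return _load_sbml(path)
    raise ValueError(f"unknown model format {format!r}")


def _load_tabular(path: Path) -> MetabolicModel:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in TABULAR_COLUMNS if c not in df.columns]
    if missing:
        raise ModelError(f"tabular model missing columns {missing}")
    objective_id = None
    reactions: list[Reaction] = []
    met_comp: dict[str, str] = {}
    seen: set[str] = set()
    for _, row in df.iterrows():
        rid = row["reaction_id"].strip()
        if rid.startswith("#"):
            continue
        if rid in seen:
            raise ModelError(f"duplicate reaction id {rid!r}")
        seen.add(rid)
        stoich, reversible, comps = parse_equation(row["equation"], rid)
        met_comp.update(comps)
        lo, hi = float(row["lower_bound"]), float(row["upper_bound"])
        subsystem = row["subsystem"].strip()
        if subsystem.endswith("!objective"):
            subsystem = subsystem[: -len("!objective")].strip()
            objective_id = rid
        reactions.append(
            Reaction(
                id=rid,
                stoichiometry=stoich,
                lower_bound=lo,
                upper_bound=hi,
                gpr=row["gpr"].strip(),
                reversible=reversible or lo < 0,
                subsystem=subsystem,
            )
        )
    metabolites = [
        Metabolite(id=mid, name=mid.rsplit("_", 1)[0], compartment=comp)
        for mid, comp in sorted(met_comp.items())
    ]
    return MetabolicModel(
        metabolites=metabolites, reactions=reactions, objective_id=objective_id,
        id=path.stem,
    )


def write_model(model: MetabolicModel, path: str | Path, format: str = "tabular") -> None:
    """Write a model; round-trips losslessly through load_model."""
    if not model.reactions:
        raise ModelError("refusing to write an empty model")
    path = Path(path)
    if format == "tabular":
        rows = []
        for r in model.reactions:
            subsystem = r.subsystem
            if model.objective_id == r.id:
                subsystem = f"{subsystem}!objective" if subsystem else "!objective"
            rows.append(
                {
                    "reaction_id": r.id,
                    "equation": format_equation(r, model),
                    "lower_bound": r.lower_bound,
                    "upper_bound": r.upper_bound,
                    "gpr": r.gpr,
                    "subsystem": subsystem,
                }
            )
        pd.DataFrame(rows, columns=TABULAR_COLUMNS).to_csv(path, sep="\t", index=False)
    elif format == "sbml":
        import cobra.io

        cobra.io.write_sbml_model(to_cobra(model), str(path))
    else:
        raise ValueError(f"unknown model format {format!r}")


# -- cobra / SBML bridge ----------------------------------------------------


def to_cobra(model: MetabolicModel):
    """Convert to a cobrapy model (used for SBML I/O and as an LP cross-check)."""
    import cobra

    cm = cobra.Model(model.id)
    mets = {}
    for m in model.metabolites:
        met = cobra.Metabolite(
            m.id,
            name=m.name,
            compartment=COMPARTMENT_CODES[m.compartment],
            formula=m.formula or None,
            charge=m.charge,
        )
        mets[m.id] = met
    cm.add_metabolites(list(mets.values()))
    rxns = []
    for r in model.reactions:
        rx = cobra.Reaction(r.id, lower_bound=r.lower_bound, upper_bound=r.upper_bound)
        rx.subsystem = r.subsystem
        rxns.append(rx)
    cm.add_reactions(rxns)
    for r in model.reactions:
        rx = cm.reactions.get_by_id(r.id)
        rx.add_metabolites({mets[mid]: coef for mid, coef in r.stoichiometry.items()})
        if r.gpr:
            rx.gene_reaction_rule = r.gpr
    if model.objective_id:
        cm.objective = model.objective_id
    # subsystems persist through SBML only as group objects
    by_subsystem: dict[str, list] = {}
    for r in model.reactions:
        if r.subsystem:
            by_subsystem.setdefault(r.subsystem, []).append(cm.reactions.get_by_id(r.id))
    cm.add_groups(
        [
            cobra.core.Group(id=name.replace(" ", "_"), name=name, members=members)
            for name, members in by_subsystem.items()
        ]
    )
    return cm


def from_cobra(cm) -> MetabolicModel:
    subsystem_of: dict[str, str] = {}
    for group in getattr(cm, "groups", []):
        for member in group.members:
            subsystem_of.setdefault(member.id, group.name or group.id)
    metabolites = [
        Metabolite(
            id=m.id,
            name=m.name or m.id,
            compartment=COMPARTMENTS.get(m.compartment, m.compartment),
            formula=m.formula or None,
            charge=m.charge,
        )
        for m in cm.metabolites
    ]
    reactions = []
    for rx in cm.reactions:
        reactions.append(
            Reaction(
                id=rx.id,
                stoichiometry={m.id: coef for m, coef in rx.metabolites.items()},
                lower_bound=rx.lower_bound,
                upper_bound=rx.upper_bound,
                gpr=rx.gene_reaction_rule or "",
                reversible=rx.lower_bound < 0,
                subsystem=rx.subsystem or subsystem_of.get(rx.id, ""),
            )
        )
    # objective: the reaction carrying a nonzero linear coefficient
    from cobra.util.solver import linear_reaction_coefficients

    objective_id = None
    lin = linear_reaction_coefficients(cm)
    if lin:
        objective_id = next(iter(lin)).id
    return MetabolicModel(
        metabolites=metabolites, reactions=reactions, objective_id=objective_id, id=cm.id
    )


def _load_sbml(path: Path) -> MetabolicModel:
    import cobra.io

    return from_cobra(cobra.io.read_sbml_model(str(path)))


# ---------------------------------------------------------------------------
# bound policy application
# ---------------------------------------------------------------------------


def apply_bound_policy(model: MetabolicModel, policy: BoundPolicy) -> MetabolicModel:
    """Return a copy of the model with the policy bounds applied (idempotent)."""
    clash = policy.free_exchange_ids & set(policy.limited_exchange)
    if clash:
        raise ModelError(f"exchange ids in both free and limited sets: {sorted(clash)}")
    new = model.copy()
    for r in new.reactions:
        if r.is_exchange:
            lo, hi = policy.exchange_default
            if r.id in policy.free_exchange_ids:
                lo = -1000.0
            elif r.id in policy.limited_exchange:
                lo = policy.limited_exchange[r.id]
            r.lower_bound, r.upper_bound = lo, hi
            r.reversible = lo < 0
        elif r.reversible:
            r.lower_bound, r.upper_bound = policy.intracellular_reversible
        else:
            r.lower_bound, r.upper_bound = policy.intracellular_irreversible
    return new


# ---------------------------------------------------------------------------
# biomass objective builder
# ---------------------------------------------------------------------------


def build_biomass_reaction(
    comp: BiomassComposition,
    rxn_id: str = "BIOMASS",
    atp_id: str = "atp_c",
    h2o_id: str = "h2o_c",
    adp_id: str = "adp_c",
    pi_id: str = "pi_c",
    h_id: str = "h_c",
) -> Reaction:
    """Assemble the biomass drain from macromolecular weight fractions.

    The coefficient (mmol/gDCW) for monomer k of macromolecule M is

        (weight_percent_M / 100) * molefrac_k / sum_k(molefrac_k * MW_k)

    so the dry weight of consumed monomers totals (100 - ash%)/100 g per
    gram of biomass.  Growth-associated maintenance is added as
    ``gam_atp ATP + gam_atp H2O -> gam_atp (ADP + Pi + H)``.
    """
    comp.validate()
    coeffs: dict[str, float] = {}
    for macro, rows in comp.monomer_table.items():
        wt = comp.weight_percent.get(macro, 0.0)
        if wt == 0.0:
            continue
        mean_mw = sum(f * mw for _, f, mw in rows)
        for mid, frac, _ in rows:
            coeffs[mid] = coeffs.get(mid, 0.0) - (wt / 100.0) * frac / mean_mw
    if comp.gam_atp > 0:
        for mid, sign in ((atp_id, -1), (h2o_id, -1), (adp_id, +1), (pi_id, +1), (h_id, +1)):
            coeffs[mid] = coeffs.get(mid, 0.0) + sign * comp.gam_atp
    coeffs = {k: v for k, v in coeffs.items() if v != 0.0}
    return Reaction(
        id=rxn_id,
        stoichiometry=coeffs,
        lower_bound=0.0,
        upper_bound=1000.0,
        subsystem="Biomass",
    )


def biomass_monomer_mass(comp: BiomassComposition) -> float:
    """g of monomers drained per gDCW (should equal (100 - ash%)/100)."""
    total = 0.0
    for macro, rows in comp.monomer_table.items():
        wt = comp.weight_percent.get(macro, 0.0)
        mean_mw = sum(f * mw for _, f, mw in rows)
        for _, frac, mw in rows:
            total += (wt / 100.0) * frac / mean_mw * mw
    return total


# ---------------------------------------------------------------------------
# mass balance checking (warning-level, per dialect variability)
# ---------------------------------------------------------------------------


def check_mass_balance(
    model: MetabolicModel, elements: Sequence[str] = ("C", "N", "O", "P")
) -> dict[str, dict[str, float]]:
    """Per-reaction elemental imbalances for the given elements.

    Exchange reactions and the biomass drain (subsystem "Biomass") are
    exempt.  Imbalances are reported, and logged as warnings, not raised.
    """
    issues: dict[str, dict[str, float]] = {}
    for r in model.reactions:
        if r.is_exchange or r.subsystem == "Biomass":
            continue
        delta: dict[str, float] = {e: 0.0 for e in elements}
        for mid, coef in r.stoichiometry.items():
            for e, n in model.metabolite(mid).elements().items():
                if e in delta:
                    delta[e] += coef * n
        bad = {e: v for e, v in delta.items() if abs(v) > 1e-9}
        if bad:
            issues[r.id] = bad
            logger.warning("reaction %s is elementally unbalanced: %s", r.id, bad)
    return issues


# ---------------------------------------------------------------------------
# expression tables
# ---------------------------------------------------------------------------


@dataclass
class ExpressionDataset:
    """Per-gene expression levels for the two cell types (arbitrary units)."""

    genes: list[str]
    E_veg: dict[str, float]
    E_het: dict[str, float]

    def validate(self) -> None:
        for g in self.genes:
            for table in (self.E_veg, self.E_het):
                if g not in table:
                    raise ModelError(f"gene {g!r} missing from expression table")
                if table[g] < 0:
                    raise ModelError(f"gene {g!r} has negative expression")

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "gene_id": self.genes,
                "E_veg": [self.E_veg[g] for g in self.genes],
                "E_het": [self.E_het[g] for g in self.genes],
            }
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ExpressionDataset":
        df = pd.read_csv(path, sep="\t")
        ds = cls(
            genes=list(df["gene_id"]),
            E_veg=dict(zip(df["gene_id"], df["E_veg"].astype(float))),
            E_het=dict(zip(df["gene_id"], df["E_het"].astype(float))),
        )
        ds.validate()
        return ds
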