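"""Deterministic toy cyanobacterial network and two-cell expression profiles.

The toy model is a lumped, elementally balanced (C/N/O/P) caricature of a
filamentous diazotrophic cyanobacterium: photosystem II and I with a
plastoquinone and ferredoxin pool, cyclic photophosphorylation, a Calvin
cycle lump behind RuBisCO, bicarbonate dehydration, a glycolysis stub with
a formate branch, the oxidative pentose phosphate pathway, sucrose
synthesis and alkaline-invertase cleavage, GS/Fd-GOGAT nitrogen assimilation,
nitrogenase (16 ATP + 8 reduced ferredoxin per N2, one obligatory H2),
uptake (Hup) and bidirectional (Hox) hydrogenases, respiration, and a
four-monomer biomass assembled by the biomass builder.

Every enzymatic reaction carries a unique toy gene; PSII carries an AND
rule and respiration an OR rule so the gene-expansion machinery is
exercised.  Generation is purely deterministic — no randomness anywhere.

The network supports, by construction: photoautotrophic growth on
HCO3+NO3 as a single cell, heterotrophic growth on fructose, and
diazotrophic growth only when the two-cell coupling shuttles sucrose,
glutamate and glutamine between the cell types.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model_io import (
    BiomassComposition,
    BoundPolicy,
    Metabolite,
    MetabolicModel,
    ModelError,
    Reaction,
    apply_bound_policy,
    build_biomass_reaction,
    parse_equation,
)

#: default expression level (microarray-like arbitrary units)
DEFAULT_EXPRESSION = 500.0
#: mean expression of the planted PSII bottleneck gene
BOTTLENECK_EXPRESSION = 56.0

BIOMASS_ID = "BIOMASS"
NGAM_ID = "ATPM"

#: genes silenced in the heterocyst profile (PSII, RuBisCO/Calvin, carbonic
#: anhydrase, Fd-GOGAT support) and genes highly expressed there
HETEROCYST_OFF_GENES = ("psbJ_toy", "psbO_toy", "rbc_toy", "hco3e_toy", "gltS_toy")
HETEROCYST_HIGH_GENES = ("nif_toy", "hox_toy", "hup_toy")

#: reactions absent from each differentiated cell type (used as the default
#: removal lists when composing the two-cell model)
HETEROCYST_REMOVED = ("PSII", "CBB", "HCO3E", "GOGAT")
VEGETATIVE_REMOVED = ("NIT",)

# (name_comp, formula) — formulas track C/N/O/P only; H, charge and the
# electron bookkeeping of the redox carrier pairs are deliberately untracked
_METABOLITES = [
    ("photon_e", ""),
    ("hco3_e", "CO3"),
    ("no3_e", "NO3"),
    ("n2_e", "N2"),
    ("fru_e", "C6O6"),
    ("glc_e", "C6O6"),
    ("h2o_c", "O"),
    ("o2_c", "O2"),
    ("co2_c", "CO2"),
    ("h2_c", ""),
    ("for_c", "CO2"),
    ("pi_c", "O4P"),
    ("h_c", ""),
    ("atp_c", "O13P3"),
    ("adp_c", "O10P2"),
    ("nadph_c", ""),
    ("nadp_c", ""),
    ("fdred_c", ""),
    ("fdox_c", ""),
    ("q_c", ""),
    ("qh2_c", ""),
    ("g3p_c", "C3O6P"),
    ("f6p_c", "C6O9P"),
    ("g6p_c", "C6O9P"),
    ("ru5p_c", "C5O8P"),
    ("pg3_c", "C3O7P"),
    ("pyr_c", "C3O3"),
    ("akg_c", "C5O5"),
    ("glu_c", "C5NO4"),
    ("gln_c", "C5N2O3"),
    ("nh4_c", "N"),
    ("suc_c", "C12O11"),
    ("fru_c", "C6O6"),
    ("glc_c", "C6O6"),
    ("glyc_c", "C6O5"),
    ("lip_c", "C6O2"),
    ("nuc_c", "C5NO6P"),
    ("suc_p", "C12O11"),
    ("glu_p", "C5NO4"),
    ("gln_p", "C5N2O3"),
]

# (id, equation, gpr, subsystem)
_REACTIONS = [
    # exchanges (bounds set by the bound policy)
    ("EX_photon_e", "photon[e] <->", "", "Exchange"),
    ("EX_hco3_e", "hco3[e] <->", "", "Exchange"),
    ("EX_no3_e", "no3[e] <->", "", "Exchange"),
    ("EX_n2_e", "n2[e] <->", "", "Exchange"),
    ("EX_fru_e", "fru[e] <->", "", "Exchange"),
    ("EX_glc_e", "glc[e] <->", "", "Exchange"),
    ("EX_h2_c", "h2[c] <->", "", "Exchange"),
    ("EX_o2_c", "o2[c] <->", "", "Exchange"),
    ("EX_co2_c", "co2[c] <->", "", "Exchange"),
    ("EX_for_c", "for[c] <->", "", "Exchange"),
    ("EX_h2o_c", "h2o[c] <->", "", "Exchange"),
    ("EX_pi_c", "pi[c] <->", "", "Exchange"),
    ("EX_h_c", "h[c] <->", "", "Exchange"),
    # photosynthetic electron transport and energy
    ("PSII", "2 photon[e] + h2o[c] + q[c] -> 0.5 o2[c] + qh2[c]",
     "psbJ_toy and psbO_toy", "Photosynthesis"),
    ("PSI", "2 photon[e] + qh2[c] + 2 fdox[c] -> q[c] + 2 fdred[c]",
     "psaA_toy", "Photosynthesis"),
    ("FNR", "2 fdred[c] + nadp[c] -> 2 fdox[c] + nadph[c]", "petH_toy", "Photosynthesis"),
    # ATP-driven ferredoxin reduction from NADP(H): the uphill direction is
    # energized, so H2 recycling via Hup (straight to Fd) is strictly cheaper
    # than via the bidirectional hydrogenase
    ("FDXR", "nadph[c] + 0.2 atp[c] + 0.2 h2o[c] + 2 fdox[c] -> 2 fdred[c] + nadp[c] + 0.2 adp[c] + 0.2 pi[c]",
     "fdxr_toy", "Photosynthesis"),
    ("NDH", "nadph[c] + q[c] -> nadp[c] + qh2[c]", "ndh_toy", "Respiration"),
    ("CEF", "2 photon[e] + adp[c] + pi[c] -> atp[c] + h2o[c]", "cef_toy", "Photosynthesis"),
    ("RESP", "0.5 o2[c] + nadph[c] + 2 adp[c] + 2 pi[c] -> 3 h2o[c] + 2 atp[c] + nadp[c]",
     "cox_toy or cyd_toy", "Respiration"),
    # carbon fixation and central carbon metabolism
    ("HCO3E", "hco3[e] + h[c] -> co2[c] + h2o[c]", "hco3e_toy", "Carbon fixation"),
    ("CBB", "3 co2[c] + 9 atp[c] + 6 nadph[c] + 5 h2o[c] -> g3p[c] + 9 adp[c] + 8 pi[c] + 6 nadp[c]",
     "rbc_toy", "Carbon fixation"),
    ("FBA2", "2 g3p[c] + h2o[c] <-> f6p[c] + pi[c]", "fbp_toy", "Glycolysis"),
    ("PGI", "f6p[c] <-> g6p[c]", "pgi_toy", "Glycolysis"),
    ("GAPD", "g3p[c] + pi[c] + adp[c] + nadp[c] -> pg3[c] + atp[c] + nadph[c]",
     "gap_toy", "Glycolysis"),
    ("PYK", "pg3[c] + adp[c] -> pyr[c] + atp[c] + h2o[c]", "pyk_toy", "Glycolysis"),
    ("PFL", "pyr[c] + 3 h2o[c] + 3 nadp[c] -> for[c] + 2 co2[c] + 3 nadph[c]",
     "pfl_toy", "Fermentation"),
    ("G6PDH2", "g6p[c] + h2o[c] + 2 nadp[c] -> ru5p[c] + co2[c] + 2 nadph[c]",
     "g6pdh_toy", "Pentose phosphate"),
    ("TKT", "3 ru5p[c] <-> 2 f6p[c] + g3p[c]", "tkt_toy", "Pentose phosphate"),
    ("AKGS", "2 pyr[c] + h2o[c] + nadp[c] -> akg[c] + co2[c] + nadph[c]", "icd_toy", "TCA"),
    # sucrose metabolism and sugar uptake
    ("SPS", "f6p[c] + g6p[c] + atp[c] + 2 h2o[c] -> suc[c] + adp[c] + 3 pi[c]",
     "sps_toy", "Sucrose metabolism"),
    ("SUCt", "suc[c] <-> suc[p]", "suct_toy", "Transport"),
    ("INV", "suc[c] + h2o[c] -> glc[c] + fru[c]", "inv_toy", "Sucrose metabolism"),
    ("HEX", "glc[c] + atp[c] -> g6p[c] + adp[c]", "hex_toy", "Glycolysis"),
    ("FRK", "fru[c] + atp[c] -> f6p[c] + adp[c]", "frk_toy", "Glycolysis"),
    ("FRUt", "fru[e] -> fru[c]", "frut_toy", "Transport"),
    ("GLCt", "glc[e] -> glc[c]", "glct_toy", "Transport"),
    # nitrogen metabolism
    ("NIR", "no3[e] + 4 nadph[c] -> nh4[c] + 3 h2o[c] + 4 nadp[c]", "nir_toy", "Nitrogen"),
    ("NIT", "n2[e] + 16 atp[c] + 8 fdred[c] + 16 h2o[c] -> "
            "2 nh4[c] + h2[c] + 16 adp[c] + 16 pi[c] + 8 fdox[c]", "nif_toy", "Nitrogen"),
    ("GS", "glu[c] + nh4[c] + atp[c] -> gln[c] + adp[c] + pi[c]", "glnA_toy", "Nitrogen"),
    ("GOGAT", "gln[c] + akg[c] + 2 fdred[c] -> 2 glu[c] + 2 fdox[c]", "gltS_toy", "Nitrogen"),
    ("GLUt", "glu[c] <-> glu[p]", "glut_toy", "Transport"),
    ("GLNt", "gln[c] <-> gln[p]", "glnt_toy", "Transport"),
    # hydrogen metabolism
    ("HOX", "nadph[c] <-> h2[c] + nadp[c]", "hox_toy", "Hydrogen"),
    ("HUP", "h2[c] + 2 fdox[c] -> 2 fdred[c]", "hup_toy", "Hydrogen"),
    # biomass precursors and maintenance
    ("GLYCS", "g6p[c] + atp[c] + h2o[c] -> glyc[c] + adp[c] + 2 pi[c]", "glgA_toy", "Biomass precursors"),
    ("LIPS", "f6p[c] + 2 nadph[c] + atp[c] -> lip[c] + adp[c] + 2 pi[c] + 2 h2o[c] + 2 nadp[c]",
     "lip_toy", "Biomass precursors"),
    ("NUCS", "ru5p[c] + gln[c] + atp[c] -> nuc[c] + glu[c] + adp[c] + pi[c]",
     "nuc_toy", "Biomass precursors"),
    (NGAM_ID, "atp[c] + h2o[c] -> adp[c] + pi[c] + h[c]", "", "Maintenance"),
]

#: macromolecular dry-weight composition (percent); the organism's measured
#: values: 48.3 protein, 24.53 carbohydrate, 11.6 lipid, 9.1 RNA, 2.27 DNA,
#: 4.2 ash (sums to 100.0)
TOY_WEIGHT_PERCENT = {
    "protein": 48.3,
    "carbohydrate": 24.53,
    "lipid": 11.6,
    "RNA": 9.1,
    "DNA": 2.27,
    "ash": 4.2,
}

#: pseudo-monomer pools: (metabolite id, mole fraction, MW g/mmol)
TOY_MONOMER_TABLE = {
    "protein": [("glu_c", 1.0, 0.147)],
    "carbohydrate": [("glyc_c", 1.0, 0.162)],
    "lipid": [("lip_c", 1.0, 0.250)],
    "RNA": [("nuc_c", 1.0, 0.330)],
    "DNA": [("nuc_c", 1.0, 0.330)],
}

#: growth-associated ATP maintenance (mmol/gDCW); order of the unicellular-
#: cyanobacterium model values the organism literature borrows.  The
#: non-growth maintenance floor is zero so that a cell with no energy source
#: is a feasible zero-growth state rather than an infeasible LP.
TOY_GAM_ATP = 30.0
TOY_NGAM_ATP = 0.0

TOY_FREE_EXCHANGES = frozenset({"EX_h_c", "EX_h2o_c", "EX_pi_c", "EX_o2_c"})
TOY_LIMITED_EXCHANGES = {"EX_hco3_e": -10.0, "EX_no3_e": -10.0, "EX_photon_e": -10.0}


def toy_biomass_composition() -> BiomassComposition:
    return BiomassComposition(
        weight_percent=dict(TOY_WEIGHT_PERCENT),
        monomer_table={k: list(v) for k, v in TOY_MONOMER_TABLE.items()},
        gam_atp=TOY_GAM_ATP,
        ngam_atp=TOY_NGAM_ATP,
    )


def toy_bound_policy() -> BoundPolicy:
    return BoundPolicy(
        free_exchange_ids=TOY_FREE_EXCHANGES,
        limited_exchange=dict(TOY_LIMITED_EXCHANGES),
    )


def make_toy_model() -> MetabolicModel:
    """Build the deterministic toy model (bit-reproducible, no randomness)."""
    formulas = dict(_METABOLITES)
    mets: dict[str, Metabolite] = {}
    reactions: list[Reaction] = []
    for rid, equation, gpr, subsystem in _REACTIONS:
        stoich, reversible, comps = parse_equation(equation, rid)
        for mid, comp in comps.items():
            if mid not in mets:
                mets[mid] = Metabolite(
                    id=mid,
                    name=mid.rsplit("_", 1)[0],
                    compartment=comp,
                    formula=formulas[mid] or None,
                )
        reactions.append(
            Reaction(
                id=rid,
                stoichiometry=stoich,
                lower_bound=-1000.0 if reversible else 0.0,
                upper_bound=1000.0,
                gpr=gpr,
                reversible=reversible,
                subsystem=subsystem,
            )
        )
    comp = toy_biomass_composition()
    reactions.append(build_biomass_reaction(comp, rxn_id=BIOMASS_ID))
    model = MetabolicModel(
        metabolites=[mets[m] for m, _ in _METABOLITES],
        reactions=reactions,
        objective_id=BIOMASS_ID,
        id="toy_cyano",
    )
    model = apply_bound_policy(model, toy_bound_policy())
    # non-growth-associated maintenance floor survives the policy
    model.reaction(NGAM_ID).lower_bound = comp.ngam_atp
    return model


# ---------------------------------------------------------------------------
# expression profiles
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ToyScenario:
    """A named expression scenario for the two cell types."""

    name: str = "baseline"
    expression_default: float = DEFAULT_EXPRESSION
    bottleneck_gene: str | None = None
    bottleneck_level: float = BOTTLENECK_EXPRESSION

    def __post_init__(self) -> None:
        if self.name not in ("baseline", "psii_bottleneck", "hup_knockout", "heterotrophic"):
            raise ModelError(f"unknown scenario {self.name!r}")
        wants_bottleneck = self.name == "psii_bottleneck" or self.bottleneck_gene
        if wants_bottleneck and not self.bottleneck_level < self.expression_default:
            raise ModelError("bottleneck_level must be below expression_default")


def make_expression(model: MetabolicModel, scenario: ToyScenario) -> "ExpressionDataset":
    """Deterministic two-cell expression profiles for a scenario.

    * baseline — every gene at expression_default in both cell types.
    * psii_bottleneck — the PSII gene (default psbJ_toy) drops to
      bottleneck_level in the vegetative profile; the heterocyst profile is
      differentiated (PSII/RuBisCO/carbonic-anhydrase/GOGAT genes silenced,
      nitrogenase and hydrogenase genes doubled).
    * hup_knockout — the differentiated profile with Hup silenced in the
      heterocyst.
    * heterotrophic — the differentiated profile with no PSII bottleneck.
    """
    from .model_io import ExpressionDataset

    genes = model.genes
    default = scenario.expression_default
    bottleneck = scenario.bottleneck_gene or "psbJ_toy"
    if scenario.name == "psii_bottleneck" and bottleneck not in genes:
        raise ModelError(f"bottleneck gene {bottleneck!r} absent from model")

    E_veg = {g: default for g in genes}
    E_het = {g: default for g in genes}
    if scenario.name != "baseline":
        for g in HETEROCYST_OFF_GENES:
            if g in E_het:
                E_het[g] = 0.0
        for g in HETEROCYST_HIGH_GENES:
            if g in E_het:
                E_het[g] = 2.0 * default
    if scenario.name == "psii_bottleneck":
        E_veg[bottleneck] = scenario.bottleneck_level
    if scenario.name == "hup_knockout":
        E_het["hup_toy"] = 0.0
    ds = ExpressionDataset(genes=genes, E_veg=E_veg, E_het=E_het)
    ds.validate()
    return ds


# ---------------------------------------------------------------------------
# sized padding model for dimension arithmetic
# ---------------------------------------------------------------------------


def make_sized_model(
    n_reactions: int, n_metabolites: int, n_genes: int = 0
) -> MetabolicModel:
    """A structurally valid model with exact reaction/metabolite/gene counts.

    Used for the dimension arithmetic of the two-cell composition and the
    regulation layer (variable/equation counting), not for growth
    simulation.  The model always contains a photon exchange, a biomass
    drain and the three periplasmic shuttle metabolites; the remaining
    columns are gene-tagged dummy conversions over a dummy metabolite pool.
    """
    core_reactions = 6  # photon EX + uptake + biomass + 3 shuttle transporters
    core_metabolites = 5  # photon_e, bm_c, suc_p, glu_p, gln_p
    if n_reactions < core_reactions + n_genes:
        raise ModelError("n_reactions too small for the requested gene count")
    if n_metabolites < core_metabolites + 1:
        raise ModelError("n_metabolites too small")

    mets = [
        Metabolite("photon_e", "photon", "extracellular"),
        Metabolite("bm_c", "bm", "cytoplasm"),
        Metabolite("suc_p", "suc", "periplasm"),
        Metabolite("glu_p", "glu", "periplasm"),
        Metabolite("gln_p", "gln", "periplasm"),
    ]
    n_dummy_mets = n_metabolites - core_metabolites
    mets += [
        Metabolite(f"dm{i}_c", f"dm{i}", "cytoplasm") for i in range(n_dummy_mets)
    ]

    reactions = [
        Reaction("EX_photon_e", {"photon_e": -1.0}, -10.0, 1000.0, subsystem="Exchange"),
        Reaction("PHOT", {"photon_e": -1.0, "bm_c": 1.0}, 0.0, 1000.0, subsystem="Dummy"),
        Reaction("BIOMASS", {"bm_c": -1.0}, 0.0, 1000.0, subsystem="Biomass"),
        Reaction("SUCt", {"bm_c": -1.0, "suc_p": 1.0}, -1000.0, 1000.0, reversible=True),
        Reaction("GLUt", {"bm_c": -1.0, "glu_p": 1.0}, -1000.0, 1000.0, reversible=True),
        Reaction("GLNt", {"bm_c": -1.0, "gln_p": 1.0}, -1000.0, 1000.0, reversible=True),
    ]
    n_dummy_rxns = n_reactions - len(reactions)
    for i in range(n_dummy_rxns):
        a = f"dm{i % n_dummy_mets}_c" if n_dummy_mets else "bm_c"
        b = f"dm{(i + 1) % n_dummy_mets}_c" if n_dummy_mets else "bm_c"
        stoich = {a: -1.0, "bm_c": 1.0} if a == b else {a: -1.0, b: 1.0}
        gpr = f"pg{i % n_genes}_toy" if n_genes else ""
        reactions.append(
            Reaction(f"DUM{i}", stoich, 0.0, 1000.0, gpr=gpr, subsystem="Dummy")
        )
    model = MetabolicModel(
        metabolites=mets, reactions=reactions, objective_id="BIOMASS", id="sized"
    )
    assert len(model.reactions) == n_reactions
    assert len(model.metabolites) == n_metabolites
    if n_genes:
        assert len(model.genes) == n_genes
    return model
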