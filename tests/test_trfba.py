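"""Expression regulation: expansion, gene rows, C calibration, shadow prices."""

import numpy as np
import pytest

from twocellfba import (
    ExpressionDataset,
    MetabolicModel,
    Metabolite,
    ModelError,
    Reaction,
    ToyScenario,
    add_expression_constraints,
    fba,
    gene_shadow_prices,
    make_expression,
    make_sized_model,
    regulate_two_cell,
    regulated_fba,
    scan_C,
    to_irreversible_no_or,
)
from twocellfba.trfba import DEFAULT_C_GRID, gpr_dnf
from twocellfba.twocell import CellSpec, compose_two_cell


# ---------------------------------------------------------------------------
# GPR normal form and expansion semantics
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "rule, expected",
    [
        ("g1", [("g1",)]),
        ("g1 and g2", [("g1", "g2")]),
        ("g1 or g2", [("g1",), ("g2",)]),
        ("(g1 and g2) or g3", [("g1", "g2"), ("g3",)]),
        ("g1 and (g2 or g3)", [("g1", "g2"), ("g1", "g3")]),
        ("(g1 or g2) and (g3 or g4)",
         [("g1", "g3"), ("g1", "g4"), ("g2", "g3"), ("g2", "g4")]),
    ],
)
def test_gpr_disjunctive_normal_form(rule, expected):
    assert sorted(gpr_dnf(rule)) == sorted(expected)


def _one_reaction_model(gpr, lo=-1000.0, hi=1000.0):
    return MetabolicModel(
        metabolites=[Metabolite("a_c", "a", "cytoplasm"),
                     Metabolite("b_c", "b", "cytoplasm")],
        reactions=[
            Reaction("EX_a", {"a_c": -1.0}, -10.0, 1000.0, reversible=True),
            Reaction("R", {"a_c": -1.0, "b_c": 1.0}, lo, hi, gpr=gpr, reversible=lo < 0),
            Reaction("EX_b", {"b_c": -1.0}, 0.0, 1000.0),
        ],
        objective_id="EX_b",
    )


def test_reversible_split_semantics():
    """One reversible reaction with gene g1 becomes two non-negative columns,
    both supported by g1."""
    ex = to_irreversible_no_or(_one_reaction_model("g1"))
    cols = dict(ex.columns_of("R"))
    assert set(cols) == {"R", "R__rev"}
    assert cols["R"] == 1 and cols["R__rev"] == -1
    assert set(ex.K["g1"]) == {"R", "R__rev"}
    assert all(r.lower_bound >= 0 for r in ex.model.reactions)


def test_or_gpr_duplicates_isozyme_columns():
    ex = to_irreversible_no_or(_one_reaction_model("(g1 and g2) or g3", lo=0.0))
    iso = [eid for eid, _ in ex.columns_of("R")]
    assert sorted(iso) == ["R__iso1", "R__iso2"]
    assert set(ex.K["g1"]) == set(ex.K["g2"]) == {"R__iso1"}
    assert set(ex.K["g3"]) == {"R__iso2"}


def test_expansion_preserves_fba_optimum(toy, diazo, expanded_diazo):
    """Irreversible/no-OR form spans the same flux space: optima agree for
    both the single-cell and the coupled two-cell model."""
    single = to_irreversible_no_or(toy)
    assert fba(single, "BIOMASS").objective_value == pytest.approx(
        fba(toy).objective_value, abs=1e-6
    )
    assert fba(expanded_diazo, diazo.model.objective_id).objective_value == pytest.approx(
        fba(diazo).objective_value, abs=1e-6
    )


def test_expansion_random_objectives_agree(diazo, expanded_diazo):
    """Optimum equality extends to arbitrary (seeded) single-flux objectives,
    a projection check of the expansion's flux-space equivalence."""
    rng = np.random.default_rng(11)
    rids = [r for r in diazo.model.reaction_ids if not r.startswith("SHUTTLE")]
    for rid in rng.choice(rids, size=5, replace=False):
        a = fba(diazo, rid).objective_value
        b = fba(expanded_diazo, rid).objective_value
        assert a == pytest.approx(b, abs=1e-6), rid


def test_mapped_back_fluxes_are_original_space(regulated):
    sol = regulated_fba(regulated)
    assert sol.optimal
    src = regulated.source
    assert set(sol.fluxes) == set(src.model.reaction_ids)
    S = src.model.stoichiometric_matrix()
    v = np.array([sol.fluxes[r] for r in src.model.reaction_ids])
    assert np.max(np.abs(S @ v)) < 1e-6


# ---------------------------------------------------------------------------
# expression rows
# ---------------------------------------------------------------------------


def test_951_genes_add_1902_rows_and_slacks():
    """The regulation layer for 951 measured genes per cell type adds exactly
    1902 slack variables and 1902 equality rows."""
    base = make_sized_model(983, 921, 951)
    tc = compose_two_cell(
        base, veg=CellSpec(prefix="Vegetative"), het=CellSpec(prefix="Heterocyst")
    )
    ex = to_irreversible_no_or(tc)
    genes = base.genes
    expr = ExpressionDataset(
        genes=genes,
        E_veg={g: 500.0 for g in genes},
        E_het={g: 500.0 for g in genes},
    )
    rm = add_expression_constraints(ex, expr, C=0.05)
    assert rm.n_added_variables == 1902
    assert rm.n_added_equations == 1902


def test_zero_expression_forces_zero_flux(diazo, toy):
    expr = make_expression(toy, ToyScenario(name="baseline"))
    expr.E_veg["rbc_toy"] = 0.0  # silence RuBisCO in the vegetative cell
    rm = regulate_two_cell(diazo, expr, C=0.05)
    sol = regulated_fba(rm)
    assert sol.optimal
    assert abs(sol.fluxes["Vegetative_CBB"]) < 1e-9
    # no carbon fixation anywhere: the filament cannot grow
    assert sol.objective_value == pytest.approx(0.0, abs=1e-8)


def test_generous_expression_is_nonbinding(diazo, toy):
    expr = make_expression(toy, ToyScenario(name="baseline"))
    rm = regulate_two_cell(diazo, expr, C=1e6)
    assert regulated_fba(rm).objective_value == pytest.approx(
        fba(diazo).objective_value, abs=1e-6
    )


def test_unmapped_genes_are_skipped_with_warning(diazo, toy, caplog):
    import logging

    expr = make_expression(toy, ToyScenario(name="baseline"))
    logger = logging.getLogger("twocellfba")
    old = logger.level
    logger.setLevel(logging.WARNING)
    try:
        with caplog.at_level(logging.WARNING, logger="twocellfba"):
            regulate_two_cell(diazo, expr, C=0.05)
    finally:
        logger.setLevel(old)
    # nif_toy maps to no vegetative reaction (nitrogenase was removed there)
    assert any("skipped" in rec.message for rec in caplog.records)


def test_nonpositive_C_rejected(expanded_diazo, bottleneck_expr):
    with pytest.raises(ModelError):
        add_expression_constraints(expanded_diazo, bottleneck_expr, C=0.0)


# ---------------------------------------------------------------------------
# monotonicity in C and calibration
# ---------------------------------------------------------------------------


def test_regulated_optimum_monotone_in_C(expanded_diazo, bottleneck_expr, diazo):
    unregulated = fba(diazo).objective_value
    values = []
    for C in (0.002, 0.005, 0.01, 0.05, 1.0):
        rm = add_expression_constraints(expanded_diazo, bottleneck_expr, C)
        values.append(regulated_fba(rm).objective_value)
    assert all(a <= b + 1e-9 for a, b in zip(values, values[1:]))
    assert all(v <= unregulated + 1e-9 for v in values)


def test_bottleneck_halving_C_halves_growth(expanded_diazo, bottleneck_expr):
    """While the PSII row binds, growth scales linearly with the cap E * C."""
    g1 = regulated_fba(add_expression_constraints(expanded_diazo, bottleneck_expr, 0.01)).objective_value
    g2 = regulated_fba(add_expression_constraints(expanded_diazo, bottleneck_expr, 0.005)).objective_value
    assert g2 == pytest.approx(0.5 * g1, rel=1e-6)


def test_scan_C_recovers_planted_value(expanded_diazo, bottleneck_expr, diazo):
    """Planting an observed growth generated at a known C returns that C with
    zero error (2%-recovery property holds with equality on the grid)."""
    planted = DEFAULT_C_GRID[10]
    rm = add_expression_constraints(expanded_diazo, bottleneck_expr, planted)
    observed = 1.1 * regulated_fba(rm).objective_value
    best, curve = scan_C(
        expanded_diazo, bottleneck_expr, diazo.model.objective_id,
        observed_growth=observed,
    )
    assert best == pytest.approx(planted, rel=1e-12)
    errs = dict(curve)
    assert errs[best] == pytest.approx(0.0, abs=1e-9)


def test_scan_C_curve_total_and_prediction_monotone(expanded_diazo, bottleneck_expr, diazo):
    best, curve = scan_C(
        expanded_diazo, bottleneck_expr, diazo.model.objective_id,
        c_grid=np.logspace(-3, 0, 10), observed_growth=0.02,
    )
    assert len(curve) == 10
    assert all(np.isfinite(e) for _, e in curve)
    # predicted growth is non-decreasing along the grid (LP relaxation)
    growths = [
        regulated_fba(add_expression_constraints(expanded_diazo, bottleneck_expr, C)).objective_value
        for C, _ in curve
    ]
    assert all(a <= b + 1e-9 for a, b in zip(growths, growths[1:]))


def test_scan_C_rejects_bad_input(expanded_diazo, bottleneck_expr, diazo):
    with pytest.raises(ModelError):
        scan_C(expanded_diazo, bottleneck_expr, diazo.model.objective_id,
               observed_growth=0.0)
    with pytest.raises(ModelError):
        scan_C(expanded_diazo, bottleneck_expr, diazo.model.objective_id,
               c_grid=[], observed_growth=0.02)


# ---------------------------------------------------------------------------
# gene shadow prices
# ---------------------------------------------------------------------------


def test_planted_bottleneck_is_unique_positive_shadow_price(regulated):
    """Only the silenced PSII gene in the vegetative cell limits growth; all
    other gene rows carry zero dual (their expression is adequate)."""
    sol = regulated_fba(regulated)
    prices = gene_shadow_prices(regulated, sol)
    positive = {k for k, (dual, _) in prices.items() if dual > 1e-8}
    assert positive == {("Vegetative", "psbJ_toy")}
    dual, per_unit = prices[("Vegetative", "psbJ_toy")]
    assert per_unit == pytest.approx(dual * regulated.C, rel=1e-12)


def test_shadow_price_matches_finite_difference(diazo, toy):
    """dual = d(growth)/d(E_j * C) for the binding row, by rhs perturbation."""
    expr = make_expression(toy, ToyScenario(name="psii_bottleneck"))
    C = 0.01
    rm = regulate_two_cell(diazo, expr, C)
    sol = regulated_fba(rm)
    dual = gene_shadow_prices(rm, sol)[("Vegetative", "psbJ_toy")][0]
    eps = 1e-3
    expr2 = make_expression(toy, ToyScenario(name="psii_bottleneck"))
    expr2.E_veg["psbJ_toy"] += eps / C  # rhs E*C grows by eps
    sol2 = regulated_fba(regulate_two_cell(diazo, expr2, C))
    fd = (sol2.objective_value - sol.objective_value) / eps
    assert dual == pytest.approx(fd, abs=1e-5)


def test_complementary_slackness(regulated):
    sol = regulated_fba(regulated)
    prices = gene_shadow_prices(regulated, sol)
    for row in regulated.gene_rows:
        cell, gene = row.name.split("_", 1)
        dual = prices[(cell, gene)][0]
        slack = sol.slacks[row.slack]
        assert abs(dual * slack) < 1e-6


def test_unbinding_gene_has_zero_price(regulated):
    """The PSII partner gene shares the bottleneck reaction but is amply
    expressed: positive slack, zero shadow price."""
    sol = regulated_fba(regulated)
    assert sol.slacks["a_Vegetative_psbO_toy"] > 1e-6
    assert gene_shadow_prices(regulated, sol)[("Vegetative", "psbO_toy")][0] == 0.0


def test_missing_duals_rejected(regulated):
    from twocellfba.fba_core import FluxSolution

    with pytest.raises(ModelError):
        gene_shadow_prices(regulated, FluxSolution(status="optimal", objective_value=0.0))
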