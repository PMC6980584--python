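"""Hydrogen production: robustness surfaces, H2 ranges, knockouts, reports."""

import numpy as np
import pytest

from twocellfba import (
    H2Experiment,
    ModelError,
    differential_flux,
    fba,
    h2_o2_surface,
    h2_range_at_suboptimal_growth,
    hox_fraction,
    knockout_h2,
    l1_minimal_solution,
    metabolite_turnover,
)


@pytest.fixture(scope="module")
def h2_extremes(diazo_h2, het_exp):
    return h2_range_at_suboptimal_growth(diazo_h2, het_exp)


# ---------------------------------------------------------------------------
# H2 range at suboptimal growth
# ---------------------------------------------------------------------------


def test_h2_range_orders_and_growth_fixing(diazo_h2, het_exp, h2_extremes):
    h2_min, h2_max, sol_min, sol_max = h2_extremes
    assert 0.0 <= h2_min <= h2_max
    target = 0.9 * fba(diazo_h2).objective_value
    for sol in (sol_min, sol_max):
        assert sol.fluxes[diazo_h2.veg_biomass] == pytest.approx(target, abs=1e-9)


def test_no_h2_secretion_at_optimal_growth(diazo_h2):
    """At 100% of the optimum every electron is needed for growth: the H2
    secretion range collapses to zero (Hup recycles the nitrogenase H2)."""
    h2_min, h2_max, _, _ = h2_range_at_suboptimal_growth(
        diazo_h2, H2Experiment(growth_fraction=1.0)
    )
    assert h2_min == pytest.approx(0.0, abs=1e-8)
    assert h2_max == pytest.approx(0.0, abs=1e-8)


def test_h2_range_matches_fva_of_exchange(diazo_h2, het_exp, h2_extremes):
    from twocellfba import fva

    h2_min, h2_max, _, _ = h2_extremes
    lo, hi = fva(diazo_h2, [het_exp.h2_exchange_id], fraction_of_optimum=0.9)[
        het_exp.h2_exchange_id
    ]
    # FVA's floor is growth >= 90%; the experiment pins growth = 90%, and H2
    # trades off against growth, so the extremes coincide
    assert h2_min == pytest.approx(lo, abs=1e-6)
    assert h2_max == pytest.approx(hi, abs=1e-6)


def test_relaxing_growth_below_optimum_frees_h2(diazo_h2):
    at_90 = h2_range_at_suboptimal_growth(diazo_h2, H2Experiment(growth_fraction=0.9))[1]
    at_100 = h2_range_at_suboptimal_growth(diazo_h2, H2Experiment(growth_fraction=1.0))[1]
    assert at_100 <= at_90 + 1e-9


def test_hup_recycling_suppressed_at_max_h2(h2_extremes):
    """The uptake hydrogenase consumes nitrogenase H2 in the minimal state
    and is silent when secretion is maximized."""
    _, _, sol_min, sol_max = h2_extremes
    nit_min = sol_min.fluxes["Heterocyst_NIT"]
    assert sol_min.fluxes["Heterocyst_HUP"] == pytest.approx(nit_min, abs=1e-8)
    assert sol_max.fluxes["Heterocyst_HUP"] == pytest.approx(0.0, abs=1e-9)
    assert sol_min.fluxes["Heterocyst_HUP"] > sol_max.fluxes["Heterocyst_HUP"]


def test_nitrogenase_rate_unchanged_between_extremes(h2_extremes):
    """Nitrogen demand is set by the fixed growth rate, so nitrogenase runs
    identically in the minimal- and maximal-H2 states."""
    _, _, sol_min, sol_max = h2_extremes
    assert sol_min.fluxes["Heterocyst_NIT"] == pytest.approx(
        sol_max.fluxes["Heterocyst_NIT"], abs=1e-8
    )


# ---------------------------------------------------------------------------
# differential flux report and Hox fraction
# ---------------------------------------------------------------------------


def test_differential_flux_identity_is_all_unchanged(h2_extremes):
    _, _, sol_min, _ = h2_extremes
    report = differential_flux(sol_min, sol_min)
    assert report.up == [] and report.down == []
    assert report.unchanged == len(sol_min.fluxes)


def test_differential_flux_classification(diazo_h2, het_exp, h2_extremes):
    _, _, sol_min, sol_max = h2_extremes
    report = differential_flux(sol_min, sol_max, model_like=diazo_h2, experiment=het_exp)
    up_ids = {r for r, _, _ in report.up}
    down_ids = {r for r, _, _ in report.down}
    assert not up_ids & down_ids
    assert len(report.up) + len(report.down) + report.unchanged == len(sol_min.fluxes)
    # the paper's mechanism: Hox activates, Hup recycling is suppressed
    assert "Heterocyst_HOX" in up_ids
    assert "Heterocyst_HUP" in down_ids
    assert "Heterocyst_EX_h2_c" in up_ids
    # more sucrose is shuttled to fuel the heterocyst's reductant supply
    assert "SHUTTLE_suc_p" in up_ids


def test_differential_flux_planted_branch():
    """A two-branch network where only one branch can grow lands exactly
    that branch in the up list."""
    from twocellfba import MetabolicModel, Metabolite, Reaction

    model = MetabolicModel(
        metabolites=[Metabolite("a_c", "a", "cytoplasm"),
                     Metabolite("b_c", "b", "cytoplasm")],
        reactions=[
            Reaction("EX_A", {"a_c": -1.0}, -10.0, 0.0, reversible=True),
            Reaction("CAPPED", {"a_c": -1.0, "b_c": 1.0}, 0.0, 2.0),
            Reaction("OPEN", {"a_c": -1.0, "b_c": 1.0}, 0.0, 1000.0),
            Reaction("EX_B", {"b_c": -1.0}, 0.0, 1000.0),
        ],
    )
    lo = l1_minimal_solution(model, fixed={"EX_B": 2.0})
    hi = l1_minimal_solution(model, fixed={"EX_B": 8.0})
    report = differential_flux(lo, hi)
    up_ids = {r for r, _, _ in report.up}
    assert "OPEN" in up_ids  # only the uncapped branch can carry the extra flux
    assert "CAPPED" not in up_ids or hi.fluxes["CAPPED"] <= 2.0 + 1e-9


def test_differential_flux_mismatched_solutions_rejected(h2_extremes):
    from twocellfba.fba_core import FluxSolution

    _, _, sol_min, _ = h2_extremes
    other = FluxSolution(status="optimal", objective_value=0.0, fluxes={"X": 1.0})
    with pytest.raises(ModelError):
        differential_flux(sol_min, other)


def test_hox_fraction_bounds_and_majority(diazo_h2, het_exp, h2_extremes):
    """Most maximal-state hydrogen comes from the bidirectional hydrogenase
    (the nitrogenase contribution is pinned by growth); the fraction is a
    proper fraction of stoichiometric H2 production."""
    _, h2_max, _, sol_max = h2_extremes
    frac = hox_fraction(diazo_h2, sol_max, het_exp)
    assert 0.0 <= frac <= 1.0
    assert frac > 0.5
    # consistency: Hox + nitrogenase account for all H2 production
    hox = sol_max.fluxes["Heterocyst_HOX"]
    nit = sol_max.fluxes["Heterocyst_NIT"]
    assert frac == pytest.approx(max(hox, 0.0) / (max(hox, 0.0) + nit), rel=1e-9)


def test_hox_fraction_zero_when_hox_deleted(diazo_h2, het_exp):
    _, _, _, sol_max = h2_range_at_suboptimal_growth(
        diazo_h2, het_exp, overrides={"Heterocyst_HOX": (0.0, 0.0)}
    )
    assert hox_fraction(diazo_h2, sol_max, het_exp) == 0.0


# ---------------------------------------------------------------------------
# knockouts
# ---------------------------------------------------------------------------


def test_hup_knockout_does_not_reduce_h2_max(diazo_h2, het_exp):
    wt, ko = knockout_h2(diazo_h2, het_exp, ["Heterocyst_HUP"])
    assert ko >= wt - 1e-9


def test_hup_knockout_strictly_lowers_growth(diazo):
    """Hup's recycling of nitrogenase H2 into ferredoxin is strictly cheaper
    than the ATP-driven route under a binding photon budget."""
    g = fba(diazo).objective_value
    g_ko = fba(diazo, overrides={"Heterocyst_HUP": (0.0, 0.0)}).objective_value
    assert g_ko < g - 1e-9


def test_hox_knockout_reduces_h2_max(diazo_h2, het_exp):
    wt, ko = knockout_h2(diazo_h2, het_exp, ["Heterocyst_HOX"])
    assert ko <= wt + 1e-9
    assert ko < wt - 1e-6  # Hox is the major producer, the drop is real


def test_deleting_all_h2_enzymes_zeroes_h2(diazo_h2, het_exp):
    _, ko = knockout_h2(
        diazo_h2, het_exp,
        ["Heterocyst_HOX", "Heterocyst_HUP", "Heterocyst_NIT",
         "Vegetative_HOX", "Vegetative_HUP"],
    )
    assert ko == pytest.approx(0.0, abs=1e-8)


def test_inactive_knockout_changes_nothing(diazo_h2, het_exp):
    """Deleting a reaction that never carries flux leaves the H2 max alone."""
    wt, ko = knockout_h2(diazo_h2, het_exp, ["Heterocyst_FRUt"])
    assert ko == pytest.approx(wt, abs=1e-8)


def test_knockout_guards(diazo_h2, het_exp):
    with pytest.raises(ModelError):
        knockout_h2(diazo_h2, het_exp, [])
    with pytest.raises(ModelError):
        knockout_h2(diazo_h2, het_exp, ["NOPE"])
    with pytest.raises(ModelError):
        knockout_h2(diazo_h2, het_exp, [diazo_h2.model.objective_id])


# ---------------------------------------------------------------------------
# H2 x O2 robustness surfaces
# ---------------------------------------------------------------------------


def test_growth_declines_with_forced_h2_at_constant_o2(diazo_h2):
    """Hydrogen production costs growth at any fixed O2 exchange, in both
    cell types."""
    for cell, o2 in (("Vegetative", 0.9), ("Heterocyst", -0.05)):
        surface = h2_o2_surface(
            diazo_h2, cell=cell, h2_grid=[0.0, 0.05, 0.1], o2_grid=[o2]
        )
        col = surface[:, 0]
        assert np.all(np.isfinite(col))
        assert col[0] >= col[1] - 1e-9 >= col[2] - 2e-9


def test_vegetative_iso_growth_h2_raises_o2_production(diazo_h2):
    """At constant growth, each extra unit of vegetative H2 demands more
    water splitting: the minimal O2 export rises monotonically."""
    exp = H2Experiment(cell="Vegetative")
    g0 = 0.9 * fba(diazo_h2).objective_value
    o2 = []
    for h in (0.0, 0.05, 0.1, 0.2):
        sol = fba(
            diazo_h2, exp.o2_exchange_id, maximize=False,
            overrides={exp.h2_exchange_id: (h, h), diazo_h2.veg_biomass: (g0, 1000.0)},
        )
        assert sol.optimal
        o2.append(sol.objective_value)
    assert all(a < b - 1e-9 for a, b in zip(o2, o2[1:]))
    assert o2[0] > 0  # photoautotrophic vegetative cells always evolve O2


def test_heterocyst_iso_growth_h2_lowers_o2_consumption(diazo_h2):
    """At constant growth, hydrogen export competes with respiration for the
    heterocyst's reductant: the attainable O2 consumption shrinks."""
    exp = H2Experiment(cell="Heterocyst")
    g0 = 0.9 * fba(diazo_h2).objective_value
    consumption = []
    for h in (0.0, 0.05, 0.1):
        sol = fba(
            diazo_h2, exp.o2_exchange_id, maximize=False,
            overrides={exp.h2_exchange_id: (h, h), diazo_h2.veg_biomass: (g0, 1000.0)},
        )
        assert sol.optimal
        consumption.append(-sol.objective_value)  # uptake is negative flux
    assert all(a > b + 1e-9 for a, b in zip(consumption, consumption[1:]))


def test_surface_slice_consistency(diazo_h2, het_exp):
    """The H2 = 0 row of the surface equals the 1-D O2 robustness curve."""
    from twocellfba import robustness_2d

    o2_grid = [-0.05, 0.0]
    surface = h2_o2_surface(diazo_h2, cell="Heterocyst", h2_grid=[0.0], o2_grid=o2_grid)
    for j, o2 in enumerate(o2_grid):
        sol = fba(diazo_h2, overrides={
            het_exp.h2_exchange_id: (0.0, 0.0), het_exp.o2_exchange_id: (o2, o2)
        })
        assert surface[0, j] == pytest.approx(sol.objective_value, abs=1e-8)


# ---------------------------------------------------------------------------
# oxygen turnover: the heterocyst is (nearly) anoxic
# ---------------------------------------------------------------------------


def test_heterocyst_o2_turnover_much_below_vegetative(diazo_h2):
    opt = fba(diazo_h2).objective_value
    sol = l1_minimal_solution(diazo_h2, fixed={diazo_h2.veg_biomass: opt})
    veg = metabolite_turnover(diazo_h2, sol, "Vegetative_o2_c")
    het = metabolite_turnover(diazo_h2, sol, "Heterocyst_o2_c")
    assert veg > 0.1
    assert het < 0.01 * veg


# ---------------------------------------------------------------------------
# regulated-model entry point
# ---------------------------------------------------------------------------


def test_h2_range_on_regulated_model(regulated, het_exp):
    """The same experiment runs on the expression-regulated model; the caps
    only tighten the attainable range."""
    h2_min, h2_max, sol_min, sol_max = h2_range_at_suboptimal_growth(regulated, het_exp)
    assert 0.0 <= h2_min <= h2_max
    assert sol_max.fluxes["Heterocyst_EX_h2_c"] == pytest.approx(h2_max, abs=1e-6)
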