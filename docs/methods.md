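# Methods

## Scope and model structure

The package implements constraint-based analysis of a two-cell-type
filament: vegetative cells and heterocysts of a diazotrophic cyanobacterium.
All computations reduce to linear programs over the steady-state flux cone
`{v : S·v = b, v_min ≤ v ≤ v_max}`; every extra biological constraint —
photon sharing, biomass coupling, per-gene expression caps — is an
additional equality row, with inequalities converted to equalities by
explicit non-negative slack variables whose rows carry the dual values
(shadow prices) that the analyses read off. LPs are assembled sparse and
solved with scipy's HiGHS backend (feasibility 1e−9, optimality 1e−8;
reported comparisons at 1e−6 — LP-standard values, since nothing in the
problem fixes them). Infeasible and unbounded problems are reported through
a status flag, never as exceptions, and infeasible cells of robustness grids
are NaN: "cannot grow at all" and "grows at rate zero" are different
statements.

### Two-cell composition

The composed model holds two id-prefixed copies of a base model with
cell-specific reactions *removed as columns* (not zero-bounded), which keeps
the dimension arithmetic exact: a base with n reactions and m metabolite
balances yields 2n + 3 + 1 variables (both cells' fluxes, three shuttles,
one photon slack) and 2m + 2 equality rows (both balance sets, photon
sharing, biomass coupling). Bicarbonate uptake exists only in the vegetative
copy, dinitrogen uptake only in the heterocyst copy. The three intercellular
shuttles (sucrose, glutamate, glutamine) are reversible
periplasm-to-periplasm transfers with ±1000 bounds — deliberately
unconstrained, so any directionality in the solutions is a prediction, not
an input. An optional glutamine:glutamate ratio toggle exists for
comparison with models that fix it, default off. The heterocyst biomass
composition equals the vegetative one; the heterocyst fraction (default
0.10 of the filament) and the total-growth factor (default 1.1) are
parameters.

In flux-level analyses (knockouts), deletions are implemented as zero
bounds, which is LP-equivalent to column removal and keeps wrapper models
(expanded/regulated) addressable by original reaction ids.

### Expression regulation

The irreversible/"without OR" expansion normalizes every GPR to disjunctive
normal form and emits one column per OR-alternative (each a pure AND of
genes), plus a backward column per reversible reaction. The expansion is
flux-space-equivalent through the mapping (forward − backward, summed over
isozyme copies); column duplication can in principle relax a binding upper
bound shared by isozymes, but with the ±1000 defaults this never binds, and
the equivalence is asserted in tests by optimum equality under many
objectives. Per measured gene and cell copy one row
`Σ_{i∈K_j} v_i + a_j = E_j·C` is added; genes mapping to no reaction in a
copy (e.g. nitrogenase genes in the vegetative cell, where the reaction was
removed) are skipped with a logged warning. Forward and backward copies of
one reaction both count in the sum — the cap is on catalytic capacity, not
net flux.

`C` is calibrated by a scan (default grid log-spaced 1e−4…1, 25 points,
bracketing the ~0.05 mmol/gDCW/h scale reported for the real organism):
for each C the regulated optimum (×1.1, a total filament growth) is
compared with an observed growth rate; the argmin of relative error is
returned, ties to the smallest C, infeasible grid points excluded. Gene
shadow prices are the duals of the gene rows (sensitivity to the rhs E_j·C);
since whether such prices should be quoted per rhs unit or per expression
unit is ambiguous, both are returned (`dual` and `dual·C`). Rows with slack
a_j above tolerance are forced to zero price (complementary slackness),
which also guards against degenerate dual bases; the binding price is
validated against finite-difference rhs perturbation in the tests.

### Degeneracy policy

Objective values come from plain FBA; every reported flux *distribution*
(differential-flux reports, turnover accounting, shuttle directionality)
comes from the Manhattan-norm-minimal solution at fixed objective values,
computed by the standard split into non-negative parts. This removes the
arbitrary-basis noise of simplex optima.

### Hydrogen analyses

Hydrogen production is measured at the H2 exchange flux (secretion).
`h2_range_at_suboptimal_growth` pins growth to a fraction (default 0.90) of
the model's *own* optimum — so a knockout that lowers the optimum also
lowers its growth target, which is how removing the uptake hydrogenase can
free capacity for H2. The Hox fraction divides Hox-catalyzed H2 production
by total stoichiometric H2 production in the norm-minimal maximal-H2
solution, guaranteeing a value in [0, 1] even when hydrogen is partly
recycled. Up/down classification of fluxes between the minimal- and
maximal-H2 states uses a 1e−6 threshold (solver-noise floor).

## The synthetic network

`make_toy_model()` is a deterministic, bit-reproducible 50-reaction network
with lumped pseudo-metabolites: PSII ("psbJ_toy and psbO_toy"), PSI, a
plastoquinone and a ferredoxin pool, cyclic photophosphorylation,
respiration ("cox_toy or cyd_toy" — the OR exercises the isozyme
expansion), bicarbonate dehydration, a RuBisCO/Calvin lump, a glycolysis
stub with a formate branch, the oxidative pentose phosphate pathway,
sucrose synthesis/alkaline-invertase cleavage, GS/Fd-GOGAT,
nitrogenase (16 ATP + 8 reduced ferredoxin per N2, one obligatory H2),
Hup and bidirectional Hox hydrogenases, and a biomass reaction assembled by
the parameterized builder from the organism's measured dry-weight
composition (protein 48.3%, carbohydrate 24.53%, lipid 11.6%, RNA 9.1%,
DNA 2.27%, ash 4.2%) over four pseudo-monomer pools with realistic
molecular weights, plus 30 mmol/gDCW growth-associated ATP.

All reactions are balanced for C, N, O and P against pseudo-formulas
(checked in tests); H, charge, and the electron bookkeeping of the carrier
pairs are untracked, but carrier stoichiometry is electron-consistent
(1 NADPH ≡ 1 H2 ≡ 2 reduced ferredoxin ≡ 2 e−), so no redox perpetuum is
expressible. Membrane transport is lumped into the consuming reactions;
the periplasm appears only as the shuttle compartment. Two choices deserve
explanation:

* **Ferredoxin reduction.** FNR runs forward only (Fd→NADPH); the uphill
  direction is a separate ATP-energized route (0.2 ATP per Fd pair). With a
  freely reversible FNR the uptake hydrogenase would be exactly redundant
  against Hox-reverse, and no Hup phenotype of any kind could exist in the
  model.
* **Zero non-growth maintenance.** The NGAM floor is 0 so that a cell with
  no energy source is a feasible zero-growth state (and the C-calibration
  error curve is total over its grid) rather than an infeasible LP; the
  `ngam_atp` plumbing stays available for users who want a floor.

Expression profiles are deterministic: a uniform baseline (500 arbitrary
units, microarray-like — only the product E·C matters), and a
differentiated profile that silences PSII/RuBisCO/carbonic-anhydrase/GOGAT
genes in the heterocyst, doubles the nitrogenase/hydrogenase genes there,
and (in the bottleneck scenario) drops the PSII core gene to 56 units in
the vegetative cell — an emulation of the under-expressed PSII subunit that
limits growth at high irradiance in the real organism.

Two condition regimes are used deliberately: the photon-limited default
(photon budget 20 = 2 × the −10 per-cell policy bound) for growth and
calibration analyses, and the carbon-limited photoautotrophic preset
(HCO3 ≤ 1, photon/N2 ≤ 1000 mmol/gDCW/h) for the hydrogen experiments. In
the second regime the norm-minimal solutions reproduce the expected
mechanism: at minimal H2 the uptake hydrogenase recycles exactly the
nitrogenase-evolved H2; at maximal H2 it is silent, the bidirectional
hydrogenase supplies the majority of the hydrogen from OPPP/glycolytic
NAD(P)H, and the nitrogenase rate is pinned by the fixed growth rate.

## What a green test does and does not establish

The toy network reproduces the *constraint structure* and the qualitative
phenotypes of a real two-cell reconstruction — coupling arithmetic,
expression-cap behavior, shadow-price localization, knockout directions,
iso-growth H2/O2 trade-offs, the heterocyst's near-zero O2 turnover. It
does not emulate genome-scale pathway redundancy, realistic P/O or quantum
yields, kinetic limits, or measured expression distributions, so absolute
numbers (growth rates, H2 yields, the calibrated C) are toy-scale only.
One degeneracy is structural: because the bidirectional hydrogenase
interconverts H2 and NAD(P)H 1:1, removing Hup cannot *strictly* raise the
toy's H2 maximum at a fixed optimum fraction (it ties exactly); the strict
effect the toy does express is that Hup removal lowers the diazotrophic
growth optimum under a binding photon budget. Quantities that require the
real organism's deposited model and expression data (the mixotrophic-growth
Pearson correlation, the 60% Hox share, C = 0.05, the 8.45e−4 heterocyst O2
turnover) are computable with the same functions but are not asserted
against those published values here.

## Numerical choices

* Comparisons against optima: 1e−6; constraint satisfaction asserted at
  1e−9; finite-difference dual checks at 1e−5.
* `scan_C` ties break to the smallest C after rounding errors at 1e−12.
* Robustness-grid infeasibility is NaN, never 0.
* Equation text in the tabular dialect serializes coefficients at 17
  significant digits (exact float round trip); SBML round trips are exact
  except coefficient text at the format's 15-digit precision.
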