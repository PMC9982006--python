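# Methods

This note documents the models, conventions and parameter choices behind
`gsmm`, in the order a study would use them.

## Model representation and conventions

A model is metabolites, reactions (stoichiometry map, bounds, GPR tree,
optional subsystem label), a gene set, and one objective reaction. Fluxes
are in mmol/gDW/h; the biomass reaction's flux is read as the specific
growth rate μ in h⁻¹. Coefficient signs: negative = consumed. Exchange
reactions carry exactly one metabolite; negative flux is uptake, positive
is secretion — stated once here and used everywhere.

GPR trees are boolean AND/OR expressions over gene ids (AND = complex
subunits, OR = isozymes). An **empty GPR means the reaction cannot be
removed by any gene deletion** (spontaneous or orphan reaction). This
convention also makes the gene-associated fraction of a model well defined
as the complement of empty-GPR reactions, counted over *all* reactions,
exchanges included. The GPR string parser accepts case-insensitive
`and`/`or` with parentheses; AND binds tighter than OR.

Subsystem labels are free strings; any rollup into reporting groups is a
configuration concern, not hard-coded.

### File formats

SBML Level 3 + fbc v2 is read and written through libsbml (bounds as
shared parameters, the objective as an fbc objective, GPRs as
gene-product associations, subsystems in reaction notes). The package's
canonical interchange form is a versioned JSON dialect (`gsmm-model-1`):
ids, stoichiometry maps, bounds, GPR as nested arrays
(`["and", [...]]` / gene-id strings), compartments, objective, optional
genome ORF count. Bounds absent in input default to (−1000, 1000) for
reversible and (0, 1000) for irreversible reactions (COBRA convention).
Media are YAML maps from exchange id to `[lower, upper]`; applying a
medium closes every exchange and then opens the listed ones. Phenotype
tables are TSV with columns substrate / role / exchange_id / in_vivo /
reference; `+`/`−` calls are parsed strictly (ASCII and Unicode minus).

## LP core

All solves use `scipy.optimize.linprog` (HiGHS) with feasibility and
optimality tolerances of 1e−9. Infeasibility and unboundedness are
reported as statuses, not exceptions. Only objective values are
contractual: under degenerate alternate optima the flux vector is one
representative vertex, and no test asserts individual fluxes unless FVA
pins them. A duality-style test cross-checks optima against an
independently constructed LP (cobra/optlang via SBML) to 1e−6 relative.

FVA solves min/max per reaction subject to objective ≥ fraction × optimum.
Robustness analysis computes the control reaction's feasible range (FVA at
fraction 0), fixes it at `n_points` evenly spaced values, and maximizes
the objective at each; infeasible points are recorded as 0, and the
plateau onset is the smallest control value whose objective reaches
(1 − 1e−3) of the curve maximum. The 1e−3 relative plateau tolerance
reflects the 2–4 significant digits such curves are read at.

## Biomass assembly

For each macromolecular class with mass fraction f (g/gDW) and monomers
with mole fractions x_i and molecular weights MW_i (g/mmol), the consumed
coefficient is f·x_i / Σ_j x_j·MW_j, which makes total consumed monomer
mass exactly 1 g per unit biomass — the property the tests assert.
Growth-associated ATP maintenance (GAM) adds ATP + H2O → ADP + Pi + H on
top and is excluded from the mass normalization; non-growth maintenance is
a separate model property (a reaction with fixed lower bound) defaulting
to 0. The packaged composition is a *synthetic stand-in* with
actinomycete-like fractions (45% protein, 25% cell wall, small monomer
tables) for exercising the arithmetic; measured compositions plug in
through the same structure.

## Phenotype screening

A sole-source screen closes every exchange able to supply the screened
element, opens the candidate at an uptake rate of 10 mmol/gDW/h (a
conventional glucose-scale rate), and calls growth when the biomass
optimum reaches 1e−6 h⁻¹. Both values are configurable; the thresholds
matter only within a few orders of magnitude because FBA growth is either
structurally zero (no route) or comparable to wild type. Carbon screens
leave amino-acid nitrogen available, matching how sole-carbon plate tests
are read; nitrogen screens keep glucose as the carbon source. Bounds are
snapshot/restored around each record, so screening is order-independent
and side-effect free. Agreement is scored as 100 × agreements / records to
one decimal, with discordant substrates listed.

The packaged utilization table transcribes the published 28-carbon /
6-nitrogen plate results for *S. radiopugnans* with both the in-vivo and
the published in-silico call columns; its exchange ids are BiGG-style
placeholders remappable to any model namespace.

## Gene essentiality

Deleting a gene zeroes the bounds of every reaction whose GPR evaluates
false without it; the model is re-solved and the ratio μ_deleted/μ_wt
classifies the gene: essential below 0.01, partially essential in
[0.01, 0.5), non-essential above. The literature names these three classes
but no universal cutoffs; 0.01/0.5 are conventional defaults, exposed as
parameters. Equivalence of GPR-mediated deletion with brute-force
reaction knockout is a tested invariant, as is deletion monotonicity.
Comparison against an essential-gene database is injected as a
precomputed mapping (gene → matched), since sequence searches are
database-version-dependent; predicted genes absent from the mapping count
as unmatched with a warning.

## Strain design (MUST/FORCE)

Two flux spaces are compared by FVA: wild type (medium, fixed measured
fluxes such as substrate uptake, growth ≥ 90% of maximum) and a
hypothetical overproducer (same constraints plus a minimum product flux,
default 50% of the theoretical maximum). With tol = 1e−6:

- MustU: overproduction minimum > wild-type maximum + tol;
- MustL: overproduction maximum < wild-type minimum − tol;
- MustZero: overproduction forces |flux| ≤ tol while the wild-type range
  excludes 0.

Only first-order sets are computed; the pairwise MustUU/MustLL/MustUL
sets of the full algorithm are a documented limitation, consistent with
reporting single-reaction/gene targets. The FORCE search greedily adds
the bound-tightening (up: lb ← wild max; down: ub ← wild min; knockout:
bounds ← 0) with the largest marginal gain in the *guaranteed* (minimum)
product flux, tie-broken by reaction id, and verifies the final set by
re-minimizing the product flux under the tightened bounds — soundness is
asserted on every run. Gene-level reports inherit reaction directions;
conflicting directions are flagged, empty-GPR reactions are reported as
non-genetic (process) levers, and subsystem keywords group targets into
four functional classes (precursor accumulation, product synthesis,
by-product elimination, energy supply).

## Network statistics

The model graph is simple and undirected with one node per metabolite,
reaction and gene: edges are nonzero stoichiometric incidences and
distinct GPR-leaf incidences. Gene nodes are included because the node
count is then exactly n_metabolites + n_reactions + n_genes, which is the
identity that pins this otherwise ambiguous convention (1,399 + 1,411 +
767 = 3,577 for the *S. radiopugnans* reconstruction). Distance statistics
(diameter, radius, characteristic path length) are computed on the
largest connected component so they stay finite on disconnected graphs,
matching common network-analyzer behavior; density is 2E/(N(N−1)),
heterogeneity the coefficient of variation of degree, centralization
Freeman's degree centralization N/(N−2)·(max_deg/(N−1) − density). A
single-node graph reports diameter 0 and density 0.

## Growth kinetics

CDW (g/L) = 0.36 × OD600. Growth curves are fitted by least squares with
the logistic X(t) = K / (1 + ((K−X0)/X0)·e^(−rt)); this parameterization
is fixed (the named "logistic function" of curve-fitting software has
variants) so that μ(t) = r(1 − X(t)/K) and μ_max = r(1 − X0/K) are well
defined. Differentiation is analytic on the fitted curve, never finite
differences on raw data. Fitting uses nine deterministic multi-starts
(three K scales × three rate scales) with tight convergence tolerances,
so results are reproducible given the data; K > X0 > 0 and r > 0 are
enforced, a flat series is rejected as unidentifiable, and a
non-increasing series draws a warning. Substrate depletion is fitted with
the same sigmoid family mirrored — C(t) = c_top − logistic(t) with a free
plateau offset — and the specific consumption rate divides dC/dt by the
concurrent CDW.

## Synthetic generators: what they emulate and what they do not

Generators build networks from feasible pathway motifs (chains, branches,
cofactor couples) rather than random stoichiometry, because random sparse
S-matrices are almost surely infeasible. All are deterministic given a
seed.

**Toy core model** (8 reactions): glucose uptake bounded at 10 mmol/gDW/h,
2 pyruvate per glucose, 3 pyruvate per biomass, plus an optional product
branch; the optimum 20/3 is hand-derivable and every LP feature is
testable against full vertex enumeration.

**Strain-design testbed**: glucose-derived acetyl-CoA splits between a
product route (FPP-like precursor, then an NADH-consuming synthase gated
by a geoA analog) and two biomass-feeding drains (TCA-like, acnA analog;
fatty-acid-like, fabD analog), with an NADH oxidase (nuo analog) burning
surplus reducing power. Biomass is NADH-neutral by construction, so the
product maximum is NADH-limited while carbon stays in surplus; at that
maximum the oxidase flux is forced to zero, the drains fall below their
wild-type levels, and the synthase exceeds its wild-type maximum — the
planted up/down/knockout key the MUST analysis must recover. The
companion overproduction spec therefore sets the product minimum at the
theoretical maximum (scaled by 1 − 1e−9 to absorb solver rounding); seeded
variants draw drain capacities in [5, 20] mmol/gDW/h and the NADH coupling
in {5, 6, 8} per product, ranges chosen so the drains remain obligatory
for wild-type growth and the key provably never changes.

**Phenotype fixtures**: n substrates, each with an exchange and
transporter; a catabolic step into the biomass pool exists only where
growth is intended. Exactly m planted mismatches keep an in-vivo "+" with
the pathway missing (the screen must call "−"), mirroring how real
reconstructions disagree with plate data through pathway gaps; a quarter
of the concordant substrates are true negatives.

**Growth series**: logistic curves (defaults K = 4 g/L, r = 0.15 h⁻¹,
X0 = 0.05 g/L over 72 h, emulating a slow filamentous batch culture) with
multiplicative Gaussian noise at σ = 0.02 for recovery tests.

These constructions exercise the algorithms' logic, not genome-scale
numerics: passing tests show correctness of the methods on networks whose
answers are provable by construction, and say nothing about the curation
quality of any particular reconstruction. Results that depend on the
*S. radiopugnans* model file itself (its μ_max, per-substrate geosmin
production rates, the urea-uptake plateau at 88.38 mmol/gDW/h, the
essential-gene count) can only be reproduced by loading that file through
`read_sbml`/`read_json_model` and running the same entry points.

## Problem sizes and determinism

The test suite and the acceptance script run entirely on the synthetic
constructions: vertex-enumeration cross-checks on the 8-reaction toy
(100 random bound perturbations), exhaustive GPR truth tables to 5
leaves, 20 seeded testbed instantiations, 20 noisy growth series, and
10 random 30-node graphs against a Floyd–Warshall oracle — sizes at which
the independent oracles are exact and fast. The acceptance script derives
every sub-seed from its `--seed` argument; reports are stamped with a
configuration hash, and rerunning a pipeline configuration reproduces its
reports byte for byte.

## Known limitations

- No parsimonious/quadratic FBA, dynamic FBA, or integer-programming
  formulations (the FORCE search is greedy with a verified guarantee, not
  a bilevel MILP).
- First-order MUST sets only (see above).
- No elemental/charge balancing audits or thermodynamic constraints.
- The greedy FORCE search requires strict marginal improvement; intervention
  sets whose members help only jointly are found when ties resolve toward
  them (as in the two-drain tests) but are not guaranteed in general.
- MATLAB .mat import and identifier web lookups are out of scope.
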