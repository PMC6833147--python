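# Methods

## Scope and model

gemkit analyses genome-scale metabolic models under the standard
constraint-based steady-state assumption: internal metabolite pools are
balanced (S v = 0) and each flux is boxed by lower/upper bounds in
mmol/gDW/h. Exchange reactions move one extracellular metabolite across
the system boundary; by convention negative flux is uptake. Growth is the
flux of a biomass pseudo-reaction (h⁻¹) whose stoichiometry encodes the
cell's macromolecular composition. Gene control enters only through
boolean GPR rules: AND across subunits of a complex, OR across
isoenzymes; a reaction with no rule is spontaneous and can never be
switched off by expression data.

## Linear programming core

FBA, flux variability (FVA), producibility and surplus analyses are all
LPs solved with HiGHS through `scipy.optimize.linprog`, single-threaded
with presolve on, so repeated solves are bit-stable. Duals are reported
on the scale of the stated objective: the reduced cost of a reaction is
∂(objective)/∂(bound) at its binding bound (0 if interior), so a
growth-limiting nutrient is the uptake exchange with the largest
|reduced cost|. This convention is checked in-package by a
finite-difference routine that perturbs a bound by δ and compares the
empirical slope; the two agree as long as δ does not cross a basis
change.

Numerical choices: flux classification tolerance 1e-6 mmol/gDW/h (a flux
below it is "zero"); bound-feasibility tolerance 1e-9; a "producible"
metabolite has maximal demand flux > 1e-6, except during gap filling
where the threshold is ε = 0.01 (exposed as a flag) because a repaired
pathway should carry appreciable flux, not a numerical sliver. Zero-flux
reactions are defined by FVA (min = max = 0 at a given growth fraction)
rather than by a single FBA solution, because optimal solutions are
degenerate; the growth fraction is a parameter, default 0.9 to match the
surplus analysis.

## Condition-specific models

A gene is inactive in a condition iff it has a recorded value in every
replicate and all values are exactly zero. There is deliberately no
abundance threshold, and a gene missing from the table stays active —
absence of evidence is not evidence of absence. Reactions whose GPR
evaluates false under the inactive set get bounds (0, 0); all other
constraints are untouched. Isoenzyme cases are resolved purely by the
boolean rule (one active OR branch keeps the reaction open); no manual
review layer is modelled. Conditions excluded from modelling can still
contribute to the "inactive in ≥ 1 condition" union via
`inactive_in_any_condition`.

Auxotrophy rescue adds, per affected metabolite, an extracellular
counterpart, an exchange with uptake open, and a transport reaction into
the metabolite's own compartment. The default uptake bound is generous
(1000 mmol/gDW/h) — the rescue expresses "the rich medium supplies it",
not a measured abundance; pass a smaller bound when one is known. A
consequence worth knowing: the *rescued* metabolite's own surplus
capacity becomes uptake-driven and is not informative; severed synthesis
is better probed at an unrescued product downstream of the break (the
FAD probe in the shipped study does exactly this).

## Surplus capacity at fixed growth

The biomass reaction is clamped with lower = upper bound at
fraction × μmax (clamping both bounds matters: with only a lower bound
the solver could trade precursor secretion against extra growth), then
one demand sink at a time is maximised — a joint maximisation over
several precursors would not be a single well-defined LP. The clamp
backs off by a relative 1e-9 from the exact optimum so the fixed-growth
LP remains feasible under solver round-off. Relative values are
normalised per metabolite to the largest condition (100%); an all-zero
metabolite reports 0% everywhere. Surplus is provably non-increasing in
the growth fraction and this is property-tested.

## Biomass construction

For a macromolecular class with dry-weight fraction f (g/gDW) and
monomer mole fractions xₘ with residue masses Mₘ (g/mmol), the
coefficient of monomer m is f·xₘ / Σₖ xₖ·Mₖ (mmol/gDW), which makes each
class consume exactly f grams and the whole equation exactly 1 g/gDW.
Residue masses are polymer-incorporated (free monomer minus one water
for protein/DNA/RNA) — the closure forces this convention.
Polymerisation ATP costs are folded into the growth-associated
maintenance (GAM) term of the biomass reaction rather than charged per
monomer; non-growth maintenance (NGAM) is a separate ATP-hydrolysis
reaction with a fixed lower bound. GAM, NGAM and the P/O ratio are study
inputs carried in the model's maintenance block; the package asserts no
defaults for them. Carbohydrate mass is split into measured wall
polymers (glucan, mannan, chitin) with the remainder divided between
trehalose and amylose at a given molar ratio. The composition is
growth-rate independent; biomass equations built this way are generally
trusted below μ ≈ 0.3–0.4 h⁻¹ and no rate-dependent rescaling is
attempted.

## Gap filling

Minimal-addition gap filling is a MILP: one binary per pool reaction,
pool fluxes gated by their binary (lb·y ≤ v ≤ ub·y), minimise Σy subject
to the target's demand flux ≥ ε. Among equal-cardinality optima the
lexicographically smallest id set is returned, found by a greedy
force-in pass over sorted ids with a MILP feasibility check per id —
determinism is what makes results testable against exhaustive subset
enumeration, which the test suite does for every fixture with pool ≤ 12.
Candidates carry provenance tags (template model, reference database) so
a curator can review them; the package does not model the literature
check itself. Per-component filling runs component-wise on the
incrementally augmented model, so a reaction needed by two components is
added once and attributed to the first; the union of additions is
order-invariant on the shipped fixtures, the attribution is not.

## Synthetic data: what it emulates and what it does not

The generator produces the study's three input kinds. (1) A
compartmentalised toy GEM: glucose uptake with a gene-bearing
transporter, a gated xylose arm, five two-step biosynthesis modules
feeding biomass precursors (each second step has a spare isoenzyme gene,
so planting the spare inactive perturbs expression without touching the
network), and a cofactor chain with the riboflavin topology — two
converging branches (GTP-like and pentose-phosphate-like), a
lumazine-like junction, then riboflavin → FMN → FAD with one gene per
step. Biomass consumes each precursor at 1/n plus 0.01 riboflavin, so
μmax ≈ 9.8 at an uptake bound of 10. (2) Expression tables: three
replicates per condition by default, planted genes exactly zero in all
replicates, all other values strictly positive log-normal(μ=2, σ=1)
draws (arbitrary but fixed — only zero/non-zero matters to the calling
rule), plus one non-planted gene with a zero in exactly one replicate so
the all-replicates rule is genuinely exercised. (3) Growth-rate tables:
true μ from FBA at clamped uptakes, observed μ with additive Gaussian
noise truncated at zero (default σ = 0.02 h⁻¹, a few percent of typical
yeast growth rates).

The shipped four-condition design plants the cofactor-chain breaks in
the static (30DS: the branch-step gene) and hot (45D: the junction and
kinase genes) conditions and gives the hot condition the most inactive
genes, mirroring the tighter regulation a heat-stressed transcriptome
shows. Spec consistency is verified semantically at build time: every
claimed auxotrophy must actually be non-producible under its planted
knockouts, and the base model must grow.

What passing these tests shows: the calling rule, GPR evaluation,
LP/MILP formulations, rescue mechanics and normalisations are correct on
networks where the ground truth is known by construction. What it does
not show: anything about real transcriptome noise structure (dropout,
depth), about the curation quality of a real reconstruction, or about
quantitative agreement with measured fluxes — the generator makes no
attempt at realistic kinetics or genome-scale network statistics.

## Problem sizes and determinism

Default test and acceptance runs use toy networks of ~20–30 reactions,
100 random models for solver cross-checks, 100–200 random compositions
for mass closure, and 100 random expression fixtures for recovery —
sizes chosen so the whole suite runs in seconds while still exercising
every code path; all randomness flows from explicit seeds and the LP
configuration is deterministic, so reruns are byte-identical.

## Known limitations

* No parsimonious FBA, loopless FVA or flux sampling; internal loops can
  carry arbitrary flux at low growth fractions (visible in FVA spans).
* Binary expression integration only — no GIMME/iMAT-style use of
  abundance levels, by design.
* The SBML layer targets L3 + FBC v2 and tolerates FBC v1/COBRA-notes
  bounds and GPRs; MAT-files and JSON dialects are out of scope.
* "Transportable cytosolic metabolite" has two defensible countings
  (cross-compartment reaction participation vs existence of an exchanged
  extracellular counterpart); both are exposed, cross-compartment is the
  default.
* Gap filling is unweighted (pure cardinality); no annotation- or
  likelihood-based scoring of candidates.
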