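# Methods

## Model representation and I/O

A model is metabolites + reactions + bounds + one objective reaction.
Metabolites flagged *external* are boundary species: they contribute no
row to the stoichiometric matrix, so the steady-state constraint never
balances them and reactions touching them act as exchanges. In the
reaction-list dialect, external species are declared in an explicit
`-EXTERNAL METABOLITES` section (authoritative) and additionally
recognised by the `_ext` suffix convention. Identifier comparison is
case-sensitive throughout — enzyme-style reaction names can differ only
by a suffix letter (e.g. `4.1.1.39b`), and case-folding would merge
them.

Stoichiometric coefficients are parsed and stored as exact rationals
(`fractions.Fraction`, accepting `2`, `0.53439` and `3/2` forms) and
converted to floating point only when the numeric matrix is assembled.
This makes the element-balance audit exact: a reaction scaled by any
positive rational is balanced iff the original is, with no tolerance in
sight.

Unconstrained fluxes get the conventional "effectively unbounded"
magnitude of 1000 mmol gDW⁻¹ h⁻¹ (`<->` ⇒ [−1000, 1000], `->` ⇒
[0, 1000]); any optimal flux that reaches this magnitude is logged,
since it usually signals a missing constraint. Explicit `-CONSTRAINTS`
lines override the defaults, which is also how reversibility control —
such as forcing NADH/NADPH transhydrogenation-prone reactions
irreversible — is expressed: as data, not code.

SBML export writes Level 2 Version 4 with `boundaryCondition="true"`
for external species and COBRA-convention kinetic-law parameters
(`LOWER_BOUND`, `UPPER_BOUND`, `OBJECTIVE_COEFFICIENT`); identifiers
not expressible as SBML SIds are sanitized deterministically
(non-alphanumerics → `_`, numeric-leading ids prefixed) and the mapping
is returned to the caller. Import reverses all of this, so
export→import is an identity up to ordering. Gene lists are stored,
never evaluated: gene–protein–reaction Boolean logic and full SBML
feature coverage (FBC, groups) are out of scope.

## Curation audits

*Element/charge balance* computes, per reaction, the products-minus-
substrates difference for every element of the supplied formula map.
Formulas are an input, not a shipped dictionary — which formula to
assign a metabolite is a curation decision we do not preempt. A
reaction with any participant lacking a formula is reported
`unknowable`, never `unbalanced`. Charge is compared only when every
participant carries a charge; otherwise it is silently skipped.
When the imbalance matches a missing water (H:O = 2:1) or bare protons,
the report carries a completion *suggestion*; nothing is ever applied
automatically, because balancing choices (which side, which cofactor)
belong to the curator.

*Duplicate detection* groups reactions by exact stoichiometry, plus
mirror-image pairs when both copies are reversible (A↔B and B↔A are the
same conversion). Grouping is a union-find partition, hence symmetric
and transitive. Duplicates are reported, not removed — apparent
duplicates may be intentional isoenzymes.

*Internal-loop detection* closes every exchange reaction (zero bounds)
and then maximizes and minimizes each remaining reaction's flux. In a
closed system the only steady-state flux vectors are internal cycles,
so a reaction with attainable |v| > 10⁻⁶ is part of a
thermodynamically infeasible loop. This is detection only; removal is
a modelling decision. Loopless-FBA with integer constraints is
deliberately out of scope.

## The LP engine

`scipy.optimize.linprog` with the HiGHS solver, presolve on, solving
min/max c·v s.t. S·v = 0, lb ≤ v ≤ ub, plus optional extra equality
rows (used for the combined-carbon constraint below). Solver statuses
map to `optimal` / `infeasible` / `unbounded` / `solver_error` and are
surfaced verbatim — a failed solve is never reported as a zero flux.
Solver feasibility works at HiGHS defaults (~1e−9); reported solutions
are asserted against the looser 1e−6 in tests. FBA optima are
degenerate as a rule, so tests assert objective values and aggregate
quantities, never individual fluxes except where the network forces
them.

**Two-step photoautotrophic optimization.** Step 1 maximizes the
biomass objective with photon uptakes bounded only by the default
magnitude. Step 2 pins the biomass flux into
[(1 − ε)·μ*, μ*(1 + ε)] with ε = 10⁻⁶ relative — exact pinning invites
numerical infeasibility — and minimizes the *sum* of the photon uptake
fluxes (a single objective; per-photosystem values are read off the
returned solution). If step 2 is infeasible at ε it is retried once at
10ε, then aborts with diagnostics.

**Inorganic carbon.** The combined CO₂ + HCO₃⁻ uptake is fixed by an
auxiliary equality row summing the named exchange fluxes to the given
total (default 1.99 mmol gDW⁻¹ h⁻¹ for the *S. elongatus* condition).
The alternative reading — each species bounded individually at the
stated value — is one flag away (`combined_carbon=False`); on a model
with two equivalent carbon sources it simply doubles the available
carbon, which is how the two readings can be told apart against a
reference model.

## Photon budget

Exact prolate-spheroid surface area (not the Thomsen approximation):
A = 2πb²(1 + a/(b·e)·arcsin e), with the sphere limit handled exactly.
The budget is A[m²]/dry-weight[g] × irradiance × 3600 × photoperiod
fraction. The photoperiod fraction defaults to 1 (continuous light)
and is *not* applied when reproducing the ≈ 2.0 mE gDW⁻¹ h⁻¹ ceiling
for the measured cell: a 12:12 factor of 0.5 would halve the value,
contradicting the published estimate, so continuous illumination is
evidently the intended reading. The ~2% gap between our exact 2.00 and
the published 1.96 is attributed to rounding or a coarser area formula
in the original estimate; we do not reverse-engineer it. The budget is
exposed as a number; whether to apply it as the photon-exchange upper
bound is the caller's choice, since the simulation minimizes photons
anyway. Self-shading, absorption cross-sections and wavelength
dependence are not modelled.

## Topology

Two degree conventions: *reaction participation* (number of reactions
containing the metabolite; default, unambiguous, directly readable off
S) and *metabolite adjacency* (distinct co-occurring metabolites).
External metabolites are excluded by default; currency metabolites are
never excluded — water, ATP and phosphate belong at the top of the hub
table. Hub ranking breaks ties lexicographically for determinism.

The power-law exponent is estimated from the empirical strictly-greater
CCDF evaluated at every observed degree ≥ k_min (default 1, using all
points), dropping the zero at the maximum, by unweighted OLS of
log₁₀ CCDF on log₁₀ k; the slope m gives γ = 1 − m, with r² reported.
This is a regression on the cumulative distribution, not a
Clauset-style maximum-likelihood fit; MLE is a documented alternative
left out of scope. The estimator has the known finite-size
shortcomings of CCDF regression (curvature at small k biases γ slightly
low); the sampler-recovery tests quantify this: single-sample error
≤ 0.15 at n = 2000 and mean bias < 0.05 at n = 5000 for γ = 2.5.

## Synthetic data

The generators define the conditions under which everything is tested;
all expected values are computed by construction-time accounting,
independent of the LP engine.

*Toy phototroph:* photon exchange → light-driven ATP synthesis →
bounded carbon uptake → an n-step fixation chain (each fixation burns
`atp_per_fixation` ATP at `photons_per_atp` photons each) → biomass
drain. By construction the optimal growth equals the carbon bound and
the minimal photon demand equals carbon × ATP-per-fixation ×
photons-per-ATP. A split-photosystem variant models a two-photosystem
Z-scheme (PSII reduces a plastoquinone pool, PSI consumes it), doubling
the photon cost and forcing equal flux through both photosystems —
the minimal-scale analogue of the 10-reaction electron-transport
representation in the full network. The default toy (carbon bound
2.0 mmol gDW⁻¹ h⁻¹, 3 ATP per fixation, 1 photon per ATP) keeps every
optimum a small exact number. The seed only permutes reaction insertion
order, which doubles as an order-invariance probe.

*Random LP models:* ≤ 8 reactions, ≤ 5 metabolites, small integer
coefficients, all bounds finite so the flux polytope is bounded and
vertex enumeration terminates; ~10% of reactions get a strictly
positive lower bound to exercise infeasible instances.

*Power-law sampler:* inverse-CDF on the zeta-normalised discrete mass
function P(k) = k^(−γ)/ζ(γ, k_min), tabulated to k = 10⁵ with Hurwitz-
zeta bisection for the deeper tail. Mean checked against the closed
form ζ(γ−1)/ζ(γ).

*Broken models:* a clean linear pathway (all formulas CH₂O, all steps
1:1, hence balanced, loop-free and duplicate-free) with exactly one
planted defect — a CH₂O-losing reaction, a duplicated step, or a
reversible 3-cycle. The audits must recover exactly the planted defect
with zero false positives.

What the toys do **not** emulate: realistic pathway redundancy,
cofactor coupling (ATP is produced from photons alone, without ADP
bookkeeping), compartments, and the sheer degeneracy of genome-scale
optima. Passing on them demonstrates the correctness of the machinery,
not predictive accuracy on real networks — that check requires the
deposited genome-scale model, which must be obtained from BioModels
separately.

## Problem sizes and numerical choices

The LP cross-validation runs 200 random models against brute-force
vertex enumeration (every subset of n − rank(S) fluxes pinned at a
bound, residual equality system solved by least squares) — small
enough that the oracle enumerates every vertex exactly. The two-step
sweep covers chain lengths 1–5, 1–3 photons/ATP and 1–4 ATP/fixation.
Audit recovery uses 50 seeded broken models per defect kind. Power-law
recovery uses n = 2000 (single seed) and 20 × n = 5000 (bias). All
randomness flows through explicit integer seeds; there is no global
RNG state.

## Known limitations

- The element-balance audit is only as good as the formula dictionary
  given to it.
- CCDF regression is a biased power-law estimator at small k_min;
  treat γ as descriptive, not inferential.
- Loop detection is O(2 · reactions) LP solves; fine at genome scale
  but not optimised for repeated interactive use.
- The biomass drain carries no growth-associated maintenance ATP term;
  if the modelled organism's composition includes one, it must be added
  as a composition entry or separate reaction.
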