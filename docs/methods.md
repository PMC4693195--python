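# Methods

## Constraint-based screening

### Model and linear program

A metabolic model is a list of metabolites and reactions with signed
stoichiometry and flux bounds (mmol·gDCW⁻¹·h⁻¹), plus two named roles: the
growth (biomass) pseudo-reaction, whose flux is the specific growth rate
(h⁻¹), and the target reaction (here the single FPP-producing reaction).
Flux balance analysis maximizes or minimizes one reaction flux subject to
steady state `S·v = 0` and the bounds. The LP is solved with HiGHS through
`scipy.optimize.linprog` behind a minimal backend contract
(`lycoscreen.lp.solve_lp`) with primal/dual tolerances of 1e-9; only the
objective value is contractually unique, alternate optimal flux vectors are
permitted. An optional flux-variability helper brackets individual fluxes
at a fixed objective for inspecting alternate optima; it is a cross-check,
not part of the screening procedure.

Conventions chosen once and used everywhere:

* Exchange (boundary) reactions are those involving exactly one metabolite,
  written `metabolite → ∅`; uptake is negative flux, secretion positive.
* Fluxes with magnitude below 1e-9 are reported as zero. Screens of
  exchange fluxes routinely surface magnitudes like 1e-35–1e-13, which are
  rounding residue of the LP solver, not biology; the same threshold is the
  default `zero_tolerance` when listing consumed exchanges.
* Bounds default to ±1000 (irreversible: [0, 1000]) when a file omits
  them, the common constraint-model convention.
* All bound edits return copies; the scan never mutates its base model.

SBML Level 3 files (including fbc flux bounds) are read and written through
cobrapy; the JSON dialect — which additionally records the growth/target
roles — is handled directly. In the test-suite cobrapy also serves as an
independent FBA route that must agree with the package's own LP core; the
primary oracle there is exhaustive vertex enumeration of the flux polytope
on randomly generated models of ≤ 6 reactions, which is exact at that size.

### Supplement screening procedure

1. Maximize growth on the base (glucose minimal) medium → μ_max.
2. Pin growth with an equality at `growth_fraction × μ_max` (default 0.9 —
   slightly sub-maximal growth leaves flux room for product formation
   without abandoning the growth phenotype) and maximize the target flux →
   baseline.
3. For each candidate independently, set its exchange lower bound to
   min(current bound, allowance) — amino acids get −2 mmol·gDCW⁻¹·h⁻¹,
   other factors −1 — and re-maximize the target *at the same pinned growth
   rate*. Pinning at the base model's rate (not the relaxed model's own
   maximum) is essential: otherwise part of the supplement's benefit leaks
   into biomass and the recorded target gain understates the effect, and
   rows would no longer share one growth rate.
4. Record Δ(target), the candidate's uptake flux at the optimum, and sort
   by descending Δ. Zero-gain candidates are retained and flagged, not
   dropped.
5. C/N filter: a candidate passes if the base medium plus the candidate at
   its implied dose keeps the molar carbon-to-nitrogen ratio above 10
   (nitrogen excess suppresses the lipid/terpenoid accumulation regime in
   oleaginous yeasts).

Categories (amino acid vs factor) come from the medium file, never from
name heuristics. The flux-to-dose conversion for the C/N check is a
declared convention, not a derived one: |uptake flux| in mmol·gDCW⁻¹·h⁻¹ is
read as a mmol/L dose on a nominal 1 gDCW·h basis and converted to g/L via
the molar mass. It preserves candidate ordering and is overridable per
candidate (`dose_overrides`) when actual doses are known. Medium C/N uses
elemental formulas parsed from reagent-label notation (hydrate dots,
parenthesized groups); molar masses derive from standard atomic weights
when not given. A medium with no nitrogen reports C/N = +∞.

### The toy terpenoid network

`synthetic_data.make_toy_model` emits a ≤ 15-reaction network — substrate
exchange, lumped catabolism (optionally consuming oxygen), biomass
formation, one FPP-synthesis reaction (the target), sinks, and per amino
acid a closed exchange plus an assimilation reaction feeding the precursor
pool. Defaults: substrate uptake capacity 10 mmol·gDCW⁻¹·h⁻¹, biomass
yield 0.1 gDCW/mmol, FPP yield 0.05 mmol/mmol, and three amino-acid boosts
(gain per unit uptake 5e-4, 1e-3, 9e-4 at a −2 allowance), sized like the
small per-amino-acid improvements genome-scale screens report. The
generator returns the guaranteed optima: μ_max = yield × capacity, target
at pinned fraction f = FPP-yield × capacity × (1−f), and per-candidate
Δ = gain × |bound|. A zero FPP yield emits the synthesis reaction with a
zero upper bound (pathway absent), making the baseline target 0. What the
toy model does *not* emulate: realistic *Y. lipolytica* biochemistry,
cofactor balancing, maintenance ATP, or competition between amino-acid
carbon and product carbon — passing tests show the *procedure* is correct,
not that any particular organism behaves this way.

## Plackett–Burman construction and analysis

### Designs

Matrices for N ∈ {8, 12, 16, 20, 24} runs are built from the published
cyclic generator rows (first row rotated N−2 times, plus a final all-minus
run). Correctness is enforced by a validator — every column balanced, all
column pairs orthogonal, full column rank of [1 | X] — rather than string
comparison against a reference. Factor letters follow the DOE convention of
skipping "I". Printed concentration tables are ingested by exact level
matching (tolerance 1e-9 after numeric parsing) against a YAML sidecar
declaring each factor's low/high level; decoding violations of balance or
orthogonality are warnings, not errors, because printed tables are data.
Run-order randomization is seed-determined (`numpy` Generator; no global
state).

### Transformation rule

max/min ≤ 10 (computed over strictly positive values): identity. Above 10:
log₁₀ when all values are positive, square root when zeros occur (a zero
always counts as ratio > 10; sqrt(0) is legal, log₁₀ of zero is a hard
error, never silently offset). An explicit override is validated against
the data. Note the rule is a heuristic: a response can have ratio > 10 with
no zeros and still be analysed under sqrt by override — the packaged
literature-table biomass response is configured exactly that way, matching
its published equation.

### Effects, limits, classification

Intercept = grand mean of the transformed response; effect = high-mean −
low-mean per column; coefficient = effect/2. On an orthogonal design these
are the least-squares estimates, which the tests verify against a
normal-equations oracle at 1e-10. A saturated design (23 factors, 24 runs)
has no residual degrees of freedom, so significance requires pooling. The
packaged reproduction configs list the published reduced-model term sets
(read off each printed equation — e.g. H₃BO₃ and NaCl are absent from the
literature-table biomass equation); the generic path pools the `auto_k`
smallest-|effect| columns plus any dummy columns. Residual mean square
comes from the reduced-model least-squares fit; SE(coef) = √(MSE/n);
t = |coef|/SE. Limits: upper α/2 and α/(2m) t-quantiles at the residual
df, m = number of candidate effects, α = 0.05 two-sided throughout.
Classification: ≥ Bonferroni limit → certain, ≥ t limit → possible, else
insignificant. When the reduced model spans the response exactly (pooled
variance 0, detected at relative 1e-18), selected-term t-values are +∞ and
classified certain. Coefficients are reported in coded units only — the
published actual-unit-looking "coded" equations for some responses carry
magnitudes inconsistent with ±1 coding and are not reproduction targets.
Display rounding: 2 decimals at |c| ≥ 0.01, `m.mmm e±00k` scientific
below.

### Bioprocess statistics

Contents are quotients of unrounded inputs (lycopene/biomass in mg/g,
100·lipid/biomass in %), rounded only for display. When contents are
re-derived from a printed table, the inputs themselves carry half-ulp
rounding (2 decimals), so derived cells can differ from printed content
cells by up to ~0.03 where biomass is small; the tests bound each cell by
the propagated input rounding instead of a flat 0.01. Pearson correlation
uses the two-tailed t test on n−2 df (via `scipy.stats.pearsonr`); the
content correlation is computed from derived (unrounded) contents, and the
printed-column route agrees within 0.001 here. Range ratios report +∞ when
a zero is present, with a `contains_zero` flag in summaries.

### Response simulation

`simulate_pb_responses` draws `y = link⁻¹(β₀ + Xβ + ε)`, ε ~ N(0, σ²)
i.i.d., with links identity, squared (inverse of sqrt) or 10^(·) (inverse
of log₁₀) so the transformation rule can be exercised on data whose
transformed scale is known. Negative draws clip at 0 and the clip count is
reported, since zero-handling is itself under test downstream. Replicates
are extra response columns from one seeded generator.

## Problem sizes and determinism

The oracle sweeps use 200 random ≤ 6-reaction models (vertex enumeration is
exact and sub-second there) and 200 simulated 12-run replicates for
coefficient recovery against the 3σ/√n CLT reference — sizes at which every
check is exact or tightly bounded and the whole suite runs in about a
minute. All randomness flows from explicit seeds; identical seeds give
byte-identical outputs (manifests record seed and config hash per run).

## Known limitations

* The genome-scale *Y. lipolytica* model behind the original medium
  predictions is not redistributable, so its specific numbers (μ_max =
  0.0350 h⁻¹ on glucose minimal medium; baseline FPP 0.4332 and e.g.
  0.4342 after isoleucine relaxation at 0.0315 h⁻¹) serve as documentation
  examples only; the procedure is validated on the closed-form toy network
  and random-model oracles instead.
* Whether a relaxed exchange's reported uptake sits at its bound or at an
  interior optimum is model-dependent and not checkable without that file.
* No gene–protein–reaction rules, thermodynamics, kinetics, or dynamic
  FBA; no fold-over or response-surface follow-up designs; interaction and
  quadratic terms are out of scope for saturated resolution-III screens.
* The exact error-pooling behind the published significance calls is not
  recoverable; only the pure contrast quantities (grand means, coded
  coefficients) are treated as reproducible, and the packaged term sets
  make the pooling explicit.
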