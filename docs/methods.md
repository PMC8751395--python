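# Methods

This note documents the models and procedures implemented in rhizoflux,
the assumptions behind them, the defaults and why they were chosen, and
what the synthetic test conditions do and do not establish.

## Steady-state framework

Every computation treats metabolism as a stoichiometric system at steady
state: flux vectors `v` satisfy `S v = 0` with box bounds `lb ≤ v ≤ ub`.
Fluxes are in mmol h⁻¹ gDW⁻¹ by convention; the default bound magnitude is
1000, which acts as "unconstrained" for realistically scaled models.
Boundary reactions follow the usual sign convention: negative flux on an
exchange or sink is uptake, positive is secretion. Exchange reactions
represent transport across the system boundary for extracellular
metabolites; sinks supply intracellular metabolites whose transporter is
not annotated (bounds `(-1000, 0)`, i.e. supply only); demands force or
permit intracellular consumption (bounds `≥ 0`).

Gene-protein-reaction (GPR) rules are boolean expressions with
case-insensitive `and`/`or` and parentheses, no negation. A deleted gene
set disables a reaction when its rule evaluates false; an empty rule means
the reaction is spontaneous or non-enzymatic and is never disabled.

## Optimization layer

All linear programs are solved with HiGHS through
`scipy.optimize.linprog`; the MILP for loopless FVA uses
`scipy.optimize.milp`. HiGHS is deterministic, which the reproducibility
guarantees below rely on.

**FBA** maximizes `cᵀv`. Infeasibility and unboundedness are reported as
result statuses, not exceptions, because both are legitimate outcomes of a
screen (e.g. a carbon source that cannot support growth).

**Parsimonious FBA** constrains `cᵀv ≥ f·z*` (the target is relaxed by
`1e-9·max(1,|z*|)` so `f = 1` stays feasible in floating point) and
minimizes `Σ|vᵢ|` through the non-negative splitting `v = v⁺ − v⁻`. At the
optimum the splitting is tight, so the objective is the true taxicab norm.
Since any internal cycle adds flux without changing net production,
taxicab minimality drives cycles to zero — this is the mechanism behind
the loop-suppression guarantee tested in the suite.

**FVA** solves `2R` LPs at an objective fraction `f` (default 0.95 for
flux-envelope validation). The loopless variant enforces the loop law with
one binary direction indicator `aᵢ` and one potential variable `Gᵢ` per
internal reaction: `vᵢ` and `Gᵢ` must take opposite signs, and `NᵀG = 0`
where the columns of `N` span the null space of the internal
stoichiometry. Both variants are available because published analyses
rarely state which was used; result metadata records the variant.

**MOMA** minimizes `‖v − v_wt‖²` over the knockout polytope with the
`trust-constr` QP solver (`gtol 1e-12`). Two shortcuts keep the limit
cases exact: if the wild-type vector is still feasible after the knockout,
it is returned verbatim (zero adjustment is the unique optimum of a
strictly convex QP); an infeasible knockout returns growth 0 with status
`infeasible`. A linear (taxicab-distance) variant is available via
`quadratic=False` for installs where the QP path is unwanted. The
reference flux for deletion screens is the parsimonious FBA solution,
which is unique on the fixtures and avoids passing an arbitrary
alternate optimum as "the" wild type.

**Gene essentiality** disables all reactions whose GPR fails under a
single-gene deletion and re-evaluates growth with FBA or MOMA. The
essentiality threshold defaults to 50% of wild-type growth: in pooled
insertion-sequencing screens all mutants grow in one culture, so a mutant
at half the wild-type rate is depleted from the pool even though the gene
is not strictly essential.

## Flux sampling

Plain sampling is hit-and-run in null-space coordinates: directions are
drawn as `N g` with `g ~ N(0, I)` over an orthonormal basis `N` of
`null(S)`, so every iterate is mass-balanced to machine precision; step
lengths are uniform on the feasible chord. The start point is the average
of all per-reaction min/max LP solutions — a convex combination of
vertices that is well-centered without a separate Chebyshev-center solve.
Defaults: thinning 20, burn-in 100. These are adequate for the polytope
sizes this package targets (tens to ~1500 reactions); for very elongated
polytopes users should raise `thin`.

Weighted mode mixes hit-and-run steps with pulls toward two LP anchors
computed once per call: the expression-parsimonious state
(`argmin Σ(1−w_r)|v_r|`) and the weighted-flux-maximal state
(`argmax Σ(w_r − 0.01)|v_r|`). A pull moves the chain a uniform random
fraction of the way to a random anchor (probability 0.25 per step). The
contract is monotone bias — expected |flux| non-decreasing in weight — not
a particular stationary distribution; tests assert the contract, and the
contextualization results depend only on flux *rankings*, which are robust
to the exact mixture. Identical seeds give bit-identical sample matrices.

## Environments and screens

An environment is a list of available metabolites plus optional fixed
uptake rates. Applying it first closes every exchange and sink to uptake
(secretion stays open, since a screen should not prevent overflow
metabolism), then opens the uptake routes of listed metabolites:
extracellular metabolites through their exchange (lower bound
`−uptake_bound`, default 1000), intracellular-only metabolites through a
sink `(-uptake_bound, 0)`. Fixed uptakes clamp the bound to the measured
rate (e.g. glucose at 1.710 mmol h⁻¹ gDW⁻¹). Environment metabolites
absent from the model are warned about and reported, never silently
dropped, and name matching is exact (against the metabolite id or its
compartment-stripped stem) — fuzzy matching would be untestable.
Growth calls use a strict tolerance of 1e-6 h⁻¹ to separate true growth
from solver noise.

## Contextualization

The integration strategy assumes transcript abundance is a (noisy,
monotone) proxy for the likelihood that a reaction carries flux. Abundance
is aggregated over GPRs with OR → max (isoenzymes add capacity) and
AND → min (a complex is limited by its scarcest subunit), then normalized
by the maximum gene-associated value to weights `w_r ∈ [0,1]`;
non-gene-associated reactions receive the median weight so they are
neither favoured nor punished.

Pruning minimizes `Σ(1−w_r)|v_r|` subject to the objective fraction and
any task constraints. A reaction is removed only if (a) it carries no
flux in the minimizer and (b) its flux range is zero across the *optimal
face* of that weighted program (cost capped at its minimum plus 1e-9
relative slack). Condition (b) is what protects alternative routes tied
at the optimum — exactly the states the sampler will explore — while decoy
routes that any optimal solution avoids are removed. The removal flux
threshold is 1e-5: two orders of magnitude above the parasitic flux the
cost-cap slack can admit, and far below any genuinely usable route. Task
protection is absolute: reactions gated by protected genes, forced
reactions, and the objective are never removed. After pruning, the
objective floor is baked into the pruned model (single-reaction
objectives), so sampling explores only near-objective states; orphaned
metabolites and genes are dropped.

Max fit evaluates the fraction grid 0.50–0.95 in 0.05 steps (the grid is
configurable), scores each feasible fraction by the Spearman correlation
between per-reaction median |flux| (over 500 samples by default) and
GPR-aggregated abundance, then bisects around the best grid point at half
the step — which is how a best fraction can fall between grid points, e.g.
0.775. Correlation is computed over the gene-associated reactions of the
*parent* model with removed reactions contributing zero flux; this makes
fractions comparable (same point set) and penalizes models that prune
highly expressed reactions. Exact ρ ties across a plateau are resolved
toward the largest fraction — the least relaxation of the objective among
equally supported models. Medians rather than means are used throughout
because they are robust to sampler burn-in; uptake summaries report
median and IQR of |exchange flux|/objective flux per sample and drop
zero-median rows.

## Reporter metabolites

Gene p-values become z-scores `z_g = Φ⁻¹(1−p)` (p clamped to
`[1e-16, 1−1e-16]` to keep z finite). A metabolite's neighbourhood is the
deduplicated set of genes in the GPRs of its reactions. The aggregate
`z_raw = Σz_g/√k` is corrected against the empirical mean and SD of
`n_background` (default 1000; warning below 100) random size-`k` gene
sets drawn from the scored pool, and `p_reporter = 1 − Φ(z_corrected)`.
Directional analysis converts two-sided p-values to one-sided before the
z-transform (`p/2` concordant, `1 − p/2` discordant); the default mode
analyses up-regulation, with down and direction-agnostic modes available.
Currency metabolites (protons, water, ATP/ADP/AMP, NAD(P)(H), phosphate,
CO₂, O₂ — a user-visible list matched on the compartment-stripped id)
are excluded by default because they neighbour most of the genome and
swamp the ranking. The background correction is what gives type-I
control; the suite verifies ≤5% (+ Monte-Carlo slack) significance under
uniform p-values.

## Validation statistics

Confusion metrics use the standard definitions — accuracy
`(TP+TN)/total`, precision `TP/(TP+FP)`, recall `TP/(TP+FN)` — with
undefined metrics reported as `None`, never as 0. Confusion tables are
built over the intersection of predicted and observed id sets, mirroring
screens that only call compounds present in the model. Flux validation
flags whether each measured mean lies in the FVA envelope at the chosen
fraction (default 0.95) and reports the fraction in range. Amino-acid
enrichment is a residue-level upper-tail hypergeometric test (background
residues as the population, subset residues as the draw) per standard
amino acid, BH-adjusted across the 20 tests; non-standard letters are
counted but excluded from testing.

## Synthetic data: what it emulates, and what it does not

`make_toy_model` builds mass-balanced networks — exchanges and gene-gated
transport for 0–3 carbon sources, a linear catabolic chain with mixed
AND/OR/isoenzyme GPRs, optional two-reaction decoy bypasses, an optional
internal two-cycle, a sinked cofactor, a demand drain, and a biomass
reaction — whose FBA optimum is available in closed form
(`sources × uptake_bound × yield`), giving every optimization test an
analytic oracle. Default sizes stay under ~40 reactions so exhaustive
oracles (per-reaction LP enumeration, brute-force deletion) run in
seconds.

`make_planted_model` builds the generative fixture for contextualization:
eight parallel routes with a linearly staggered capacity spread (±25%)
feed biomass, sized so that exactly all of them are saturated at the
planted objective fraction (default 0.8 of the uptake-limited optimum);
overflow routes (needed only above the planted fraction) and pure
two-reaction detours are decoys; idle side branches take an intermediate
expression tier. Expression is simulated from the planted state: active
genes at a mean proportional to their reaction's reference flux
(normalized to its median, scale 100 RPKM), decoys at 10, others at 30,
with multiplicative lognormal noise (`mean·exp(σZ)`, exact means at
`σ = 0`). The default `noise_sd = 0.05` is deliberately below the
adjacent-capacity gap (~7%) so the planted flux ranking remains
identifiable; recovery of the planted fraction degrades gracefully as
noise grows past that gap, which users probing robustness can observe by
raising `noise_sd`.

Two properties of real data are *not* emulated: transcript abundance in
real cells is a weak, condition-confounded proxy for flux (correlations
near 0.2–0.35 rather than the ~0.9 the clean fixture reaches), and real
networks have deep pathway structure whose alternative routes differ in
cofactor usage rather than simple parallel capacity. Passing the
round-trip tests therefore establishes the *machinery* — weighting,
pruning, sampling, sweep and scoring interact correctly and recover a
known truth when one exists — not that a particular biological best-fit
fraction is accurate. Likewise `simulate_de_scores` plants sub-uniform
p-values (`u^(1+effect)`) around one metabolite's neighbourhood; it
validates calibration and power of the reporter statistic, not any
biological claim.

## Problem sizes and determinism

The test suite and the acceptance script run everything at fixture scale:
100 random toys for LP-oracle equivalence, 20 toys for deletion
agreement, 20 seeds × 150 samples for planted-context recovery, 50 score
sets × 300 background draws for reporter calibration. These sizes were
chosen so each check completes in seconds to a couple of minutes while
keeping Monte-Carlo error well inside the asserted tolerances; all are
parameters, not limits of the implementation. Every stochastic component
takes an explicit seed (`numpy.random.default_rng`), and identical
seeds reproduce byte-identical outputs, including TSV artifacts written
by the CLI (floats are formatted at 6 significant digits).

## Known limitations

- Multi-reaction objectives cannot have the objective floor baked into
  the pruned model's bounds, so weighted sampling of such contexts is not
  constrained to near-objective states (the sweep itself still applies
  the constraint during pruning).
- Loopless FVA scales poorly beyond a few hundred internal reactions
  (one MILP per bound); plain FVA plus parsimonious loop suppression is
  the practical route for genome-scale models.
- The hit-and-run sampler is not a calibrated ACHR replacement for
  genome-scale polytopes; for those, mixing diagnostics are the user's
  responsibility.
- SBML ids must be valid SBML SIds; the JSON dialect has no such
  restriction, so round-tripping arbitrary ids through SBML is not
  guaranteed.
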