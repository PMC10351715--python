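# Methods

## The problem

Small cell lung cancer tumors are mixtures of discrete transcriptional
cell states (subtypes **A**, **N**, **A2**, **Y**; A and N are
neuroendocrine, Y is non-neuroendocrine, A2 carries markers of both).
Bulk deconvolution of three cohorts gives, per cohort, the mean and
variance of each subtype's proportion across replicate samples.  Many
mechanistic stories are compatible with such data: which subtypes are
present, which seed the tumor, which convert into which, and whether the
non-neuroendocrine states modulate the growth of the others.  Rather than
committing to one story, the package enumerates every biologically
plausible candidate model, scores each by its Bayesian marginal
likelihood against the cohort summaries, and asks questions of the whole
ensemble (multimodel inference).

## Candidate-model grammar

A candidate is (topology, initiation, transitions, effects):

* **Topology** — any subset of {A, N, A2, Y} with 2–4 members (11
  options).
* **Initiation** — any nonempty subset of the topology's subtypes seeds
  the tumor; 100 cells are split equally among initiators.  Subtypes that
  are neither initiators nor reachable through transitions are
  inaccessible, and such candidates are discarded.
* **Transitions** — one of: none; the full unidirectional developmental
  hierarchy A→N, A→A2, N→Y, A2→Y (restricted to the topology); or
  symmetric bidirectional plasticity over any connected set of subtype
  pairs.
* **Effects** — no inter-subtype effect, Y as effector, or A2-and-Y as
  effectors (whichever members are present).  An effect scheme modulates
  either the division/death rates of the non-effector subtypes together
  with the late hierarchy steps (into Y), the same growth rates together
  with the early steps (out of A), or all hierarchical transitions alone.

Every subtype in a topology always divides and dies; the reaction catalog
over the full universe therefore holds 8 division/death reactions × 3
effect options = 24 variants, 4 hierarchical transitions × 3 = 12, and 8
non-hierarchical transitions (never effect-modulated) = 44 reaction-rule
variants in total.  Unconstrained, initiations × rule subsets would give
15 × 2^44 ≈ 2.6 × 10^14 models; the grammar above, after deduplicating
candidates with identical rule sets and initiators, yields 5,890
heterogeneous models.  The shipped preset also includes the homogeneous
single-A baseline (division + death only) — the "no heterogeneity" null
that matches the nearly monoclonal cell-line cohort — for a calibrated
total of 5,891 candidates.  The A2 class label (NE vs Non-NE) is tracked
but two candidates that differ only in the label describe identical
dynamics and are deduplicated; A2 acts as an effector exactly in the
A2-and-Y scheme.

All axes are configuration (`EnumerationConfig`), so restricted or
extended spaces are one object away.

## Population dynamics

Rules compile to ODEs over cell counts: division `+kX`, death `-kX`,
transition X→Z moving `kX`.  An effect-modulated rate follows the
saturating law `k_eff = k (1 + (m-1) w/(K+w))` with effector count `w`,
multiplier `m` and saturation constant `K` (in cells): the baseline rate
when no effectors are present, `k·m` at saturation.  This per-capita form
is chosen over plain mass action because it keeps the modulated rate a
bounded per-day rate (a 5% supportive effect turns 0.469/day into at most
0.493/day regardless of tumor size); a mass-action interaction would grow
without bound.  With all multipliers at 1, or no effect rules, the system
is linear and is solved exactly through the eigendecomposition of the
rate matrix on the full output grid; systems with active effects use
LSODA (rtol = atol = 1e-6).

Simulations run over a 60-day horizon on a fixed 601-point grid.  A
simulation is *at steady state* when every subtype's proportion
trajectory has a least-squares slope within ±1e-4/day over the final 7.5%
of the grid, and *valid* when in addition the final population exceeds
100 cells.  Non-finite states or more than 1e12 cells trip an overflow
guard.  Invalid or failed simulations are not scored.

## Likelihood

A cohort is summarized per subtype by mean proportion `x_s` and standard
deviation `sigma_s` across samples.  A valid simulation is scored as a
sum over the cohort's subtypes: a subtype present in the topology
contributes the log density at `x_s` of the Beta distribution
moment-matched to mean = simulated proportion and variance = `sigma_s^2`
(`nu = mu(1-mu)/sigma^2 - 1`, requiring `sigma^2 < mu(1-mu)`); a subtype
absent from the topology contributes `ln(lambda) - lambda x_s` with
`lambda = 1/sigma_s`, so omitting an abundant subtype is expensive and
omitting a rare one is cheap.  Simulated proportions are clipped to
[1e-6, 1-1e-6] before matching; a moment-matching failure, like a
non-steady simulation, returns the invalid sentinel (NaN).  All
logarithms are natural.  The sum runs over every subtype in the data
summary; compositional redundancy (proportions summing to one) is
accepted rather than dropping one subtype, since the choice of which to
drop would be arbitrary.

## Priors

Division and death rates: truncated normals on (0, inf), centered at a
per-rule rate table (default 0.469/day for division — a doubling-time
conversion — and 0.1/day for death; the table is an editable package
default, not a measured set) with 25% relative spread.  Transition rates:
uniform on [0, 1]/day.  Effect multipliers: truncated normals centered at
0.95 for division (effects damp growth by default) and 1.05 for death and
transitions, with twice the baseline relative spread.  Saturation
constants: log-uniform on [10, 1e5] cells (median 1000).

## Nested sampling

The bundled sampler is a classic single-ellipsoid-free implementation:
live points in the unit hypercube (the prior's inverse CDF maps the cube
to parameter space), worst-point replacement by a likelihood-constrained
random walk with a run-adaptive step size, geometric volume shrinkage
`X_i = exp(-i/n_live)`, rectangle-rule evidence accumulation (widths
telescope to exactly 1, so a flat likelihood integrates exactly), and
termination when the best remaining live point cannot move ln Z by more
than `dlogz` (default 0.01).  The reported uncertainty is
`sqrt(H/n_live)` with `H` the prior-to-posterior information gain.
Equally weighted posterior samples come from importance resampling of the
dead points.  Runs are fully determined by their seed.

Unscorable parameter sets (NaN log-likelihood) form an atom of zero
likelihood but real prior volume: the live set is filled by rejection and
the run's starting volume is the estimated scorable fraction, which keeps
evidences comparable between models with different scorable fractions.
If no scorable point is found within a draw budget the run aborts with a
diagnostic error.

`brute_force_evidence` (trapezoid integration on the unit cube, dimension
≤ 3) is the independent oracle used in the tests; the sampler is checked
against it, against analytic Gaussian and conjugate-normal evidences, and
against exact flat-likelihood integration.

## Multimodel inference

With equal model priors, `P(M_k|D) = Z_k / sum_j Z_j` (log-space).  Two
confidence sets: the smallest prefix of descending posteriors reaching
95% cumulative mass, and the relative-likelihood set of models within a
Bayes factor of sqrt(10) of the best.  Hypotheses are predicates over
candidates with priors; each hypothesis's evidence is the *mean* of its
member-model evidences (conditional prior `P(H)/|members|`), so equal
evidence everywhere returns the prior regardless of how many models carry
a feature (bias avoidance).  The hypothesis prior appears both in the
conditional model prior and in the final Bayes update, following the
reference formulation verbatim; a normalized variant (conditional prior
`1/|members|`) is available and provably identical whenever competing
hypotheses share one prior.  Posterior odds are `p/(1-p)`, with bands:
substantial (≥0.75 or ≤0.25), notable (≥0.667 or ≤0.333), otherwise
uninformed by the data.

Bayesian model averaging pools up to the first 1000 equally weighted
posterior samples per model, each carrying its model's posterior
probability (normalized within the model).  Group comparisons resample
1000 values per group from the weighted distribution, run one-way ANOVA
followed by all-pairs Tukey HSD at a family-wise error rate of 0.01,
repeat for 10 seeded iterations, and call a pair different only on a
strict majority of significant iterations (a 5/10 tie is not different).
Consolidation of a feature scored in several analyses keeps the
posterior closest to the 0.5 prior (ties toward the smaller value) — the
most conservative statement of what the data established.

## The regression demonstration

A response `y = 8 z` (z standard normal) and four unit-variance
predictors `x_i = r_i z + sqrt(1-r_i^2) e_i` with default correlations
(1.0, 0.85, 0.6, 0.0) and n = 100 observations.  All 16 subset
regressions are fit by nested sampling with uniform(0,10) coefficient and
uniform(-10,10) intercept priors under the Gaussian kernel
`ln L = -RSS/(2 var(y))`.  The response amplitude of 8 places the true
x1 coefficient mid-way through the coefficient prior; with a unit-scale
response the per-variable Occam factors would be ~0.01 and every
inclusion posterior would collapse toward zero, which is inconsistent
with the published behavior of the demonstration the priors were designed
for.  The correlation tiers (0.85/0.6) separate the x2/x3/x4 posteriors
beyond sampler noise; both are configurable.

Per variable, the report carries the sum of AICc Akaike weights (SW) over
models containing it (AICc from the best nested-sampling sample, K =
intercept + included coefficients) and the Bayes-MMI hypothesis posterior
at a 0.5 inclusion prior.  The instructive contrast: the posterior for
the uncorrelated x4 falls to ~0.09 while its SW stays ~0.25.

## Synthetic cohorts and problem sizes

Cohort generators draw Dirichlet replicates (`alpha = concentration *
means`) around preset compositions emulating the three study cohorts
(masses over A/A2/Y, over A/N/Y, and dominated by A, with concentration
30 and 20 replicates by default).  The preset means are synthetic
stand-ins chosen only for structure, not published values; no conclusion
in this package depends on them.  Emulated features: compositional rows,
between-sample dispersion, cohort-specific support.  Not emulated:
deconvolution error correlated across subtypes, sample-size imbalance,
batch structure — so green tests here say the *pipeline* recovers truth
under its own generative assumptions, not that the biological inferences
of any particular study are correct.

The recovery experiment uses a 2-subtype fixture (A dividing, dying and
converting to Y; steady state ≈ 65/35) with Dirichlet concentration 200
over 20 replicates, 20 seeded repetitions, 80 live points: the true
topology's evidence must beat a topology that omits the abundant Y, and
the BMA 95% interval for the steady-state A proportion must cover the
truth in at least 90% of repetitions.  The full-scale study (thousands of
models × cohorts at ~10^1-hour fits per model) is out of desk scope by
design; all shipped experiments are sized to minutes.

## Known limitations

* The single-ellipsoid-free random-walk sampler is adequate for the ≤
  10-dimensional, unimodal-ridge problems it ships with; heavily
  multimodal likelihoods would need a multi-chain or clustering backend
  (the operation contract allows swapping one in).
* Evidence uncertainties are the information-based estimate only; no
  bootstrap over runs.
* The enumeration grammar reproduces the published hypothesis-space size
  through one explicit calibration choice (the homogeneous baseline
  model); the underlying per-axis counts are otherwise derived from the
  grammar.
* ANOVA/Tukey on resampled BMA draws inherits the arbitrariness of the
  draw count (1000); verdicts near the significance boundary can flip
  between seeds, which the 10-iteration majority vote only damps.
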