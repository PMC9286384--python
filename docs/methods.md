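# Methods

## The inference problem

A gradable adjective ("tall", "warm") asserts that a degree exceeds a
context-dependent threshold *relative to some comparison class*. When the
class is left implicit — "they're tall", said of a basketball player — the
listener must decide whether the speaker meant *tall for a basketball
player* or *tall for a person*. `compclass` implements a family of
probabilistic models of that decision and a joint Bayesian analysis that
fits them to two kinds of behavioral counts:

* **comparison-class inference**: how often paraphrases of a bare
  adjectival statement name the subordinate category rather than a more
  superordinate one, per item and adjective polarity;
* **adjective endorsement**: how often an adjective with an *explicit*
  superordinate class ("cold relative to other days of the year", of a
  winter day) is judged true.

## Model

Degrees live on a standardized scale, discretized to an evenly spaced
grid (default `[-5, 5]`, 201 points); distributions are probability mass
vectors over the grid. Each item set's superordinate category has the
fixed unit-normal degree prior; each subordinate category `k` has a free
Gaussian prior `P(x|k) = N(mu_k, sigma_k)` (truncated to the grid and
renormalized).

**Literal listener.** The positive form is true iff `x > theta`, the
negative iff `x < theta`, with the threshold `theta` uniform over the
grid; silence is vacuously true. The joint over `(x, theta)` is
proportional to `[[u]](x, theta) * P(x|c) * P(theta)`, normalized once,
and `theta` is marginalized out, giving
`L0(x|u,c) ∝ P(x|c) * P([[u]] true at x)`. Ties `x = theta` satisfy
neither polar form; on a symmetric grid this makes reflection symmetry
exact to machine precision.

**Speaker.** `S1(u|x,c) ∝ exp(alpha * (ln L0(x|u,c) − cost(u)))` over the
three alternatives {positive, negative, silence}. Soft-max is computed in
log space with max subtraction; zero-mass states propagate `-inf` and
yield zero production probability. `alpha = 0` returns the uniform
distribution by convention, so the listener's class posterior reduces
exactly to its prior in that limit.

**Pragmatic listener.** `L1(x,c|u,k) ∝ S1(u|x,c) * P(x|k) * P(c|k)` over
the two-class hypothesis space (subordinate vs. superordinate), with
`P(x|k)` the referent category's own degree prior. A rival
**literal class listener** replaces `S1` with the literal truth
semantics, `∝ [[u]](x,theta) * P(x|c) * P(theta) * P(c|k)`; it predicts
the opposite polarity-by-expectation interaction, which is the model
comparison at the heart of the package.

**Endorsement.** The probability of endorsing `u` given an explicit class
is the expected production probability
`sum_x P(x|k) * S1(u|x, class; alpha2)` with a task-specific optimality
`alpha2`. Because the judged sentence is supplied to the participant, the
endorsement speaker compares the alternatives *cost-free* (see "Utterance
costs" below).

**Comparison-class prior.** Four parameterizations of
`P(c_sub|k) = logistic(b0 + beta1 * r)`, where `r` is the log corpus
frequency ratio of the subordinate to the superordinate NP: `flat`
(exactly 0.5), `basic` (intercepts only), `freq` (slope only) and
`basic_freq` (both). Two intercepts encode the basic-level bias: `beta00`
when the named category is subordinate-level (its pair partner is
basic-level), `beta01` when the named category is itself basic-level
(paired with a true superordinate). The logistic link is this package's
choice — the original analysis does not print its link function — and is
isolated in one module so it can be swapped.

Three-level "imputed" class priors over {subordinate, basic,
superordinate} chain the two intercepts as pairwise log-odds relative to
the basic level: `w_sub = exp(beta00 + beta1*r)`, `w_basic = 1`,
`w_super = exp(-(beta01 + beta1*r))`, jointly normalized. Zero
intercepts give the uniform prior; within each adjacent pair the chaining
reduces to the two-class logistic. Any monotone chaining reproduces the
qualitative level ordering; only this pairwise-consistency property is
relied on.

## Utterance costs and identifiability

The production speaker's default costs are 0.5 for each adjective and 0
for silence. Besides being the natural "speaking costs effort"
assumption, a strictly positive adjective cost is what makes the joint
analysis identified: with zero costs the likelihood is flat along the
transformation `(mu, sigma, alpha) -> (s*mu, s*sigma, alpha/s)`, because
near the grid center the log threshold-CDF is approximately linear in the
degree, so stretching all degree priors is compensated almost exactly by
lowering the speaker optimality. Measured on simulated data, the
log-likelihood changes by under 2 nats across `s ∈ [0.75, 3]` at zero
cost, and MCMC started at the generating parameters drifts to `s ≈ 2`;
with cost 0.5 the same stretch loses hundreds of nats. The cost enters
the utility as `alpha * cost`, which cannot be rescaled away.

The endorsement speaker uses zero costs: endorsement is a truth judgment
of a sentence the task supplies, not a production choice, and a
production cost at `alpha2 ≈ 5` would implausibly depress endorsement of
clearly-true statements (e.g. "cold for a winter day" would fall to
~0.17 instead of ~0.63). Both cost vectors are configurable.

## Bayesian data analysis

One parameter vector serves both tasks: `alpha1` (class-inference
speaker), `alpha2` (endorsement speaker), the class-prior coefficients of
the chosen variant, and `(mu_k, sigma_k)` per subordinate category.
Counts are binomial: subordinate-paraphrase counts against the pragmatic
listener's class marginal, endorsement counts against the endorsement
probability. Priors: `alpha ~ U(0, 20)` (brackets published
speaker-optimality estimates with room), `mu ~ N(0, 2)`,
`sigma ~ U(0.01, 2)`, class coefficients `~ N(0, 3)`. Cells whose model
probability is exactly 0 or 1 against contradicting counts return `-inf`
rather than raising.

**Sampler.** Adaptive block random-walk Metropolis. The likelihood
factorizes over categories given the globals, so one iteration updates
`alpha1` (against the class-inference slice only), `alpha2` (endorsement
slice only), the class-prior coefficients jointly, and then proposes new
`(mu_k, sigma_k)` for *all* categories at once, accepting each category
independently in a single vectorized pass — valid because both the
likelihood and the prior factorize over categories given the globals.
Proposal scales adapt toward 44% (scalar) / 30% (block) acceptance during
burn-in and are frozen afterwards, keeping the post-burn-in chain
Markovian. Chains are initialized from a moderately overdispersed region
of the regime RSA fits occupy (optimalities U(0.3, 6), coefficients and
means N(0, 1), sigmas U(0.3, 1.5)). Default run: 3 chains × 20,000
iterations, 50% burn-in; convergence is monitored by split-R-hat (< 1.1)
rather than visual inspection. Fixed seeds give bit-identical chains.

**Marginal likelihood.** Annealed importance sampling with a geometric
inverse-temperature ladder (`beta = 0`, then geometric from 1e-4 to 1),
block-Metropolis sweeps at fixed scales as the transition kernel, and a
bootstrap SE over the annealing runs. The estimator is validated against
the conjugate Beta(1,1)-Binomial evidence (`ln(1/11)`) through the same
generic machinery. The lightweight default ladder (30 temperatures × 300
runs × 2 sweeps) is adequate for toy problems; for model comparison over
the full parameter space the validation suite uses 100 temperatures ×
200 runs × 3 sweeps, where the bootstrap SE drops to ~1–3 nats — shallow
ladders underestimate the evidence of high-dimensional variants by tens
of nats. Log Bayes factors are differences of log marginal likelihoods,
reported against the full `basic_freq` variant.

**Fit metrics.** `r²` is the squared Pearson correlation between
predicted and observed cell proportions (0 when predictions are
constant; undefined and signaled when the observations are constant);
MSE is the mean squared difference. Following the original presentation,
metrics use the maximum-a-posteriori predictions; posterior means and
95% credible intervals are reported alongside.

## Synthetic data

The generator emulates the study design: item sets of three subordinate
categories at the low/mid/high end of a scale (generating degree-prior
means -1/0/+1, sd 0.5) under one superordinate, crossed with both
adjective polarities, with ~50 responses per cell by default; 90 sets
reproduce the study's 540 unique cells. Log frequency ratios are drawn
`N(-1.5, 1)` (superordinate NPs are typically the more frequent, so the
ratio is usually negative) and the basic-level flag is Bernoulli(0.5) per
set. Generating global parameters mimic fitted values —
`alpha1 = 1.5`, `alpha2 = 5`, `beta00 = -0.1`, `beta01 = 1.6`,
`beta1 = 0.2` — so the synthetic regime is realistic. Counts are drawn
binomially from the package's own forward model, which is exactly the
model the fitting pipeline assumes.

What the generator does **not** emulate: free-text variability (responses
are templated "other <NP>" strings, used only to exercise the coding
rule), the ~15% of real responses naming neither the subordinate nor the
modal superordinate NP (the analysis folds these into "superordinate", and
so does the generator implicitly), item-level idiosyncrasy beyond the
Gaussian degree-prior family, and any model misspecification. Passing
recovery tests therefore demonstrates the pipeline's internal
consistency, not that real behavior follows the model.

The free-response coding rule is implemented as in the original analysis:
a paraphrase codes as *subordinate* iff it contains the subordinate NP as
a substring after lowercasing, whitespace normalization, an optional
user-supplied token synonym map, and stripping one trailing "s" per token
(plural-insensitivity). Full lemmatization and spell correction are out
of scope.

## Known limitations

* **Nuisance-marginalization bias at scale.** Each category's `sigma_k`
  is weakly identified by its four cells (changing `sigma` 0.5 → 0.9
  moves the best-fitting cell probabilities by < 0.01, well under
  binomial noise at 200 responses per cell), so under the flat
  `U(0.01, 2)` prior the `sigma` posteriors inflate toward ~0.9 and drag
  `alpha2` (and occasionally `alpha1`) with them by 3–12%. With `sigma`
  clamped at its generating value the `alpha` posteriors re-center on the
  truth, confirming the effect is marginalization volume, not a sampler
  or likelihood defect. Consequently the marginal 95% intervals for the
  speaker optimalities can undercover at desk scale; the class-prior
  coefficients are unaffected. A hierarchical prior on `sigma` would
  shrink this, at the price of departing from the stated independent
  priors.
* The two-class hypothesis space is an idealization; real paraphrases
  include intermediate and cross-hierarchy classes.
* AIS estimates carry Monte-Carlo error of a few nats at the default
  settings; Bayes-factor *orderings* across variants are stable, small
  differences (< ~3 nats) are not interpretable.
* The literal-listener variant has no `alpha1`; its parameter vector
  simply omits it.
* Degree priors proposed during fitting may extend beyond the grid and
  are truncated/renormalized; the strict constructor for user-facing
  priors enforces ±4 sd coverage instead.

## Problem sizes used in validation

Simulation-based checks run at reduced but regime-faithful sizes chosen
as a deliberate trade-off between statistical resolution and a
single-CPU workflow: parameter recovery uses 20 item sets × 200
responses/cell × 5 seeded replicates at 3 × 20,000 iterations;
model-recovery comparisons use 10 item sets × 100 responses/cell with
AIS at 100 temperatures × 200 samples × 3 sweeps; oracle equivalence
checks 20 random configurations against a 4×-resolution nested-loop
reimplementation.
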