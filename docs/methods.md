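# Methods

This note records the statistical model, the defaults, and the numerical and
design choices behind `trialrescue`, in the order of the pipeline.

## Scope and data model

A trial dataset is a rectangular table of N patient records whose columns
carry a *kind* (continuous, binary, categorical, event-time) and a *role*
(treatment, outcome, event-indicator, stratum, covariate,
recruitment-index). The recruitment index is a unique integer giving the
accrual order; "insufficient accrual" is modeled by deleting the k =
round(r·N) highest-index records (half-up rounding, so e.g. N = 218 at
r = 0.2 leaves 174). Missing values are rejected at read time rather than
imputed: the augmentation contract assumes complete records, and silently
guessing a missingness model would contaminate every downstream metric.
Treatment is binary, with the second declared level treated — a fixed sign
convention for all effect estimates.

## Synthetic trial generator

Because realistic trial datasets are access-restricted, the package ships a
first-class simulator rather than fixtures. It emulates the structure of
two-arm oncology trials: iid stratification factors, independent mixed-type
covariates, and an endpoint from one of three families, with patient i
(accrual order i = 1..n) receiving linear predictor

    eta_i = intercept + sum_j coef_j x_ij + (beta + delta * i/n) * treat_i.

* Arms are assigned by stratified randomization with *exact* per-stratum
  quotas (largest-remainder integerization of p_treat, random positions
  within the stratum). This mirrors stratified block randomization and makes
  quota behavior deterministic and testable, unlike Bernoulli coin flips.
* `delta` implements a *linear* drift of the effect in normalized accrual
  order — the simplest monotone alternative for calibrating the
  recruitment-order interaction test; the true shape of any real drift is
  unknown, and a linear ramp is the conventional first-order alternative.
* Event times are exponential proportional-hazards (rate
  `baseline_rate * exp(eta)`) with independent exponential censoring; this
  is the simplest mechanism compatible with the Cox analysis family.
* Defaults: sd = 1, p_treat = 0.5, baseline_rate = 0.1,
  censoring_rate = 0.02 — an event-rich trial with light censoring, typical
  of the adjuvant-therapy settings the pipeline targets.
* `required_n_per_arm(beta, sd, power, alpha)` is the closed-form two-sample
  normal sizing `ceil(2 sd^2 (z_{1-a/2}+z_pow)^2 / beta^2)`; the simulation
  studies below size trials with it (e.g. 63/arm for beta = 0.5, sd = 1,
  80% power).

What the simulator deliberately does **not** emulate: covariate
correlation, informative censoring, dropout, missingness, multi-arm
designs, or site/cluster effects. Passing tests therefore demonstrate the
pipeline's operating characteristics under a clean randomized design, not
robustness to those complications.

## Generators

All three synthesizers implement one contract: `fit` on a training dataset,
`sample(k, seed)` returning k complete records (never the recruitment
index), deterministic given (training data, config, seed), and never
emitting a categorical level absent from the declared levels. Model-based
generators refuse to train on fewer than `min_train = 50` records — a
deliberate floor, since CART chains and network scores are meaningless at
a few dozen rows — and the refusal is a catchable signal that the
experiment runner records as a failure row.

* **bootstrap** — rows resampled with replacement from training; the
  baseline every generative method must beat.
* **sequential-trees** — visit order defaults to strata, treatment,
  covariates, event indicators, outcomes (conditioning outcomes on design
  variables follows the causal direction of a randomized trial; the
  literature leaves the order open). The first variable keeps its empirical
  marginal; each later variable gets a CART (scikit-learn,
  `min_samples_leaf = 5`, unlimited depth — standard CART-synthesis
  practice, no tuning) on the preceding variables, and sampling routes a
  partially generated record to a leaf and draws uniformly from that leaf's
  training values. No kernel smoothing: donor draws keep generated values
  inside the training support.
* **bayes-net** — continuous variables are quantile-binned into at most
  `n_bins = 10` states (duplicate quantiles merged); structure search is
  greedy hill climbing from the empty graph over add/remove/reverse moves
  on the decomposable BIC score (the score is a declared default — the
  method family names the search, not the score); CPTs are the posterior
  mean under a symmetric Dirichlet(1) prior, so unseen parent
  configurations still have proper distributions; sampling is ancestral,
  and a sampled bin is back-transformed by a uniform draw from the training
  values in that bin. Ten bins balance marginal resolution against CPT
  sparsity at the few-hundred-record training sizes typical after
  reduction.

Event-time endpoints are synthesized as an ordinary (continuous, binary)
pair; no survival-specific generator is attempted.

## Augmentation

Quota cells are the cross of stratum levels and arm (arm-only when
unstratified; a single cell for descriptive schemas). The k missing records
are apportioned across cells proportionally to the *reduced* dataset's
observed frequencies (largest-remainder, deterministic tie-break) — in a
real rescue the reduced data are the only guaranteed reference, though a
design-target reference can be passed instead. Rejection sampling accepts a
candidate iff its cell is unfilled, so the fill matches quotas exactly; if
more than `max_factor = 1000` × k candidates are drawn the fill aborts,
naming the starving cell (this bounds runtime when a generator cannot reach
a required cell). Each of the m replicates gets a fresh fill from a seed
derived deterministically from the master seed, and appended records
continue the recruitment index N−k+1..N.

## Estimation

Each analysis family returns the effect on its natural scale with a Wald
95% CI (`estimate ± z_{0.975}·se`); `significant` is derived from the CI
excluding zero, because all replicability metrics are CI-based. Notable
choices:

* "GEE-style" binary endpoints are served by a binomial GLM with HC0
  sandwich SEs under an independence working model — identical point
  estimates to GEE-independence; cluster identifiers are outside the data
  model, which is a documented limitation.
* Cox ties are handled by Breslow (the lifelines default); the
  survival-probability difference uses hand-computed product-limit
  estimates with Greenwood variances combined in quadrature (the variance
  is not exposed by the fitting libraries).
* Statistical fit failures — separation, non-convergence, zero events,
  degenerate variance — raise a dedicated `FitFailure`, distinct from a
  crash, so experiment runners can count them as failures.

The recruitment-order interaction test fits treatment, normalized accrual
rank (i/n ∈ (0,1]) and their product in the family-appropriate model and
reports the interaction coefficient with its Wald CI. Normalized rank makes
the coefficient directly comparable to the simulator's `delta`. Calibration
under delta = 0 is ~5% rejection; with the effect doubling over the
enrollment window (delta = beta) at n = 2000 power exceeds 50%.

## Combining rules

With replicate estimates q_i and variances v_i = se_i²:
q̄ = mean(q_i), v̄ = mean(v_i), b = Σ(q_i−q̄)²/(m−1), and the adjusted total
variance is the standard partial-synthesis estimator

    T = v̄ + b/m,

with the large-sample 95% CI q̄ ± 1.96√T (normal quantile deliberately;
no small-m degrees-of-freedom correction is applied). m = 10 is the
default replicate count, consistent with current synthetic-data practice.

**Known limitation — under-coverage with improper generators.** T assumes
the synthesis mechanism propagates parameter uncertainty ("proper"
synthesis). Bootstrap resampling does not: v̄ is the analysis variance of
an N-record dataset, while the pooled center q̄ carries the information of
only (1−r)·N real records, and b/m captures only between-replicate
resampling noise. For a mean difference the effective criticality is
z_eff ≈ 1.96·√(T/Var(q̄)), giving ≈90% actual coverage at r = 0.3
(measured 88.6% ± 1.4% over 500 simulated rescues; ≈92–94% at r = 0.1).
This is a property of the estimator under improper synthesis, not an
implementation artifact, and is the main caveat on interpreting the
combined CI at large r.

## Replicability and fidelity metrics

* *Estimate agreement*: augmented point estimate inside the real 95% CI
  (closed interval — ties are measure-zero and closedness makes the rule
  deterministic). Asymmetric by construction: the real CI is the yardstick.
  Under no bias and equal variances the expected rate is
  2Φ(1.96/√2) − 1 ≈ 0.834.
* *Decision agreement*: same significance status **and** same sign — the
  sign condition applies to non-significant pairs too, by the criterion's
  literal definition; not applicable to descriptive analyses.
* *Standardized difference*: Z = (q̄ − q̂_real)/√(se_real² + T), flagged
  consistent with no difference iff |Z| ≤ 1.96.
* *CI overlap*: the symmetric two-way average ½(L/len_real + L/len_aug)
  with L the intersection length. This form was frozen after verifying it
  reproduces published worked cells computed from printed (estimate, SE)
  pairs (0.85, 0.95 and 0.79 exactly at two decimals; one cell prints 0.88
  where the printed-summary recomputation gives 0.887, i.e. one final-digit
  ulp, attributable to the source rounding from unrounded model output).
* *Hellinger fidelity*: per variable,
  H = (1/√2)·‖√p − √q‖₂ ∈ [0,1], computed over declared/observed levels for
  discrete variables and over 10 equal-width bins spanning the pooled range
  for continuous ones (binning is configurable; the granularity is a
  declared default). Implemented in the ‖√p−√q‖ form so identical empirical
  distributions give exactly 0. Distances are averaged over variables and
  over the m replicates, in two views: generated-chunk-vs-training and
  same-size-generated-vs-training.

## Experiment runner

`run_sweep` is a pure function of (dataset, config, seed): per-cell seeds
are derived from the master seed by a stable hash of (generator, r), so no
cell reuses another's stream and reruns are byte-identical. Generator
refusals and fit failures become failure rows; aggregate denominators in
`run_simulation_study` exclude them. Simulation-study problem sizes used in
the shipped tests — 500 replicates for rate estimates, 1000 for the
interaction-calibration check, trials of 126–2000 patients — were chosen to
keep Monte-Carlo standard errors near one percentage point.

## Open design points resolved

* Quota reference: reduced-data proportions by default (design-target
  override available) — the reduced data are what a practitioner actually
  has.
* Rounding of k: half-up, matching published reduced sample sizes.
* Missing values: rejected, not imputed (see above).
* Covariate correlation in the simulator: independent by default; users
  who need correlated covariates can post-process the simulated table
  before analysis.
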