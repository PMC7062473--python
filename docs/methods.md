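# Methods

This note documents the models implemented in `neurochoice`, the
conventions and defaults they rely on, what the synthetic generators do and
do not emulate, and the numerical choices made where the design was open.

## Behavioral choice models

All behavioral fits are unpenalized binomial maximum likelihood (Newton,
convergence tolerance 1e−8 on the log-likelihood, at most 200 iterations)
of the probability of choosing juice B on completed, non-forced, non-error
trials with both offered quantities positive. The quantity-ratio regressor
uses the natural logarithm: the relative value ρ = exp(−a0/a1) is invariant
to the base, while the steepness η = a1 scales with it, so the base is part
of η's definition.

Model catalogue (X is the logit of P(choice B)):

| model | X | derived parameter |
|---|---|---|
| basic | a0 + a1·log(qB/qA) | ρ = exp(−a0/a1), η = a1 |
| side bias | … + a2·(δ_A,right − δ_B,right) | ε = −a2/a1 (>0: rightward bias) |
| choice hysteresis | … + a2·(δ_prev A − δ_prev B) | ξ = −a2/a1 (>0: repeat juice) |
| direction hysteresis | … + a2·(δ_A on prev side − δ_B on prev side) | θ = −a2/a1 (>0: repeat side) |
| stimulation split | every base term duplicated per condition | per-condition ρ, η, ε/ξ/θ |

The stimulation-split design shares no terms across conditions, so the
joint fit is algebraically identical to two independent fits on the OFF and
ON partitions; the test suite asserts this equivalence to 1e−6.

**Predecessor rule for hysteresis.** The "previous trial" is the most
recent *completed* (non-aborted) trial, including forced choices and
forced-choice errors — any trial with a realized chosen juice and side can
seed the history regressors, while aborted trials cannot. The dependent
observation itself must be a completed, non-forced binary choice. Trials
whose predecessor cannot be resolved (e.g. the session's first completed
choice) are dropped from hysteresis fits. Offer repeats triggered by
forced-choice errors are treated as ordinary trials.

**Separation and flagging.** A session where the animal chose the same
juice on every usable trial, a non-convergent Newton run, a
perfect-separation failure, or any coefficient exceeding 50 in magnitude
yields `converged = False` with NaN derived parameters. Flagged sessions
are excluded from cross-session summaries, and the reports log the
exclusion reason rather than silently dropping data.

**Confidence intervals.** The 95% CI for log ρ = −a0/a1 uses the delta
method on the MLE covariance. Over 200 simulated sessions of 300 trials
with ρ ∈ [1.2, 4] and η ∈ [0.6, 2.5], the median absolute error of log ρ̂
is ≈ 0.08 and empirical CI coverage ≈ 93–95% (recomputed in the test
suite).

## Inactivation effects

- SSI = 2(η_ON − η_OFF)/(η_ON + η_OFF); LSI is the same contrast on mean
  licks/trial counted in [1.5, 4.5) s from trial start over all trials of a
  condition. Both indices are bounded in (−2, 2) and antisymmetric in their
  condition arguments.
- The distribution-broadening test is a two-sided F test for equality of
  variance applied to log ρ (the log scale symmetrizes multiplicative
  changes of relative value), with the ON-condition variance in the
  numerator. The steepness test is a two-sided paired t test on
  η_ON − η_OFF. Both achieve their nominal 5% type-I error under the null
  generator (verified at 2000 replicates).
- The SSI–LSI relation is summarized by Pearson correlation. Outliers are
  not removed implicitly: callers pass an explicit exclusion set (a robust
  criterion — beyond 3 × 1.4826·MAD from the median on either axis — is
  provided as `robust_outliers`), and excluded sessions are listed in the
  output.
- The choice deficit is CD = −mean(SSI) per mouse over its stimulation
  sessions; positive CD means the steepness dropped under inactivation.

**Lesion LASSO map.** CD is regressed on per-area infection volumes
(stained-pixel counts; areas measured at two AP coordinates contribute two
columns) with an L1 penalty. Predictors are standardized to zero mean and
unit SD before penalization and coefficients are reported on that scale.
Because the number of areas exceeds the number of mice, no unique
least-squares fit exists; the penalty is chosen by leave-one-out
cross-validation over a 50-point logarithmic path from the critical penalty
(all-zero model) down 3 decades, and the sparsity pattern along the entire
path is returned so the sign of any area's association can be audited at
every penalty rather than trusted at a single point. Constant predictor
columns are dropped with a warning; an identically-zero deficit returns the
all-zero map.

## Neuronal encoding analysis

**Windows.** Five windows: pre-offer (−0.6–0 s re offer onset), post-offer
(0.2–0.8 s), late delay (0.6–1.2 s), pre-juice (−0.6–0 s re juice
delivery), post-juice (0–0.6 s). Firing rate = spike count in the window /
window duration.

**Trial types and responses.** A trial type is an offer type (qA, qB) plus
the spatial configuration and the choice, both expressed relative to the
cell's recording hemisphere (ipsi/contra); Euclidean sides are never used
downstream of this mapping, and the suite verifies that simultaneously
flipping all hemispheres and all trial sides leaves every result unchanged.
Aborted trials and forced-choice errors are excluded; trial types with
fewer than 3 trials are dropped. A neuronal response is one cell × one
window.

**Screening.** Task-relatedness is a 1-way ANOVA over trial types on
per-trial rates at p < 0.001. A 3-way ANOVA (offer type × position of A ×
chosen side, main effects only, type-II sums of squares for robustness to
unbalanced designs) is reported for the summary count tables but does not
gate inclusion. Factors with a single level are skipped with a warning;
identically constant responses yield p = 1 rather than a numerical failure.

**Candidate variables.** Twelve variables per trial type: position of A,
offer value A/B/ipsi/contra, chosen value and its four conditionals
(A/B/ipsi/contra, equal to chosen value when the condition holds and 0
otherwise), chosen juice, chosen side. Values are expressed in units of
juice B through the session's fitted ρ (an offer of qA drops of A is worth
ρ·qA); sessions with a flagged ρ are excluded from encoding analysis. On
forced choices the unoffered juice contributes offer value 0, and position
of A follows A's actual (or, for forced-B trials, implied opposite) spout.

**Regression and selection.** Each task-related response is regressed (OLS
on trial-type mean rates, unweighted) against each variable separately; a
variable *explains* a response when its slope differs from zero at
p < 0.05, and R² is recorded as 0 for non-explaining variables. The
stepwise procedure repeatedly selects the variable with the most best fits
(highest R²) within any single time window, requires its marginal
explanatory power — the percent of task-related responses explained by it
and by no other selected variable — to be ≥ 5%, and removes the responses
it explains; if adding a candidate would push a previously selected
variable below 5%, the candidate is rejected and the procedure stops. The
best-subset procedure exhaustively scores every subset of size d by the
number of pooled responses explained by at least one member. Tie-breaks are
deterministic and documented: best-fit ties go to the smaller slope
p-value then alphabetical; selection ties to the larger total explained
count then alphabetical; tied best subsets are all reported, with the
alphabetically first as the primary pick. By default the pre-offer window
participates in screening and count tables but not in variable selection
(configurable via `RunConfig.include_pre_offer`); reports record which
convention was used.

## Synthetic generators

The generators are exact inverses of the fitted models, so generate-then-fit
is consistent by construction and every pipeline stage can be validated
against known truth.

- **Sessions** are drawn sequentially from the full logistic model
  (ρ, η, ε, ξ, θ), with hysteresis terms conditioned on the realized
  previous completed trial — the same predecessor rule the fitting side
  uses, so the fitted models are correctly specified. Defaults emulate the
  task: 300 trials, a 12-offer menu (qA ≤ 3, qB ≤ 6 drops, four forced
  anchors), 40% forced choices split evenly per juice, pseudo-random sides,
  a 2.8 s offer period, 5% wrong-spout errors on forced choices (with the
  offer repeated on the next trial), 1% aborts, and Poisson lick trains at
  4.3 Hz in the 1.5–4.5 s window. Stimulation trials are interleaved
  Bernoulli(p_stim) with their own (ρ_ON, η_ON) and lick rate.
- **Spike populations**: each cell encodes one variable (or none) linearly,
  rate = max(0, baseline + gain·v). Because the default analysis windows
  overlap in time, per-window independent draws cannot coexist in one spike
  train; spikes are instead drawn from a piecewise-constant-rate Poisson
  process (baseline outside the driven epoch, the tuned rate from 0.2 s
  after offer onset to 0.6 s after juice delivery), which yields exactly the
  intended marginal — the count in every analysis window is Poisson with
  mean rate × duration — from a single consistent train. The reference
  population is 300 cells (60 offer value ipsi, 60 chosen side, 30 position
  of A, 40 chosen value, 110 untuned; hemispheres alternating) at baseline
  4 Hz with gains of 0.8 Hz per unit value and 5 Hz for binary variables.
  These gains produce the few-fold rate modulation characteristic of
  recorded value and binary cells, with single-cell detection near ceiling
  but trial-type means noisy enough that correlated variables do not
  cross-explain every response; at saturating SNR the marginal-power
  criterion degenerates, because every value-correlated regressor becomes
  significant on every value-tuned response.
- **Lesion datasets**: per-area infection volumes are log-normal
  (independent across areas), CD = Σ β_a·z(vol_a) + Gaussian noise.
- **Stimulation parameter sets** provide per-session (η, log ρ) pairs for
  calibration and power studies: under the null the ON draws replicate the
  OFF distribution (η lognormal around 1.19, log ρ normal around log 2.39
  with SD 0.25, 15 sessions per mouse); under the effect η_ON = 0.7·η_OFF
  with lognormal jitter (σ = 0.1) and the log ρ SD is inflated 3-fold.

**What the generators do not emulate.** Rates are stationary within the
driven epoch (no peri-event dynamics), spike counts are Poisson (an
over-dispersion knob is not enabled by default), cells encode at most one
variable with constant gain across windows, lick trains are homogeneous
Poisson confined to the analysis window, and infection volumes are
independent across areas whereas real infections spread to anatomical
neighbors. Passing tests therefore demonstrate the correctness and
calibration of the analysis machinery under its own model assumptions, not
robustness to the mis-specification real data would add (bursting,
history-dependent rates, correlated lesions, drifting motivation).

## Numerical conventions and degenerate inputs

- Zero-variance inputs raise explicit `DegenerateDataError`s rather than
  returning NaN (F test with a constant sample; LSI with no licks in either
  condition); identical paired samples return t = 0, p = 1.
- Separation in logistic fits is flagged, never silently truncated.
- All generators and reports are deterministic given their seeds; encoding
  reports serialize to byte-identical JSON on reruns.
- Problem sizes used by the validation suite — 200 sessions × 300 trials
  for recovery, 2000 replicates for test calibration, a 300-cell population
  on a 400-trial session for selection recovery, 200 datasets for LASSO
  support recovery — were chosen as the smallest sizes at which the
  Monte-Carlo error of each checked quantity is well below its acceptance
  margin.

## Known limitations

- Cross-session summaries are simple means/variances per mouse; no
  mixed-effects pooling.
- The 3-way ANOVA reports main effects only; interactions are not modeled.
- Per-trial (rather than trial-type-mean) encoding regressions are out of
  scope, as is any population-dynamics analysis.
- With 5 mice and 16 predictors the LASSO's selected-penalty solution is
  unstable by nature; conclusions should be read from the reported
  whole-path sparsity pattern, not the point estimate alone.
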