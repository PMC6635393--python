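# Methods

`pulseddm` models choice behavior in a pulsed somatosensory
evidence-accumulation task: on each trial a head-fixed mouse receives two
independent streams of brief air puffs (left and right whiskers) over a cue
period, holds the evidence across a short delay, and licks toward the side
that delivered more puffs. The package provides the task's synthetic-data
generator, a five-parameter accumulator model of the decision process with
two independent likelihood engines, a maximum-likelihood fitting protocol,
a binned-evidence logistic regression of choice, and psychometric summaries.

## The accumulator model

A scalar decision variable `a` starts at 0 at cue onset and evolves in
continuous time as

    da = sigma_a dW + lambda * a dt + (delta(t - t_R) * eta_R - delta(t - t_L) * eta_L)

where right (left) puffs add positive (negative) increments with i.i.d.
amplitudes `eta ~ N(1, sigma_s)`, `dW` is a Wiener process, and `lambda`
exponentially drifts the memory: `lambda < 0` is leak (earlier evidence
counts less), `lambda > 0` instability. At the end of the trial — defined
here as cue period plus delay, the moment the choice is reported — the
response is rightward when `a` exceeds a `bias` threshold, except on a
`lapse` fraction of trials on which the response is a fair coin flip, so
P(right | a > bias) = 1 − lapse/2. The five parameters:

| parameter  | units        | meaning                               | ideal |
|------------|--------------|---------------------------------------|-------|
| `lambda`   | 1/s          | memory leak (<0) or instability (>0)  | 0     |
| `sigma_a2` | units²/s     | diffusion noise of the accumulator    | 0     |
| `sigma_s2` | units²       | per-pulse amplitude variance          | 0     |
| `bias`     | units        | decision-threshold offset             | 0     |
| `lapse`    | probability  | evidence-independent random choices   | 0     |

The memory time constant is reported as `tau = 1/|lambda|` with a
leaky/unstable label, since positive time constants are the field's
convention for leaky integration.

There is no absorbing decision bound and no pulse adaptation: exactly these
five parameters are implemented. That choice has a useful consequence — the
model is linear-Gaussian, so conditional on the puff times the accumulator
at trial end is exactly Gaussian with

    mean = sum_i s_i exp(lambda (T - t_i)),
    var  = sigma_s2 sum_i exp(2 lambda (T - t_i)) + sigma_a2 (exp(2 lambda T) - 1) / (2 lambda)

(`s_i = ±1` by puff side; the diffusion term tends to `sigma_a2 * T` as
`lambda -> 0`).

### Three likelihood routes, cross-checked

1. **Closed form** (`choice_probability_analytic`, `TrialMatrix`): the
   Gaussian expression above, with an analytic gradient in all five
   parameters. This is the default engine for fitting: it is exact and
   vectorizes over trials.
2. **Grid propagation** (`propagate_distribution`): the accumulator
   probability mass on a uniform grid (default spacing 0.02 accumulator
   units, auto-sized extent) propagated in `dt` steps (default 15 ms, the
   simulation step used for all forward simulation). Each inter-event
   interval applies the exact drift factor `exp(lambda * delta)` by
   mass-conserving two-point redistribution and convolves with the exact
   interval noise `N(0, sigma_a2 (exp(2 lambda delta) - 1)/(2 lambda))`;
   each puff convolves with a cell-integrated `N(±1, sigma_s2)` kernel at
   its exact onset time (steps are split at puff times). Mass reaching the
   grid boundary above 1e-8 raises an error rather than truncating
   silently; verified sub-tolerance kernel-tail losses are renormalized so
   the distribution stays proper. Kernels and the drift redistribution are
   built mirror-symmetrically, which makes the left/right mirror identity
   P_right(mirrored trial, −bias) = 1 − P_right exact to machine precision.
3. **Forward simulation** (`simulate_accumulator`): trajectories stepped
   between merged step boundaries and puff times with the exact per-interval
   drift factor and noise variance, so the noise-free path is independent of
   `dt` and single-pulse responses match `exp(lambda * elapsed)` to float
   precision.

The test suite requires routes 1–2 to agree to 2e-3 in choice probability
and routes 2–3 to agree within 3 binomial standard errors at 50,000
simulations per instance. Grid-vs-analytic agreement degrades gracefully
with grid spacing; halving spacing and `dt` moves P(right) by less than
1e-3 on the test battery.

Numerical details: mass exactly at the decision threshold splits 50/50 (the
threshold cell is linearly interpolated), which makes the mirror identity
exact and P(right) continuous in `bias`. Log-probabilities are floored at
the smallest positive double. Simultaneous left and right puffs convolve
sequentially (order-independent).

## Fitting protocol

`fit_ddm` follows a repetition-based protocol: each repetition omits a
random 20% of trials, fits the remainder by L-BFGS in unconstrained
coordinates (`lambda`, `bias` free; variances via `1e-6 + exp(theta)`;
lapse via a logistic map) with the analytic gradient, and is accepted only
if the optimizer converged and the Hessian of the negative log-likelihood
at the optimum is positive semidefinite. Median parameters and 2.5/97.5%
quantiles are taken across accepted repetitions; the held-out 20% provides
the cross-validated choice-prediction accuracy (predict right when
p(R|theta) ≥ 0.5). The study-scale protocol is 1000 repetitions; the
packaged experiments and tests use 50 (5–10 for the multi-replicate
sweeps), which keeps the repetition medians stable at the trial counts
used.

Two implementation choices matter for robustness:

- **Initialization screening.** The likelihood surface has a flat
  coin-flip plateau (lapse → 1, or very large noise variances) that
  captures gradient ascent from roughly half of uniformly drawn starts.
  Each repetition therefore draws 8 candidate initializations uniformly
  from the documented ranges (`lambda` ∈ [−5, 5]/s, variances ∈ [0, 20],
  `bias` ∈ [−3, 3], `lapse` ∈ [0, 1]), ranks them by their starting
  log-likelihood, optimizes from the top 2, and keeps the better converged
  result.
- **Boundary-aware PSD filter.** `hessian_psd_check` computes a
  central-difference Hessian on the natural scale but excludes parameters
  pinned at a constraint boundary (variances at the positivity floor,
  lapse at 0 or 1) and requires the reduced Hessian's smallest eigenvalue
  to be ≥ −1e-6 × the largest. At boundary optima — e.g. data constructed
  by flipping a fraction of ideal choices, where both variances fit to the
  floor — the unconstrained Hessian is legitimately indefinite along the
  constrained directions, and the reduced check is the KKT-appropriate
  condition.

Model comparison uses the score `BIC = ln L − k ln(n)/2`, under which
**larger is better**; this is the opposite sign convention from the
textbook `−2 ln L + k ln n` and is labeled in all outputs.
`relative_bic` reports variant minus full model, positive favoring the
variant. Reduced variants fix `lapse` and/or `bias` at 0.

Identifiability: `lapse`, `sigma_a2`, and `sigma_s2` trade off along a
shallow likelihood ridge at realistic trial counts — a lapse of a few
percent mimics, and is mimicked by, extra accumulator noise on the hardest
trials. At n = 10,000 trials the sampling SD of the fitted lapse is of
order 0.03, so point recoveries of a true lapse of 0.05 occasionally pin
at 0. `lambda` and the leak/instability ordering are much better
determined: datasets generated at tau = 6.7 s vs 0.72 s are separated with
fitted-tau ratios of 7–13 at n = 5,000.

## Synthetic task generator

Defaults are the task's stated statistics: per-side puff trains at a mean
2.5 Hz with a 200-ms minimum inter-puff interval, generated as a renewal
process with intervals `0.2 s + Exponential(mean 0.2 s)` so that both the
mean rate and the refractory gap hold exactly in expectation (the first
interval is drawn the same way from time 0). Cue duration is 3.8 s with
probability 0.85, else 1.5 s; the delay is 0.8 s; sessions run 200–300
trials with light delivered on a random 15–30% (default 20%) under a
configurable schedule of windows (full cue, first/middle/last third of the
cue, delay, and 200/500-ms delay prefixes). Tie trials (#R = #L) are
regenerated, because the rewarded side is undefined for ties. Guided
trials carry a single-sided cue train plus regular 2.5-Hz guide puffs
through the delay and are excluded from all analyses except response-
capability summaries. Decision latencies are synthesized as
0.578 ± 0.222 s (truncated Gaussian) from the end of the delay.

Choices come from either a drift-diffusion agent (per-trial exact path
simulation, or a vectorized shared-grid path for bulk generation, which
matches the per-trial path up to O(dt) puff-timing quantization) or a
psychometric-curve agent. Impairment interventions re-draw choices from
the curve after modifying the evidence: *sensation* gives puffs inside the
light window a configurable weight (default 0.5); *retention* down-weights
puffs strictly before light onset; *action* draws normally and then flips
the choice with probability `min(1, kappa / time from light offset to the
decision lick)` with `kappa` defaulting to 0.4 s (the proportionality
constant is exposed because no canonical value exists); *lapse_flip*
inverts a uniformly random fraction (default 25%) of all choices, which
maps analytically to a fitted lapse of twice the flip fraction. The curve
is evaluated at non-integer effective evidence directly (the 4PL is
continuous).

What the generator does not emulate: trial-to-trial dependence (e.g.
win-stay/lose-shift), session-level drifts in motivation, per-subject
heterogeneity, whisker-motion or lick-kinematic correlates, and the rig's
exact (unpublished) difficulty sampler. Passing tests therefore establish
estimator correctness and the qualitative impairment signatures under the
stated stimulus statistics, not fidelity to any particular animal's
behavior.

## Choice regression

The regression is an intercept-free logistic model of choice on the
per-bin evidence `ln p/(1−p) = Σ_i beta_i E_i`, with `E_i` the #R − #L
count in the i-th of three temporally uniform bins of the 3.8-s cue period
(edges at multiples of 3.8/3 s in full precision; bins are half-open on
the right, so a puff exactly at an interior edge belongs to the later
bin). Only decision-made, non-guided, long-cue trials enter. Uncertainty:
asymptotic SEs with 99% CIs (statsmodels), plus a 100-resample trial
bootstrap; resamples that lose a choice class are skipped, and more than
20% skipped is an error. Predictive accuracy uses stratified 3-fold
cross-validation. Complete separation (near-deterministic synthetic
agents) raises an explicit error; an opt-in ridge flag refits with a small
L2 penalty and reports weights without asymptotic SEs.

For cue-third light conditions, per-condition weights are averaged aligned
to light onset: lag 0 is the light-carrying bin, and each lag averages
only the conditions in which that lag exists (e.g. lag +1 averages the
first- and middle-third conditions). Per-lag bootstrap SDs apply the same
averaging to bootstrap replicates. The shuffle control permutes condition
labels across the light-on trials before the per-condition regressions; a
flat aligned profile indicates the unshuffled structure was real.

Under the half-magnitude interventions the expected weight on an affected
bin is exactly half the unaffected weight (the agent is logit-linear in
the weighted evidence), so the dissociation tests check that the affected
weight falls significantly and is consistent with a 50% drop within
bootstrap uncertainty while the unaffected weights are unchanged — the
retention scenario depresses pre-light weights with the light-bin weight
intact, and the sensation scenario the converse.

## Psychometrics

Performance is the fraction correct over decision-made trials with
Jeffreys binomial intervals (central quantiles of Beta(k+1/2, n−k+1/2);
the interval touches 0 when k = 0 and 1 when k = n). The psychometric
curve is the four-parameter logistic `y(x) = y0 + A/(1 + exp(−(x−x0)/b))`
of right-choice fraction against x = #R − #L, fit by least squares
weighted by per-x trial counts over pooled trials; `b` is bounded below at
1e-3 so step-like (ideal-agent) data fit cleanly. Condition contrasts are
paired two-tailed t-tests on per-subject fractions correct. Guided trials
are excluded from psychometrics and summarized separately.

## Problem sizes in the packaged experiments

The bundled acceptance script and test suite run the full pipeline at desk
scale, the package's chosen experiment sizes: 10,000-trial recovery
datasets with 50 fit repetitions; 5,000-trial datasets for the
leak-regime (10 replicates, 5–10 repetitions each) and BIC (20
replicates) sweeps; 6,000-trial regression scenarios with 100 bootstrap
resamples; 50,000 forward simulations per grid-oracle instance. Recovery
experiments generate long-cue-only sessions so the stated trial counts all
pass the 3.8-s analysis filter.

## Known limitations

- No reaction-time modeling or absorbing-bound first-passage likelihoods;
  the model addresses choices only.
- The lapse/noise ridge described above limits lapse precision at
  realistic n; report the repetition quantiles, not just the median.
- The grid engine is O(grid × steps) per trial and is meant for
  validation and visualization; use the closed form for fitting.
- Per-subject (hierarchical) fits are out of scope; the pipeline pools
  trials ("meta-mouse") and the psychometric branch compares subjects only
  through per-subject performance summaries.
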