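# Methods

## Task structure and sequence generation

A session is a sequence of blocks of visual-search trials over six locations
arranged on a ring (indexed 0–5 clockwise; distances between locations are
minimal circular steps). Within each block the generator realizes the
paradigm's probability structure *exactly*, not in expectation:

- half of the trials have a color-singleton distractor;
- of those, 2/3 place the distractor at the session's high-probability (HP)
  location and the rest are split equally over the five low-probability (LP)
  locations;
- the target appears at every location equally often per block. Because the
  target can never share a location with the distractor, balance requires a
  compensation scheme: on HP-distractor trials targets are spread equally
  over the LP locations, and on exactly half of LP-distractor trials the
  target sits at the HP location.

The remaining LP-distractor trials need a distractor→target assignment that
is a bijection onto the LP locations with no fixed point (a derangement).
Two modes are provided. The *predefined* mode uses a fixed cyclic shift on
the sorted LP locations, constant across blocks and subjects: any fixed
derangement satisfies the count constraints, and the cyclic shift is the
simplest one that is guaranteed to exist for every HP location. The *random*
mode draws a fresh seeded derangement per block. Trial order within a block
is a seeded uniform shuffle of the quota-satisfying trial multiset; the
paradigm constrains counts, not order.

The *changing* schedule moves the HP location every
`change_interval_trials` trials (a whole number of blocks) through a seeded
permutation of all six locations, so each location serves as HP exactly
once. Designs whose quotas are not integral raise a configuration error
naming the violated constraint rather than silently rounding.

Stimulus colors are stored (seeded 50/50 per trial) for dataset realism but
drive nothing downstream; fixation-interval jitter affects no modeled
quantity and is omitted.

## Trial-level GLM and the nine models

Only distractor-present trials are modeled; distractor-absent trials carry
no measurement of suppression. Rows additionally exclude the first trial of
each block (it has no previous-trial label), inaccurate trials, and RTs
below 200 ms. Two choices deserve emphasis because they are easy to get
subtly wrong:

- **Exclusions filter measurements, not experience.** Learning states update
  on every distractor-present trial, including trials excluded from the GLM
  rows. A subject still experiences a distractor on a trial they answer
  incorrectly.
- **Predictions are causal.** The regressor for trial *i* uses state through
  trial *i − 1* only.

The global practice decay is `exp(−b_global (i−1))` over the 1-based index
of *all* distractor-present trials; it equals 1 on the first present trial
and never resets across blocks (the block-reset model variants reset the
per-location learning states only). The accumulator prediction is
`1 − exp(−b_distractor · c_l)` with `c_l` the per-location distractor count;
the delta-rule variant nudges all six per-location predictions toward the
trial's outcome vector with learning rate α, starting from 0.16667 (= 1/6)
per location, and does not update on distractor-absent trials. The
categorical regressor is 1 when the distractor occupies a location of
maximal accumulated count, with ties included — in particular the all-zero
initial state is a full tie, so the first present trial scores 1. The
categorical regressor is parameter-free: the argmax of the counts is
invariant to any monotone transform, so no decay rate is fitted for it
(models 3/6 have five free parameters, models 1/2/4/5 six, models 8/9 four —
models 8/9 drop both the decay regressor and its rate from model 1/4).

Continuous regressors (global decay, graded prediction) are z-scored per
subject over the included rows; dummy and categorical columns stay 0/1. RTs
are modeled in seconds so one prior variance suits all parameters.

The likelihood is Gaussian with the residual SD profiled at its MLE:
σ̂ = √(RSS/n), giving the closed form
`LL = −(n/2)(1 + ln 2π) − n ln σ̂`. The degenerate case RSS = 0 raises
rather than returning an unbounded likelihood.

## Hierarchical fitting and model comparison

Raw (unconstrained) parameters carry the priors: rates are log-transformed,
learning rates logit-transformed, GLM coefficients untransformed, each with
an independent Normal(0, 6.25) prior initially. Per-subject fits are MAP
estimates by multi-start L-BFGS with an analytic gradient (the β-gradient is
standard GLM algebra; each nonlinear parameter enters through exactly one
standardized column whose derivative is available in closed form, the
delta-rule case via a parallel filter recursion). The objective is floored
at −10²⁰. Model evidence is a Laplace approximation at the MAP; a
non-positive-definite Hessian is eigenvalue-floored with a logged warning.

The hierarchical loop alternates:

- **E-step** — per-subject MAP and Laplace evidence for every model under
  the current group priors (warm-started from the previous iteration's MAP;
  prior-draw restarts in the first iteration only, 4 by default, 2 in the
  recovery settings);
- **responsibilities** — softmax over models of evidence plus the Dirichlet
  expected log frequency;
- **M-step** — responsibility-weighted group means and variances (the
  variance update includes the subject-level Laplace variances, floored at
  1e−6 to avoid collapse) and Dirichlet pseudo-counts (prior count 1 per
  model).

Iteration stops when the summed evidence changes by less than 1e−4 or at
`max_iterations` (default 50, matching the recovery procedure's cap; hitting
the cap returns the result with a non-convergence flag — in multi-model
comparisons the frequencies polarize slowly even after the winner is
stable, so the cap is the effective stop there).

Exceedance probabilities are Monte Carlo over the fitted Dirichlet (10⁶
draws by default, 10⁵ in recovery loops); the Bayesian omnibus risk compares
the variational free energy of the fitted frequency model against the
equal-frequency null, `bor = 1/(1 + exp(F1 − F0))`; and
`pxp = xp (1 − bor) + bor/K`. The HBI t-test divides a group mean by its
hierarchical error; the error is reported as √(group variance / N_k) with
N_k the summed responsibility, and the degrees of freedom are treated as
method-supplied — callers pass them explicitly, with N_k − 1 exposed as a
default.

## Synthetic data

The generator emulates the statistical structure the analysis assumes:
subject-level raw parameters are independent Normal draws around a group
mean with a hierarchical spread; RTs on included present trials are the
model's linear prediction plus Gaussian noise (50 ms SD in the low-noise
setting); everything is clipped to the 200–2000 ms response window, so
simulated trials are never excluded by the fast-guess filter. Accuracy
labels are i.i.d. Bernoulli(0.95) by default — real accuracy in this
paradigm runs 94–98% — or copied from a supplied template.
Distractor-absent and excluded trials receive placeholder RTs from the
intercept and decay terms for dataset realism; they never enter fitting.
Simulation builds its design matrix through the same code path as fitting,
including the per-subject z-scoring, so fitting a noise-free simulation
returns the generating coefficients exactly.

What the generator does *not* emulate: sequential RT dependencies beyond the
modeled regressors, non-Gaussian RT skew, lapses, speed–accuracy coupling
(accuracy is independent of the simulated RT), or post-error slowing.
Passing recovery tests therefore show that the estimation machinery inverts
its own generative assumptions at realistic noise levels — not that human
data satisfy those assumptions.

## Reference group parameters

`reference.py` records the published hierarchical group estimates for the
categorical model in the constant-probability experiment: suppression
coefficient −0.040 s, global-decay coefficient 0.092 s, decay rate 0.015 per
present trial, previous-trial coefficient −0.006 s, intercept 0.895 s.
Hierarchical spreads are the half-widths of the reported intervals; the
decay-rate spread is mapped to the log scale as half the log-interval width,
consistent with the rate's raw-space parameterization.

## Recovery experiments

`run_recovery` simulates group datasets from each generating model's group
spec, refits every candidate hierarchically, and scores the winner as the
candidate with the highest exceedance probability (exact ties — possible
only degenerately — go to the lowest model id with a logged warning). The
default study size follows the original analysis scale where feasible: 17
subjects per dataset on fresh constant-probability sequences with
Bernoulli(0.95) accuracy (the original used the observed participants' real
sequences and accuracy labels, which a data-free pipeline cannot), 50 ms
noise, a 50-iteration cap, and ten replicate datasets in the packaged
acceptance study. The residual-matched high-noise condition requires the
original per-participant residual SDs and is out of scope, though
`NoiseSpec("per_subject", ...)` supports it when such SDs are available.

## Numerical and tie-breaking choices

- Quartile binning of RTs by model-derived predictions uses rank-based bins
  with near-equal occupancy (difference ≤ 1 trial); tied prediction values
  are assigned in trial order, earlier trials to lower bins. All-equal
  predictions collapse to one bin with a warning.
- A continuous regressor with zero variance over included rows is left
  centered instead of divided by ~0; the resulting collinearity surfaces as
  a regularized-Hessian warning rather than a crash.
- Design matrices with fewer than (columns + 2) rows raise a degenerate-fit
  error.
- All randomness flows from `numpy` `SeedSequence` spawning — one global
  seed determines sequences, parameter draws, noise, optimizer restarts, and
  Monte Carlo draws; no stage reads wall-clock entropy.

## Known limitations

- The Laplace approximation can misstate evidence for strongly non-Gaussian
  posteriors (e.g. a learning rate pinned near 0 or 1).
- The group posterior is empirical-Bayes rather than fully Bayesian: no
  hyperprior on group variances beyond the floor, so with very few subjects
  group variances can be underestimated.
- Reported degrees of freedom for the HBI t-test are a convention
  (N_k − 1), not derived from the marginal posterior; conclusions should not
  hinge on exact tail probabilities.
- Winner selection uses raw exceedance, not pxp; with high omnibus risk the
  two can disagree.
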