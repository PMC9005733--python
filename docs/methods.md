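# Methods

`jointddm` implements a model-based analysis of two-alternative motion
discrimination in children: a hierarchical Bayesian drift-diffusion model
of choice and response time with explicit group-difference parameters,
joint models coupling drift-rate to a response-locked EEG build-up slope
and to ADHD symptom scores, the EEG component/deconvolution pipeline that
produces the slope, and a seeded synthetic-data generator with known
ground truth for end-to-end validation.

## Behavioural model

Each trial is a Wiener diffusion between absorbing bounds at 0 ("left")
and `a` ("right"), starting at `z`, with drift `v` and within-trial noise
`s = 0.1` (the conventional scaling constant). Response time is
`ter + T`, with `T` the first-passage time and `ter` the non-decision
time. Densities and defective CDFs use the standard small-time /
large-time series with automatic switching; term counts are chosen for an
absolute truncation error at or below 1e-12 on the normalized density, far
inside the 1e-7 requirement. Defective CDFs use the analytically
integrated large-time tail for normalized times above 0.25 and 96-point
Gauss-Legendre integration of the density below that (the cancellation
region of the tail series). Trials without a response by the 2500 ms
deadline are censored and contribute the survivor function at the
deadline; responded trials with RT at or below `ter` make the
log-likelihood `-inf` (the sampler rejects) rather than raising.

Response coding is stimulus coding by default: the upper bound is the
rightward response, the drift sign follows the true stimulus direction,
and `z/a` is a rightward response bias. Accuracy coding is available via
`coding="accuracy"`. Difficulty level 1 is the easy condition, so a
positive `v.diff = v1 - v2` means faster accumulation on easy trials.

### Simulator

`simulate_trials` samples exactly from the analytic distribution: the
bound (or censoring) is drawn from the defective CDF masses at the
deadline, and the conditional hitting time by inverse-CDF lookup on a
1024-point grid with linear interpolation (grid error is far below the
KS tolerances used anywhere). The test suite cross-checks the analytic
densities against an independent Euler-Maruyama simulator with the
Broadie-Glasserman boundary-shift correction.

## Hierarchical model

Five participant-level parameters (`a`, `z/a`, `ter`, `v.diff`,
`v.mean`), each with group-level mean `mu`, spread `sigma` and half group
difference `delta` (autistic group centred at `mu + delta`, comparison
group at `mu - delta`; the group difference is `2 delta`). Priors:

    a_p   ~ N+(mu_a +/- delta_a, sigma_a)         mu_a   ~ N+(0.2, 0.2)
    z_p/a_p ~ TN01(mu_z +/- delta_z, sigma_z)     mu_z   ~ TN01(0.5, 0.2)
    ter_p ~ N+(mu_ter +/- delta_ter, sigma_ter)   mu_ter ~ N+(0.3, 0.3)
    v_p1 - v_p2       ~ N(mu_vd +/- d_vd, s_vd)   mu_vd  ~ N(0, 0.1)
    (v_p1 + v_p2)/2   ~ N(mu_vm +/- d_vm, s_vm)   mu_vm  ~ N(0.3, 0.3)
    sigma_* ~ Gamma(1,1);  delta_* ~ N(0, 0.01)

All second arguments are standard deviations (the convention of the
hierarchical-diffusion literature these priors come from); Gamma(1,1) is
the unit exponential. Truncated-normal participant terms include their
normalizing constants, which depend on the hyperparameters and therefore
matter for sampling.

Covariate partialling: a standardized covariate enters the group-level
mean of every parameter linearly with `beta ~ N(0, 0.5)` per parameter.
The mechanism is a design choice of this package (the "partial out, then
compare delta" logic); it is deliberately simple and is flagged here
because other mechanisms (e.g. residualizing the data) would differ.

The `+/- delta` notation is read literally as one group at `+delta` and
the other at `-delta` (difference `2 delta`).

## Sampler

DE-MCMC: each chain proposes its current value plus
`gamma * (x_r1 - x_r2)` from two other chains plus uniform jitter on
+/-0.001, Metropolis-accepted blockwise. `gamma = 2.38 / sqrt(2 d)` per
block dimension `d`. Blocks are: one `(mu, sigma, delta[, betas])` triple
per model parameter, the joint-model extension blocks, and one 5-vector
block per participant. Per-parameter hyper sub-blocks replaced a single
joint hyper block after the latter mixed far too slowly at 15 chains
(acceptance ~5%, PSRF ~3 on a 16-participant study); low-dimensional
blocks are standard in hierarchical DE-MCMC.

Chains update in two complementary halves ("red-blue"): each half draws
its difference vectors from the other, momentarily fixed half, so a whole
half can be proposed and accepted in one vectorized pass without breaking
the product-target invariance that a fully synchronous update would.
Participant blocks are conditionally independent given the hypers and are
updated in a single batched pass per half.

Migration: at a fixed interval inside an early-iteration window, a random
subset of chains (size uniform on 2..n/2) performs cyclic
Metropolis-accepted swaps, applied blockwise (hyper block and each
participant block). Blockwise swaps rescue individual stuck blocks — the
classic DE-MCMC outlier-chain pathology — much faster than whole-chain
exchanges, which in testing failed to heal a stuck participant block
within a short window.

Initialization draws each chain from the priors, keeping for every
participant block the best of 50 finite-posterior prior draws. Starting
the population near the likelihood ridge keeps DE difference vectors
commensurate with the posterior; first-finite initialization left joint
fits unable to move badly initialized blocks when migration was off.

Default schedule: 15 chains, 4000 iterations, 1500 burn-in, migration
every 14 iterations between iterations 500 and 1100. Joint models
default to 3000 iterations, 1000 burn-in, no migration. Reduced desk-
scale runs in the tests and acceptance script use 1000 iterations, 400
burn-in and a proportionally early migration window (iterations 100-500).

Convergence is summarized by the classic split-free Gelman-Rubin PSRF,
`sqrt(((n-1)/n W + B/n) / W)`.

## Inference

Group differences are tested with Savage-Dickey density ratios:
`BF10 = prior(0) / posterior(0)`, the posterior density at zero estimated
by a Gaussian KDE with Silverman bandwidth (a moment-matched normal
approximation is available as a sensitivity check; the choice of density
estimator at the null is otherwise arbitrary). Results based on fewer
than 10 draws within three bandwidths of the null are flagged
low-confidence. Interpretation bands use boundaries exactly at 3 and 1/3
(moderate evidence for the alternative / null; anything between is
anecdotal).

Model fit is checked with posterior-predictive defective CDFs: for each
posterior draw every participant's trials are re-simulated at the
observed per-cell trial counts, pooled by group x difficulty into
correct/error defective CDFs, and summarized as 2.5/50/97.5 percentile
bands with the observed curves overlaid. Censored mass equals one minus
the terminal defective CDFs by construction.

## Joint models

The EEG joint model replaces the two univariate drift terms with
bivariate normals coupling `(v.diff, EEG.diff)` and `(v.mean, EEG.mean)`,
one correlation per equation, shared across groups or per group.
Additional priors: `mu_EEG.diff ~ N(0, 0.5)`, `mu_EEG.mean ~ N(0, 1)`,
`sigma ~ Gamma(1,1)`, `delta ~ N(0, 0.01)`, `rho ~ U(-1, 1)`. Because
these are unit-scale priors, the slope columns are z-scored on entry by
default (`standardize=False` disables); the correlation is invariant to
this, and without it the sampler must haul `mu_EEG.mean` many prior SDs
from its initialization. Participants without EEG contribute the
univariate (marginal) drift terms, keeping sample sizes comparable to the
behaviour-only fit; listwise exclusion is available by subsetting the
trial table. Covariates (age) are partialled out of both the behavioural
and the EEG group-level means.

The ADHD joint models couple one parameter of interest (`a`, `ter` or
`v.mean`) with one bounded item-average subscale (`inatt` or `hyper`)
through a bivariate normal with per-group correlations;
`mu_subscale ~ N(0.5, 0.2)`. One model is fit per (parameter, subscale)
pair — fitting both subscales in a single posterior would count the
linked parameter's marginal twice. The bivariate normal is untruncated
even when the linked parameter has positive support in the base model;
that mismatch is inherited from the model specification being
implemented, and a support-respecting variant (rejection plus marginal
renormalization, an approximation) is available behind
`respect_support=True`.

## EEG pipeline

Input is cleaned (band-passed, artifact-corrected) continuous data at
250 Hz with an event list. Steps:

1. Response-locked epochs, -600 to +200 ms, for responses between 200 and
   2500 ms after stimulus onset, baselined to the last 100 ms of the
   random-motion period.
2. Reliable Components Analysis on epochs pooled over participants:
   the generalized eigenproblem `C_across w = lambda C_within w`, where
   `C_across` averages cross-trial covariance (trial-unique noise cancels)
   and `C_within` the within-trial covariance. The within matrix gets 1%
   diagonal loading for rank-deficient data. Components are ordered by
   reliability; the explained fraction is the component's share of the
   positive generalized eigenvalue mass. Signs are fixed so the mean
   forward projection over centro-parietal channels is positive, and
   weights are scaled so the forward projection peaks at 1, putting the
   projected series in scalp microvolts at the component's peak channel
   (this makes ramp slopes recoverable in physical units; the convention
   is exact in the rank-1 limit).
3. Deconvolution: a time-expanded design with one predictor per (event
   type x difficulty x lag) over -1000..+1000 ms (500 lags at 250 Hz);
   samples above 250 microvolts absolute are dropped from the system.
   OLS or ridge solutions via the normal equations; the ridge parameter
   is chosen per participant by 5-fold cross-validation over contiguous
   temporal segments on a log grid, then fixed at the mode across
   participants so regularisation differences cannot masquerade as group
   differences. The printed artifact threshold is implemented in
   microvolts (a millivolt threshold would never trigger on cleaned
   data); it is configurable.
4. Slope: OLS fit to the deconvolved response-locked waveform from
   -200 to 0 ms, endpoints inclusive (51 samples at 250 Hz).

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes,
with every quantity seeded and reproducible.

* Behaviour: participants drawn from the hierarchical group
  distributions; trials simulated exactly per the task design (4 x 38
  trials, 2500 ms deadline); optional sub-200 ms contaminant responses
  (uniform on [0, 200) ms) exercise the RT-floor filter — the analysis
  model itself has no contaminant component. Catch trials get twice the
  easy drift and are tagged `catch` (excluded from fitting, which has
  exactly two difficulty drifts).
* Group-level mean defaults sit at the analysis-prior locations (a=0.2,
  z/a=0.5, ter=0.3 s, v.diff=0, v.mean=0.3). Group-level SD defaults
  (0.05, 0.08, 0.05, 0.05, 0.08) are spreads typical of hierarchical
  diffusion studies of children; the Gamma(1,1) prior mean (sigma = 1)
  is a prior, not a population description — it would put most RT mass
  beyond the deadline.
* EEG: per participant, a continuous recording at 250 Hz built from a
  stimulus-locked biphasic transient and a response-locked linear ramp
  projected through fixed smooth topographies, plus spatially white 1/f
  noise band-limited at 0.3 Hz (the generator emulates *cleaned*,
  band-passed data — that is the pipeline's input). The ramp's slope
  over its final 400 ms is `gain * v_difficulty + participant noise`;
  the default gain (60 uV/s per drift unit) and noise (4 uV/s) put the
  simulated slopes on the few-to-tens of uV/s scale of the real measure.
  Setting a target correlation solves the slope noise SD from the sample
  drift spread. Not emulated: raw 500 Hz data, blinks/artifacts, bad
  channels, spatially correlated noise, alpha rhythms — so passing
  pipeline tests demonstrates correctness of the measurement chain, not
  robustness to artifacts.
* ADHD scores: Gaussian copula between the chosen parameter and each
  subscale within group, transformed to the configured group means/SDs
  (defaults: inattentiveness 0.17/0.58, hyperactivity 0.08/0.55 for
  comparison/autistic) and clipped to [0, 1]. Clipping mimics bounded
  item averages and attenuates realized correlations by a few percent at
  the default spreads.

## Problem sizes used in the tests

The full protocol (50 participants/group, 152 trials/task, 4000
iterations) is not needed to validate the machinery; the suites run
reduced configurations chosen for statistical power:

* reduced convergence study: 8 participants/group, 60 trials per
  difficulty, 15 chains, 1000 iterations (400 burn-in), migration every
  14 iterations in iterations 100-500;
* recovery calibration: 20 replicates, 6 participants/group, 24 trials
  per difficulty, truths drawn from the priors (spreads at generator
  defaults), 12 chains x 600 iterations — nominal-coverage check of the
  95% intervals for `mu` and `delta`;
* correlation-ordering sweep: 6 replicates x targets {-0.5, 0, 0.5},
  12 participants/group, 40 trials per difficulty, 12 chains x 800
  iterations with migration; the sweep is paired (same behaviour within
  a replicate), and the ordering of posterior means is the check — these
  short fits are not individually converged to PSRF 1.1;
* EEG pipeline: 50 participants, full 152-trial task, 32 channels,
  default noise.

## Known limitations

* The partialling mechanism and the EEG standardization are documented
  package choices where the analysis description is silent.
* The ADHD joint model's untruncated bivariate normal can place prior
  mass on negative `a`/`ter` (see above).
* The posterior-predictive band reflects parameter and sampling
  variability at the observed trial counts, not model-misspecification
  diagnostics beyond the defective-CDF overlay.
* Migration plus best-of-draws initialization make small joint fits
  converge, but very weakly informed fits (few participants, few trials)
  still mix slowly in the `sigma` hyperparameters; the reported PSRF
  should always be checked.
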