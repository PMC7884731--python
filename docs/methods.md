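# Methods

`evcontrol` implements, end to end, the modelling and analysis pipeline of a
reward x efficacy incentive Stroop paradigm: a normative model of cognitive
control allocation (expected value of control, EVC), a synthetic-study
generator producing behavior, single-trial EEG and continuous pupillometry
with every planted parameter recorded, the corresponding signal
quantification stages, and the hierarchical-regression stage that turns the
signals into incentive effects.  Because all data are generated with known
ground truth, the whole pipeline is verifiable by parameter recovery with no
external data.

## The EVC allocation model

A trial cues a monetary reward `R` (dollars) and an efficacy `E` — the
probability that the outcome is determined by performance rather than a
random draw.  A control intensity `u in [0, 1]` buys criterion success with
probability

    P(u) = logistic(b0 + b1 u - c k),

where `k = 0/1/2` for congruent/neutral/incongruent Stroop targets, at a
quadratic effort cost `cost(u) = a u^2`.  The payoff is the efficacy-weighted
mixture of the contingent and non-contingent reward routes plus an intrinsic
value of accuracy:

    payoff(u) = R [E P(u) + (1 - E) r0] + v P(u),
    EVC(u)    = payoff(u) - cost(u),

and the allocated control `u*` is the argmax of EVC on a 101-point grid over
[0, 1] (ties broken toward smaller `u`: effort is costly; a 10,001-point
brute-force grid guards the discretization in tests).  The functional forms
are the minimal ones reproducing the qualitative behavior of the theory:
payoff increasing in `u` with diminishing returns, flat payoff at zero
efficacy, optimum increasing in both `R` and `E`, and a positive
reward x efficacy interaction in `u*`.

Defaults: `a = 0.5`, `b0 = -1`, `b1 = 4`, `c = 1` per congruency step,
`v = $0.05`, `r0 = 0.7`.  These are declared package constants, not
empirical claims; they produce interior optima across all study conditions
(`u*` = 0.02 / 0.08 / 0.02 / 0.78 for the four Study-2 cells) and, through
the RT gain below, incentive effects of the same order as those reported for
this paradigm (reward ~ -5 ms, efficacy ~ -6 ms, interaction ~ -10 ms).
The intrinsic-accuracy value `v > 0` keeps allocated control above zero when
efficacy is nil, reflecting the residual effort people exert in fully
non-contingent conditions; it can be set to 0.  The non-contingent rate `r0`
is a free parameter rather than being tied to the yoked empirical rate.

## Study designs

Three layouts are generated (per-subject, balanced within block up to
rounding, shuffled under per-subject seed streams):

* Study 1 — 2x2 ($0.10/$1.00 x 0%/100%), 4 blocks x 75 trials, cue 1500 ms
  followed by a 250 ms fixation.
* Study 2 — same cues, 8 blocks x 75 trials, no cue-target fixation, 800 ms
  post-response blank (the EEG/pupil recording geometry; EEG is rendered
  only for this geometry).
* Study 3 — parametric 4x4 ($0.10/$0.20/$0.40/$0.80 x 25/50/75/100%),
  300 trials per subject.

Responses must beat a 750 ms deadline to count toward reward; reaction
times are recorded up to 1000 ms and later responses are missing.

## Behavior generator

Per condition the generator allocates `u*` from the EVC model (congruency is
unknown at cue time, so allocation assumes a neutral target).  Accurate RT:

    RT = beta0_s - g u* + congruency costs + trend * trial_c
         + subject random slopes + neural coupling + eps,

with `g = 15` ms per unit control, congruency costs of 16 ms
(neutral - congruent) and 64 ms (incongruent - neutral), a practice trend of
-10 ms per within-subject SD of trial number, and `eps` zero-mean
shifted-lognormal noise (SD 90 ms, log-sigma 0.4) capturing RT right-skew.
Subject heterogeneity: intercept SD 20 ms; reward/efficacy/interaction slope
SDs 2/2/3 ms.  Accuracy is Bernoulli in the EVC success model's linear
predictor plus a subject accuracy bias (population mean +2.5 log-odds,
SD 0.3) — the same intrinsic accuracy motivation expressed by `v` — plus a
small practice trend; without the bias the EVC defaults would imply
unrealistically low accuracy at low allocated control.  Missing responses
(RT beyond 1000 ms) occur at the rate implied by the noise tail (~0.5-1%)
and count as inaccurate.

Reward outcomes implement the yoking procedure: with probability `E` the
outcome is performance-determined (fast and accurate -> rewarded, 100%
contingency); otherwise the reward is drawn at the rolling mean of the last
10 performance-determined criterion outcomes, pooled across blocks within
subject, with a cold-start probability of 0.5 before any history exists.
Outcomes are drawn at feedback time.  This equates expected reward across
efficacy levels (tested to within 0.02 over 5,400 trials).

## EEG generator and quantification

Amplitude planting and waveform rendering are separate stages.  Planted
single-trial amplitudes (microvolts) follow declared linear models with the
same coded predictors the analysis uses:

* P3b (cue-locked, parietal, 250-550 ms): mean 5, reward 0.7,
  efficacy 0.9, no interaction, trend -1.1 per trial-SD, noise SD 2.
* CNV (cue-locked frontocentral ramp over the final 500 ms pre-target):
  mean -2, reward -0.55, efficacy -0.6, interaction -0.7 (the CNV alone
  integrates the two incentives), a carry-over of 0.16 x the same trial's
  P3b amplitude (signal autocorrelation: a larger positive P3b lifts the
  subsequent window), a -0.05 leak from its own epoch baseline, noise SD 2.
* ERN/CRN (response-locked, FCz, 0-100 ms): accuracy effect +3 (errors more
  negative), reward x efficacy interaction +1.5, noise SD 2.5.
* FRN (feedback-locked, FCz, peak-to-peak): mean 5, reward receipt -0.8,
  receipt x reward -0.8, receipt x efficacy +0.8, noise SD 1, floored at
  0.5 (a peak-to-peak magnitude cannot be negative).

Behavior couples to the standardized *residuals* of the cue-locked
amplitudes (RT: -4 ms per P3b residual SD, +8 ms per CNV residual SD;
accuracy: +0.10 and -0.12 log-odds), so larger-magnitude preparatory
activity predicts better performance trial by trial while the behavioral
condition contrasts stay analytically known.

Rendering paints each amplitude into 512 Hz, six-channel epochs (Fz, FCz,
Cz, Pz, P3, P4) with compact-support temporal kernels and channel weights
normalized against the quantifier's exact sample masks, plus per-trial
baseline offsets (SD 3), 1/f background noise (RMS 8 by default) and a
configured fraction (5%) of injected artifact epochs alternating >150 uV
spikes and >50 uV sample-to-sample jumps.  With noise off, quantification
recovers every planted amplitude to 1e-9 — the geometry (epoch windows
cue -200..1500 ms, stimulus/response/feedback -200..800 ms; baseline
[-200, 0) ms; ROI windows above) is shared between generator and
quantifier, which is what the exactness tests verify.  The planted
topographies are zero outside their own ROI; real scalp fields overlap
components across electrodes, so passing exactness tests says nothing about
source separation on real recordings.

Quantification: per-trial/channel baseline subtraction (returning the
baselines as nuisance covariates), whole-epoch artifact rejection at
+/-150 uV amplitude or 50 uV gradient (absolute successive-sample
difference; the paper-style rule leaves "gradient" undefined, this is the
standard reading), windowed means for P3b/CNV/ERN, and peak-to-peak FRN:
the negative peak in 250-350 ms minus the positive peak in the 100 ms
strictly preceding the detected trough (flat epochs give 0).  Odd/even
split-half reliability is the Pearson correlation of subject-level
half-means.

## Pupillometry

The pupil is modelled as a linear time-invariant system.  Each event
(fixation, cue, target, response, feedback) triggers the Erlang-gamma
impulse response `h(t) = t^n exp(-n t / t_max)` with `n = 10.1`,
`t_max = 1.30 s`, rescaled to unit peak so coefficients are in trace units
(the unnormalized peak is ~t_max^n, which is numerically hostile and
statistically equivalent).  The generator plants a cue response of
1.0 - 0.3 E (larger under low efficacy — arousal tracking outcome
uncertainty, not control), fixed amplitudes for the other events, slow
sinusoidal drift, white noise and Poisson blink gaps, producing one 500 Hz
session trace per subject.

Preprocessing interpolates blinks linearly from 200 ms before onset to
200 ms after offset (the window is configurable; the source description is
ambiguous between this and a +/-200 ms window around onset), downsamples to
20 Hz by non-overlapping block means and z-scores within subject.
Deconvolution builds one regressor per event type — cue events split by
condition — by evaluating unit-peak response trains on the oversampled grid
and decimating them exactly as the data, then solves OLS with an intercept
and optional linear drift term.  Because regressor construction mirrors the
forward model, noise-free round trips are exact to 1e-6 and recovery at
noise SD 0.1 is within +/-0.05.  Per-subject, per-condition cue
coefficients are z-scored within subject and fed to a mixed model on the
incentives; one whole-session GLM per subject is fitted (trial-wise
alternatives exist, but the session GLM is the natural reading of
event-type coefficients).

## Hierarchical regression

All models are two-level single-trial regressions (trials in subjects).
Regressor coding: two-level incentives to +/-0.5 (Study-3 levels centered
and scaled to the same span; the dollar scale is used linearly), congruency
as sliding-difference contrasts whose coefficients estimate the
neutral-congruent and incongruent-neutral differences, trial number
standardized within subject, baselines within-subject centered, ERP
amplitudes used raw (ERP models) and within-subject z-scored
(ERP-to-behavior models).

Gaussian responses use statsmodels `MixedLM` (REML; ML inside
likelihood-ratio comparisons), with the declared random intercept + slope
structure pruned as supported by the data: while the random-effects
covariance is singular (relative smallest singular value below 1e-6, the
package's operationalization of SVD-guided pruning) the slope with the
smallest variance share is removed and the model refitted; the pruning path
is recorded and deterministic.  During development `MixedLM.fit(method=
"lbfgs")` proved unreliable (silent garbage optima); the engine uses the
default optimizer with deterministic fallbacks and treats non-finite
log-likelihoods as failures.

Binomial responses (accuracy, reward receipt) use a conditional
fixed-effects logit with sum-coded subject effects.  The stack has no
frequentist binomial GLMM; the variational alternative was evaluated and
its mean-field posterior SDs are materially too narrow at this scale
(coverage ~85% on data where the conditional logit is verifiably unbiased).
The conditional logit targets the same within-subject estimands, its ML
standard errors are well calibrated, the reported intercept is the mean
subject effect with the between-subject sampling term added to its SE, and
perfectly separated subjects (constant response) are dropped with a
warning.  Two-sided p-values use the large-sample normal approximation
throughout (a Satterthwaite refinement changes nothing of note at ~20k
observations).

Model battery: behavior (accurate RT gaussian; accuracy binomial; both on
reward, efficacy, their interaction, congruency contrasts, trial), ERP
(P3b on incentives + trial + its baseline; CNV additionally on the same
trial's P3b and its own baseline), ERP-to-behavior (both behavioral
responses on incentives + z-scored P3b and CNV + congruency + CNV-epoch
baseline + trial — "baseline" here is the CNV-epoch baseline, the component
the models control most directly), outcome models (ERN on accuracy,
incentives and their interaction; FRN on reward receipt and its
interactions with the incentives), and the pupil cue-coefficient model.
The accurate-RT models condition on correct responses recorded inside the
1000 ms window.

The CNV-vs-P3b slope comparison is a likelihood-ratio test: the full
accurate-RT model against one constraining the two ERP slopes to equal
magnitude after sign alignment (the CNV, a negative-going component, is
negated), both fitted by ML with the same random structure (strict
nesting), chi-square on 1 df.

## Ground-truth bookkeeping

Recovery tests compare fitted coefficients to analytically derived
estimands, not to raw generator inputs, because three mechanisms shift the
estimand away from the planted value:

1. Recording-window truncation: missing responses truncate the RT noise
   (kept-trial means computed from lognormal partial expectations,
   integrating the subject-intercept spread by 21-node Gauss-Hermite
   quadrature) and force accuracy to 0 (observed log-odds are
   `logit(p * P[response])`, which deflates high-accuracy cells
   disproportionately — ignoring this biases incentive effects by ~8%).
2. Sample composition: the accurate-RT models see an accuracy- and
   response-filtered sample, so the projection of the structural
   expectation onto the design uses those trials' inclusion probabilities
   as weights, plus the selection shift induced by the correlated neural
   couplings of RT and accuracy.
3. Variance reallocation: with z-scored ERP regressors in the model, the
   residual couplings and the condition parts of the amplitudes are
   redistributed between the z terms, the incentive terms and the baseline
   covariate; the algebra uses the population within-subject SDs.

All truths are deterministic functions of the configuration and the trial
design; nothing is estimated from simulated outcomes.

## Problem sizes and what the tests show

The statistical-recovery suite runs 20 replicates of the full pipeline at
the main study's size (44 subjects x 600 trials) and asserts sign recovery
of every planted nonzero fixed effect (>= 18/20 each), aggregate 95% CI
coverage >= 0.90 across all planted effects, and the component-specific
interaction pattern (CNV interaction sign-recovered; P3b interaction CI
covering zero in >= 17/20).  Type-I-error calibration uses a null
configuration (constant control policy, all incentive effects zero) at
24 subjects x 300 trials — size is scale-free — with the exact binomial
band for 20 replicates at alpha = 0.05.  The slope-comparison size/power
suites use 16 subjects x 150 trials with symmetric component effects (so
the equality constraint holds exactly under the null) and, for power, a
CNV slope planted at twice the trial noise SD.  Recovery replicates consume
planted amplitudes directly through the same analysis path; waveform
rendering + quantification is itself verified end-to-end (exactness at
1e-9, artifact bookkeeping) at smaller sizes, since rendered epochs at the
full design are several gigabytes per replicate.  Pupil recovery
(deconvolution oracles, sign of the efficacy effect on cue coefficients)
runs at 1-6 subjects with tens of trials.

Passing these tests shows the pipeline is internally correct and
well-calibrated on data satisfying the generator's assumptions —
linear-in-coded-predictor effects, gaussian/lognormal noise, exactly known
event timing, ROI-separated components.  It does not validate the EVC
model against real behavior, nor the quantification against real EEG with
overlapping scalp topographies, ocular artifacts or non-stationary noise.

## Known limitations

* The EVC functional forms are minimal; no learning dynamics, no
  reinforcement-learning account of efficacy estimation.
* Planted scalp topographies are ROI-disjoint by construction.
* The binomial engine reports no shrinkage-based random-effect estimates.
* Blink gaps are benign (linear interpolation suffices by construction);
  real blink artifacts have recovery transients.
* Study-3 parametric truths are pseudo-true projections (the 4x4 surface
  is not saturated by the linear model); recovery suites use Study 2.
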