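# Methods

This package implements, end to end, the statistical workflow of a
visuo-tactile crossmodal congruency experiment on peripersonal space (PPS)
after spinal cord injury: three groups (healthy controls C, complete
paraplegics CP, incomplete paraplegics IP) judge tactile stimuli while
ignoring visual distractors near the feet, before/during/after visuo-motor
manipulations delivered in two sessions (videos showing legs being moved or
still, crossed with actual passive leg motion). The pipeline runs entirely
on synthetic data with known ground truth; this note records the models,
the defaults, and the choices made where the design was open.

## Behavioural measure and preprocessing

Per trial the response is a vocal onset; reaction time (RT) is extracted
from 8000 Hz PCM audio as the first crossing of a short-window RMS envelope
(10 ms causal window) above 5x the file's first-decile RMS, a silence-floor
estimate. The threshold rule and window are configurable; on the bundled
generator (1 kHz burst at amplitude 0.8 over a 0.001 noise floor) onsets
resolve to within a few samples (~0.25 ms).

The exclusion cascade is fixed: (1) participants must exceed 44% accuracy
(strict) over target trials; (2) RTs under 100 ms are removed; (3)
inverse efficiency IE = RT / block proportion correct, computed per
participant x block, with incorrect trials counted in the denominator but
contributing no IE entry; (4) one-pass outlier removal keeping values in
the inclusive range [mean - 2.5 SD, mean + 2.5 SD]. Mean and SD for the cut
are computed once, by default over the whole IE set (`outlier_scope =
"global"`); a per-participant scope is available as a switch. The cut is
deliberately not iterated.

Note one real consequence of the global cut: conditions with a planted
congruency cost have more mass in the upper tail and lose a little more of
it, attenuating recovered effects by roughly 10 ms at the default noise
level. This is inherent to the outlier rule itself, not an artifact of
this implementation.

## The CCE model

The crossmodal congruency effect (CCE) is the incongruent-minus-congruent
IE difference; a unilateral CCE exceeding the bilateral one marks an intact
PPS representation. The analysis response is the CCE per participant x
block x laterality cell (mean IE over that cell's incongruent trials minus
congruent trials). A trial-level response was considered and rejected: the
model's fixed-effect structure (Group, Condition, Laterality and their
interactions) contains no congruency regressor, so congruency-difference
effects are only identifiable once the response itself is the congruency
difference. Aggregating to the block cell also keeps the Gaussian
assumption reasonable (each cell is already a mean over trials).

The full model has all seven fixed terms selectable (Group, Condition,
Laterality, the three 2-way interactions, the 3-way), random slopes for
Laterality, Condition, Laterality x Condition and the standardized block
order, grouped by participant. Participants keep one id across sessions,
so dual-session members pool (70 grouping units on the default cohort).
Block order is standardized to mean 0, SD 1 (population SD) over the
distinct block numbers within participant x session.

Baseline equivalence is tested first on blocks 1 and 8 only (factors
Laterality, Condition = Baseline/Follow-up, and their interaction); blocks
merge into a single "NoStimulation" condition when the interaction Bayes
factor supports the null (BF10 <= 1/3). Post-hoc unilateral-vs-bilateral
contrasts refit the model per group x condition subset, and run only when
a laterality-involving omnibus term reaches BF10 >= 3 — the same reporting
gate the study design uses. Subset refits keep the full random structure
by default (`full_random=False` reduces it to random intercepts).

## The Kuo-Mallick engine

Models are hierarchical GLMs in which every selectable term's design block
X_j enters the linear predictor as g_j X_j b_j, with a single Bernoulli(0.5
by default) indicator g_j per term. Categorical factors use sum-to-zero
contrasts so one indicator gates a whole factor or interaction block. The
Bayes factor for a term is the posterior inclusion odds divided by the
prior odds; an indicator that never flips across all retained draws is
reported as a one-sided bound at the total draw count, flagged, never as
infinity. The Monte Carlo SE of the inclusion probability comes from the
spread of per-chain inclusion frequencies and is propagated to the BF by
the delta method.

Priors: coefficients are Normal(0, tau^2) with tau = `effect_scale` x
sd(y) for gaussian models (unit-information style; default multiplier 1)
and tau = 2.5 logit units for binomial models. Residual and random-effect
SDs carry half-Cauchy priors with scale sd(y), implemented exactly through
the inverse-gamma mixture representation so every variance update stays
conjugate. Gaussian fits are pure Gibbs; all likelihood quantities reduce
to precomputed Gram matrices, so sweep cost is independent of the row
count. Binomial fits use random-walk Metropolis for coefficient blocks and
per-participant random-effect vectors, with proposal scales adapted
(target acceptance 0.3) only during the declared adaptation phase and
frozen afterwards. The gaussian response is centred internally for
numerical conditioning and the offset restored at prediction time.

The default chain layout is the full-scale profile (5 chains x 15000
retained draws, 2000 burn-in, 2000 adaptation); the test-scale profile
(3 x 2000, 500/500) is used throughout the test suite and the default
pipeline profile. Under a fixed seed, draws are bit-reproducible (one
`SeedSequence` spawn per chain).

Estimates are model-averaged: predictions multiply each selectable block
by its indicator draw, so a weakly supported term shrinks its contribution
toward exactly zero. This is the intended behaviour of the
indicator-variable formulation; conditional-on-inclusion summaries can be
obtained from the raw draws if needed.

### Posterior summaries and diagnostics

- **HPDI**: shortest window over the sorted draws spanning
  floor(mass * n) index steps, ties broken at the lowest start.
- **Posterior mode**: argmax of a Gaussian KDE (Scott bandwidth) on a
  512-point grid; degenerate draws return the unique value.
- **R-hat**: the classic Gelman-Rubin factor,
  sqrt(((n-1)/n W + B/n) / W). The convergence flag is `rhat < 1.1`
  (half-open at 1.1); sampling noise can push the statistic marginally
  below 1, which still counts as converged. Random-effect SDs mix slowest
  at test scale and occasionally flag; reports name every flagged
  parameter rather than suppressing them.

## Movement verbal feedback

Feedback accuracies (one 0/1 per participant x video) feed a hierarchical
binomial model with Group, Condition and their interaction selectable and
Condition random slopes by participant. The point hypothesis that
responses are informed rather than guessed is a closed-form Bernoulli
likelihood ratio per group x condition cell, Bin(k; n, 0.85) / Bin(k; n,
0.5). Pairwise condition comparisons are model refits on condition pairs;
no multiplicity adjustment is applied (Bayes factors compare models
directly) and output headers say so.

## Covariation analyses

Physiological (SCL range, ln RSA), interoceptive (BPQ body-awareness
score) and clinical (AIS grade A-E coded 1-5; neurological level C1-S5
coded 1-30) covariates are related to the *unilateral* CCE only. The
response and all covariates are z-scored within the analysis set, so
slopes are on the standardized scale. Fixed terms: Group, Condition, each
covariate and its interactions with Group and Condition (all selectable);
random slopes for Condition and block order by participant. Clinical
covariates restrict to the CP and IP groups and enter additively.
Per-condition slope posteriors (mode, 99% HPDI) are reported only for
covariates whose terms support the alternative, mirroring the reporting
gate used everywhere else.

## Physiological indices

- **SCL range**: 4th-order Butterworth low-pass at 40 Hz ("low band
  filtered at 40 Hz" read as a low-pass cutoff, the only physically
  sensible reading for skin conductance), applied forward-backward with
  Gustafsson initial conditions; a 20 ms guard band at each edge drops the
  residual transient; then max - min within the 2-minute window. The
  filter is skipped with a warning when the sample rate cannot represent
  the cutoff. The index is offset-invariant and scales linearly.
- **Beats**: systolic peak detection with a 0.3 s refractory constraint
  and parabolic sub-sample refinement; inter-beat intervals outside
  0.3-2.0 s are flagged, not interpolated.
- **RSA**: peak-valley per respiratory cycle — cycles segmented at rising
  zero crossings of the mean-removed respiration trace, each cycle with
  >= 2 beats contributing max(IBI) - min(IBI) — and the index is the
  natural log of the *mean* excursion (ln of a mean, not mean of lns; a
  deliberate choice where the wording is ambiguous, switchable in
  principle by computing from the per-cycle excursions). Sampling the
  sinusoidal modulation at ~5 beats per cycle attenuates the recovered
  amplitude by ~6%, well inside the 10% recovery tolerance the tests
  assert.

## Synthetic cohort: what it emulates, and defaults

The generator reproduces the design: 14 participants per group per
session, two sessions, 8 blocks (56 target trials in baseline and
follow-up, 36 in the six video blocks), four balanced laterality x
congruency cells per block, control ("luci") and false-stimulation
("niente") trials at a default 10% rate (their proportion is not stated in
the design; they are excluded from IE cells). Dual-session membership is
9 CP + 5 IP + 0 C, the only allocation consistent with the stated group
totals and the 70 distinct participants.

RTs are log-normal — right-skewed like empirical RTs — with median
`base_rt` = 600 ms and coefficient of variation `rt_sd / base_rt` with
`rt_sd` = 150 ms (typical vocal-RT dispersion); the CCE is an additive
shift on incongruent trials, 100 ms in unilateral "PPS present" cells and
0 elsewhere by default, with the present-cell map following the study's
qualitative finding (C: visuo-motor congruent conditions and rest; CP:
only actual motion; IP: any movement signal). Participant-level unilateral
CCE variability is Normal(0, 20 ms). Error rate 10%; control-trial lapse
rate 5%. Feedback accuracies default to the reported per-cell proportions
(k/42). Latent per-block z-scores couple behaviour to physiology: the SCL
range scales linearly and the RSA amplitude log-linearly in z, and
`EffectSpec.covariate_slopes` plants a CCE-covariate slope (ms per SD) in
chosen conditions.

What the generator does *not* emulate — and hence what green tests do not
establish about real data: speech acoustics beyond a clean tone burst (no
breath noise, no fricatives, no variable onsets), RT autocorrelation and
fatigue drifts beyond the block-order term, heart-rate variability beyond
a single sinusoidal respiratory modulation, electrodermal responses beyond
a smooth drift, missing data, and any systematic group difference in
baseline RT or accuracy.

### Per-trial timing

Inter-trial spacing is not stated in the design; audio rendering uses a
configurable 3 s trial window with the stimulus onset 0.25 s in, and
rejects RTs whose burst would cross the window.

## Calibration and recovery checks (what the suite runs)

The acceptance-style tests run at reduced problem sizes chosen as the
package's fast profile: the conjugate oracle at n = 20 (5 chains x 4000);
BF calibration on 20 + 20 two-factor datasets of n = 200 with a
2-residual-SD interaction; interval coverage over 50 hierarchical
simulations (12 groups x 8); planted-CCE recovery and the qualitative
pattern reproduction on the default cohort (14 per group, full trial
counts) with 2-chain fits. Pattern scoring classifies a cell as
"PPS present" when its gated post-hoc contrast mode exceeds half the
planted amplitude; with per-cell realized-effect SD around 17 ms, a
replicate occasionally draws a cell near 50-65 ms where no detector at
that threshold can honestly call the pattern — the ≥ 80%-of-replicates
bound accommodates this.

## Known limitations

- Kuo-Mallick BFs far from 1 are bounded by the retained draw count and
  carry heavy-tailed Monte Carlo error (the estimator is a ratio of
  inclusion frequencies); bands beyond "very strong" should not be read
  quantitatively.
- Random-effect SD parameters mix slowly at the test-scale chain length;
  their R-hat values are reported and sometimes exceed 1.1 there. The
  full-scale profile resolves this at proportional cost.
- The binomial sampler is random-walk Metropolis; for separated cells
  (perfect accuracy) coefficients are identified mainly by the prior, as
  is inherent to logistic models with separation.
- No artifact correction is applied to physiological traces beyond
  flagging implausible inter-beat intervals.
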