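# Methods

## Task model

A trial presents 15 tokens that leave a central circle one by one, every
200 ms, for one of two lateral circles; the winning circle is the one that
ends with at least 8 tokens. Given `N_L` and `N_R` tokens already placed and
`N_C` in the centre, each remaining token is an independent fair coin, so the
probability that the left choice is ultimately correct is the binomial tail
`Σ_{k=0}^{min(N_C, 7−N_R)} C(N_C, k) / 2^{N_C}`. This is computed with exact
integer binomials and a single final division (error ≪ 1e−12), and is
verified in the tests against exhaustive enumeration of all `2^{N_C}`
completions for every reachable state with `N_C ≤ 12`.

Trial types are defined by constraints on the correct-side success
trajectory and generated as follows:

* **ambiguous** — strict alternation through Jump 10, starting toward the
  correct circle. This is the only orientation consistent with the
  trajectory staying in [0.5, 0.66] up to Jump 10 (the mirrored orientation
  dips below 0.5). The five completion jumps are drawn uniformly from the
  16 tails that leave the correct side with ≥ 8 tokens; the completion rule
  is otherwise unconstrained, and uniformity is our choice.
* **obvious** / **misleading** — rejection sampling of fair 15-flip
  sequences (conditioned on the correct side receiving ≥ 8) against the
  trajectory constraints (> 0.7 after Jump 3 and > 0.8 after Jump 5;
  < 0.4 after Jump 3, respectively), with a 10,000-attempt cap. The
  constraints are printed facts; rejection sampling is the generative
  choice.
* **random** — 15 fair flips; with 15 tokens a majority always exists and
  that side is labelled correct post hoc.

All within-trial times are integer milliseconds with Jump 1 as the zero of
analysis time. The default clock (2,500 ms inter-trial screen, 800 ms
pre-jump delay, 14 × 200 ms jump intervals, 500 ms feedback) closes to the
6,600-ms trial; the baseline TMS pulse precedes tokens onset by 500 ms and
hence Jump 1 by 1,300 ms. The default session composition fixes the
320-trial cross-tabulation of trial type × TMS timing (17/58/56/56
ambiguous, 3/16/15/15 obvious, 6/16/16/16 misleading, 3 unstimulated + 27
baseline random; 291 pulses in total). The per-timing split of obvious and
misleading pulses is not constrained by the design (those MEPs are not
analysed), so they are balanced with remainders to the earliest timing.

## Urgency-gating simulator

At each jump time `t_k = (k−1)·0.2 s` the model evaluates
`y_i = (N_i − N_j)·[a·t_k + b]_+` per side and commits to the first side
with `y_i ≥ T` (T = 1). Evidence changes only at token jumps, so evaluation
is restricted to jump times. Ties (possible only with noise) break
uniformly. Optional zero-mean Gaussian noise enters the evidence term by
default — `y = (ΔN + ε)·[a t + b]_+` — rather than being added after the
gain. The placement matters for the direction of the accuracy effect: in
ambiguous sequences the early leader *is* the correct side by construction,
so post-gain additive noise penalises slow (cautious) agents most, whereas
evidence noise amplified by a high urgency gain makes hasty agents commit on
spurious evidence, which is the phenomenon the synthetic cohort must
emulate. With `noise_sd = 0` the simulator is a pure function of
(trial, parameters). Response time adds a log-normal motor delay with
configurable median (default 250 ms, σ = 0.15) to the commitment time; the
simple-RT distribution is measured, not modelled, in such experiments, and
log-normal with that median is a standard stand-in.

## Behavior quantification

Decision time is RT minus the median simple RT; negative DTs are retained
with a warning. Evidence is summarised as a sum of per-token log-likelihood
ratios with a constant per-token ratio λ (default 1), making SumLogLR equal
to λ times the token-count difference for the chosen side; the per-token
likelihoods themselves are not specified by the task, only this
proportionality, and λ cancels out of between-context contrasts (the
estimator is exactly scale-covariant: multiplying λ by c divides urgency,
slope and intercept by c — a tested invariant). SumLogLR "at DT" uses the
token state after the last jump at or before the DT, i.e. commitment is
taken at the end of the DT.

Urgency estimation sorts a participant × context's responded, positive-DT,
nonzero-evidence trials by DT (stable sort) into 10 consecutive bins, sizes
as equal as possible with remainders allocated to the earliest bins. Per
bin, `U = T / mean SumLogLR` (T = 1); bins with non-positive mean evidence
are excluded with a warning and at least 3 usable bins are required.
Ordinary least squares of U on the bin-mean DT *in seconds* (not bin rank)
gives the slope (1/s) and intercept, keeping the estimate on the same scale
as the simulator's `a` and `b`.

Permutation Pearson correlations permute y across participants with the
add-one correction, `p = (1 + #{|r_perm| ≥ |r_obs|}) / (n_perm + 1)`,
two-sided by |r|. Paired contrasts report the two-tailed paired t and
`d = |t|/√n`.

## MEP pipeline

Amplitude is the peak-to-peak of the channel inside a post-pulse search
window — 10–60 ms for finger muscles, 20–80 ms for leg, configurable; the
window is a conventional choice, not a constraint of the design. Exclusion
statistics are computed per participant × muscle × session in a single pass:
trials whose pre-pulse RMS ([−250, −50] ms) exceeds the group mean + 3 SD,
and MEPs outside mean ± 3 SD. Deliberation analyses keep ambiguous trials
stimulated at Jump 1/4/7 with RT in the closed interval [1,350, 2,800] ms
(responses at least 150 ms after the last pulse and before Jump 15);
participants averaging fewer than 8 retained trials per timing × context are
flagged for exclusion.

RT matching discretizes both contexts' RTs into 200-ms bins anchored at
0 ms (the anchoring is unspecified in such designs; 0 is the simplest
convention), keeps all trials of the smaller side per shared bin plus an
equal-size uniform subsample of the larger side, and drops one-sided bins.
Because the draw is random, the whole selection is repeated (default 100
iterations): per iteration the per-condition median amplitude is computed,
and the final value is the median across iterations. Baseline-timing MEPs
skip RT matching (they precede deliberation). Normalization is per hand
first — each muscle × body-side scaled by its own baseline median — and only
then pooled (averaged) into chosen/unchosen classes, so left/right gain
differences cannot masquerade as side-class effects; baseline itself is
expressed as % of resting-state medians. The pipeline is unit-free:
rescaling all raw amplitudes by any positive constant leaves the
percentages unchanged (tested invariant).

Spatiotemporal maps average normalized excitability across participants on
an 8-slot somatotopic axis (chosen thumb, index, pinky, leg; unchosen leg,
pinky, index, thumb) × 3 timings, then linearly interpolate 100 points
between adjacent timings and 100 between adjacent slots; interpolation is
exact at the nodes, and the difference map is hasty − cautious.

## Vigor

Epochs span [−300, 0) ms before the key press (600 samples at 2,000 Hz);
trials with a pulse in [−400, 0] ms of the press are discarded. The mean of
the first 50 ms is subtracted, the signal rectified, and per
muscle × RT-class × context the pointwise median across epochs is baseline
corrected ([−300, −200] ms) and low-pass filtered (first-order Butterworth,
5 Hz). The filter is applied forward–backward (zero phase) so peak latency
is unbiased — the two-pass application doubles the attenuation relative to a
single pass, which the tests check analytically at 4× the cutoff. Onset is
the first post-baseline sample above the baseline mean + 3 SD; time to peak
is peak time minus onset. RT classes come from a within-participant ×
context median split (ties and the odd middle trial go to the short class),
followed by cross-context RT matching within each class; participants left
with an empty cell are flagged.

## Repeated-measures correlation

`rmcorr_fit` centres x and y within participant — algebraically identical to
projecting out participant-intercept dummies — and correlates the residuals;
the sign is the common slope's. Error degrees of freedom are
`N − k − 1` for N points and k participants; the parametric p uses the t
distribution and the 95% CI the Fisher z transform with standard error
`1/√(df − 1)` (the CI method is a conventional choice; it reproduces the
reference R implementation, and the estimator is verified against both a
dummy-coded OLS oracle and `pingouin.rm_corr` in the tests). The
permutation p shuffles y independently *within* each participant, which
preserves the intercept structure under the null; 1,000 permutations by
default.

The seed suite takes the single-trial Jump-7 table (six finger MEPs per
trial, normalized to baseline), and per RT-matching iteration square-root
transforms the amplitudes (variance stabilisation for right-skewed MEPs)
and computes r and permutation p for the chosen index against each of the
five other representations in both contexts. Medians across iterations are
the reported estimates; significance is Bonferroni-corrected (α = 0.005 for
10 correlations); the between-context contrast per pair is significant when
the 95% CIs do not overlap (CI overlap, rather than a Fisher Z test, is the
default contrast; both views are derivable from the outputs).

## Synthetic cohort and what it does / does not emulate

Agents draw a shared urgency slope `a ~ N(0.6, 0.15)` (floored at 0.05) and
context intercepts `b ~ N(0.45, 0.12)` hasty / `N(0.15, 0.12)` cautious,
floored at 0 — the hasty intercept roughly twice the cautious one, with
evidence noise SD 0.5. These values were chosen once to produce the
qualitative study conditions: a clear SAT shift (faster, less accurate
hasty decisions), urgency intercepts recoverable across agents, and enough
ambiguous-trial RTs inside the 1,350–2,800 ms inclusion window for the MEP
stages.

MEP amplitudes follow a multiplicative model:
`baseline_muscle × timing_gain × context_gain × shared_trial_gain ×
lognormal observation noise (σ = 0.25)`. Defaults: baselines 800/600/500 μV
(index/thumb/pinky) and 200/120/120 μV (leg muscles); timing gains 1.0 at
baseline, 1.05/1.15/1.30 at Jump 1/4/7; hasty-context gains of 1.20 for the
chosen index and 0.85 for chosen thumb/pinky at Jump 7, 1.15 for the chosen
leg at all deliberation timings, and 1.0 everywhere else (the cautious
context and the whole unchosen side are neutral). The shared trial-level
gain is log-normal with σ = 0.25 in the cautious and 0.05 in the hasty
context, producing the cross-muscle coupling difference the rmcorr suite
must detect. Raw EMG is Gaussian background noise (3 μV) carrying one
single-cycle raised-cosine biphasic MEP template per channel (15 ms, onset
20 ms post-pulse for fingers, 30 ms for leg — placeholder physiology,
configurable) scaled to the drawn amplitude, plus a raised-cosine voluntary
burst before the press on the chosen hand (300 μV prime mover, 60 μV
neighbours), context-independent by default. All randomness flows from one
master seed through named sub-streams, so identical configurations
reproduce byte-identical datasets.

What passing tests show: the pipelines recover configured effects of these
forms and sizes at realistic trial counts. What they do not show: real EMG
has 1/f-like spectra, movement artifacts, electrode drift, and MEP
amplitudes whose variability is state-dependent rather than i.i.d.
log-normal; the urgency model is evaluated only at jump times and ignores
sensory-processing lag at commitment. Conclusions about real data need the
real data.

## Problem sizes and numerical choices

Default analysis-driver sizes (12 agents, 100 RT-matching iterations, 1,000
permutations) run in about a minute end to end; the test suite uses smaller
cohorts (8 agents, 10–30 iterations, ≤ 200 permutations), sizes chosen as
the smallest at which the recovered effects sit well clear of their
Monte-Carlo spread (tolerances in the tests are ±3 SD measured across
seeds). Probability arithmetic is exact-integer based; urgency and rmcorr
fits are closed-form least squares (no iterative optimisation anywhere).
Degenerate inputs fail loudly: constant correlation inputs, zero-variance
paired differences, non-positive normalization denominators, missing map
cells, and sub-3-bin urgency fits all raise instead of returning NaN.
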