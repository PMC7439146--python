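# Methods

## Preprocessing

Device exports arrive as minute-level heart rate (bpm) and 15-minute
step totals. The pipeline:

1. **Nonwear screening.** A complete calendar day (midnight to
   midnight) is nonwear when more than 30 minutes of heart rate are
   missing or the daily step total is zero — both signatures of a
   removed device, which reports nothing rather than resting values.
   Partial first/last days are not counted. A participant with more
   than 50% nonwear days is excluded outright. Screening is per-day and
   idempotent.
2. **Downscaling.** Each 15-minute step total U is spread evenly,
   U/15 per minute, preserving the bin total exactly. Downscaled steps
   are therefore real-valued, not integers.
3. **Activity level.** x_ACT = log(steps + 1) per minute. The log
   tames the right skew of step counts and makes a Gaussian emission
   defensible; a Poisson emission on raw counts was deliberately not
   pursued (counts up to ~160/min make it expensive and no better
   behaved).
4. **Residual gaps.** Missing heart-rate minutes that survive day
   screening stay in the series flagged `hr_missing`; the model
   likelihood handles them (below). Nothing is imputed.

## The hidden Markov model

Two states (sleep-like, wake-like), homogeneous transition matrix Γ,
free initial distribution π, and Gaussian emissions per state:
scheme M1 is the bivariate normal with per-state correlation ρ between
heart rate and activity; scheme M2 assumes contemporaneous conditional
independence (ρ ≡ 0); HR-only and activity-only variants observe a
single channel. Free-parameter counts are 13 / 11 / 7 / 7 — per state
the emission parameters (5, 4, or 2), plus two free transition
probabilities and one free initial probability.

**Missing data.** A minute with both channels missing contributes
emission probability 1 in every state (it carries only transition
information); a minute with one channel missing contributes that
state's marginal density of the observed channel — the consistent
likelihood extension of the fully-missing rule.

**Fitting.** Baum–Welch EM with closed-form Gaussian M-steps. Missing
components enter the M-step through their state-conditional expected
sufficient statistics (conditional means/variances given the observed
channel and the state), which keeps every iteration an exact EM step:
the observed-data log likelihood is non-decreasing, and the suite
asserts it on every fit. The forward–backward and Viterbi recursions
are scaled/log-space (numba-compiled) and stable beyond 10^5 minutes.

* Initialization: split minutes at the median activity level (heart
  rate for the HR-only model); state moments from the two halves; Γ
  diagonal 0.95; π = (0.5, 0.5). Additional restarts perturb the
  initial means by up to ±0.5 SD under the run seed; the best restart
  by final log likelihood wins.
* Convergence: relative log-likelihood change < 1e-8 or 500
  iterations (both overridable).
* Guards: variance floor 1e-6, |ρ| ≤ 0.999, probability floor 1e-10
  with renormalization — these bound, but do not remove, genuine ML
  degeneracies (see limitations).
* Label switching: states are reordered after fitting so state 0 has
  the lower mean heart rate (mean activity for the activity-only
  model); downstream labeling is deterministic.

**Selection and diagnostics.** AIC = −2ℓ + 2·df and
BIC = −2ℓ + df·ln(T) over the fits on the same series; the default
choice minimizes AIC, ties go to fewer parameters, and an AIC/BIC
disagreement is logged (BIC wins only on request). Goodness of fit uses
ordinary normal pseudo-residuals, computed per channel:
u = Φ⁻¹(F_t(x)), where F_t is the two-component normal mixture CDF with
state weights P(z_t | all other observations) — the model's conditional
distribution of minute t given the rest of the series. A correct model
gives standard-normal residuals; Kolmogorov–Smirnov summaries are
attached. The residuals are per channel because the bivariate CDF has
no scalar inverse.

**Decoding and scoring.** Viterbi decoding maximizes
P(Z_1..T | X_1..T); exact ties (possible only inside fully-missing
stretches) resolve to the lower state index. The state with higher
µ_HR and µ_ACT is wake; if the channels disagree, activity decides with
a warning (activity separates the states far more sharply in this
domain). Webster rescoring rules 1–5 then run, each as one
left-to-right pass over the sequence as updated by the earlier rules:
after ≥4 / ≥10 / ≥15 minutes of wake, the next 1 / 3 / 4 sleep minutes
become wake; sleep runs ≤6 (≤10) minutes flanked by ≥10 (≥20) wake
minutes become wake. "Surrounded by" is read as both flanks (the
original formulation); `surround="either"` restores the literal
either-side reading. Rescoring never converts wake to sleep, so scored
sleep can only shrink. Total sleep time counts rescored-sleep minutes
inside each night's habitual bedtime window (windows crossing midnight
attach to the bedtime's night); partially covered nights are flagged.

## Longitudinal analyses

Per-day fits segment the series into anchored 24-hour days, by default
08:00–07:59 so a full night's sleep sits inside one day; a day is
classed weekday/weekend by its anchor date. Days incompletely covered
after nonwear removal, or on which EM degenerates (a state occupying
under 30 posterior minutes), are excluded. Day fits can be seeded with
the participant-level parameters to suppress day-level label switching.
For each of the 12 reported parameters (γ wake→sleep, γ sleep→wake, and
per state µ_ACT, σ²_ACT, µ_HR, σ²_HR, ρ — the diagonal transition
entries are redundant with the off-diagonals) a two-tailed
independent-samples t test compares weekday vs weekend daily estimates.
Welch's unequal-variance form is the default (safer for 20-vs-8 group
sizes); pooled variance and Benjamini–Hochberg adjustment are opt-in
switches, the latter because the headline report deliberately shows raw
p-values per parameter. Identical groups report p = 1; a group with
zero variance makes the test not computable and is flagged. Cohort
summaries report the mean (sample SD) of each parameter across
participants.

## The synthetic generator

`sleephmm.synthetic` emulates the study conditions the method targets:
a three-month recording (default 90 days) of an older community-dwelling
adult wearing the device continuously. Defaults are the cohort-level
parameter estimates (wake µ_HR 87.18 bpm, sleep 66.37; γ wake→sleep
0.011/min, sleep→wake 0.017; wake ρ 0.54), with between-participant
variation drawn from the cohort SDs under truncation to valid ranges.
Two presets reproduce the demonstration participants: `high_contrast`
(wake µ_HR 110.21, widely separated states) and `sedentary` (wake µ_HR
80.17, sleep activity essentially zero — the printed "<0.01" values are
taken as 0.005). Heart-rate missingness is injected in geometric runs
(mean 5 minutes, an invented but plausible device-dropout shape) to a
target rate of 0.64% of minutes, matching the observed 0.31–0.96%
range; nonwear days are emulated by zeroing steps and deleting heart
rate.

Generation runs on the model's own scale — states, then
(HR, log-activity) pairs — and is then degraded to device format:
integer bpm, per-minute steps max(0, round(exp(act) − 1)) summed into
15-minute bins. Activity draws below zero are truncated at zero by
default (log-steps cannot be negative). All draws are bit-reproducible
under a seed.

What the generator does **not** emulate: circadian structure. The
homogeneous chain scatters sleep through the 24 hours in bouts of
~1/γ(sleep→wake) minutes instead of one consolidated night, there is no
pre-sleep activity taper, and no time-of-day dependence in either
channel. Passing tests therefore demonstrate statistical correctness of
the machinery under the stated model, not field accuracy on real sleep.

## Validation studies and their problem sizes

* **Parameter recovery** (`validation.parameter_recovery_study`,
  also `scripts/acceptance.py`): 100,000 minutes per seed, 20 seeds,
  5 EM restarts, per preset. This study simulates the *exact*
  bivariate-normal HMM — zero-truncation of activity is switched off —
  because truncation changes the generating family (a point mass at 0)
  and visibly biases γ and ρ recovery beyond Monte-Carlo error; with
  the families matched, medians recover the generating values within
  Monte-Carlo precision.
* **Type-I calibration** (`null_calibration_study`): 100 replicate
  28-day studies (20 weekday, 8 weekend days — a four-week block),
  every day simulated from identical cohort-mean parameters; the pooled
  weekday/weekend rejection rate sits within the 95% binomial interval
  of the nominal 0.05.
* **End-to-end accuracy** (`end_to_end_accuracy_study`): 20 seeds of a
  7-day sedentary-preset recording pushed through the full
  device-format pipeline and compared minute-by-minute against the
  generating states.

## Known limitations

* **Step-bin smearing bounds end-to-end accuracy.** Even downscaling
  spreads a bin's steps over all 15 minutes, so sleep minutes sharing a
  bin with wake minutes inherit substantial activity. Under the
  homogeneous generator (~16 sleep bouts/day) roughly a quarter of
  sleep minutes are affected, and they are scored wake by any
  maximum-likelihood fit — decoding with the *true* generating
  parameters hits the same ~92% ceiling (rescoring lowers it further,
  to a 20-seed median near 0.89). The corresponding accuracy test
  asserts the 95% design goal and currently fails for this structural
  reason; on real data, where sleep is consolidated and pre-sleep
  activity tapers, far fewer minutes sit in mixed bins.
* **Quantization degeneracy.** Device-rounded sleep activity is almost
  entirely exactly zero, so EM drives the sleep-state activity variance
  to the floor; the likelihood gain is genuine (a point mass fits a
  spike), and the floor merely bounds it. Heart-rate parameters and
  transitions are essentially unaffected at the separations studied.
* Downscaled activity is autocorrelated within bins (one draw smeared
  over 15 minutes), which the conditionally independent emission model
  ignores; pseudo-residuals on such data show the mismatch.
* No covariates in Γ or the emissions, no more than two states, and a
  single fixed local time offset (no DST or timezone arithmetic).
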