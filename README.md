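# sleephmm

Unsupervised, personalized sleep/wake scoring from consumer-wearable
heart-rate and step data.

Consumer wrist devices report minute-level heart rate and 15-minute step
totals, but their sleep scoring is proprietary, activity-only, and
one-size-fits-all. `sleephmm` instead learns each wearer's own sleep and
wake physiology from weeks of their unlabelled data — no polysomnography
annotation — and scores every minute of the recording, day and night.
It is aimed at researchers running longitudinal free-living studies
(e.g. sleep monitoring in older adults) who have device exports and
habitual bedtime questionnaires, not ground-truth sleep labels.

## The model

Each minute carries a bivariate observation
**x**<sub>t</sub> = (x<sub>t</sub><sup>HR</sup>, x<sub>t</sub><sup>ACT</sup>),
where x<sup>ACT</sup> = log(steps + 1) after the 15-minute step totals
are evenly downscaled to minutes. A two-state hidden Markov model with
states S = {sleep, wake}, initial distribution π, and transition matrix
Γ (γ<sub>ij</sub> = P(z<sub>t+1</sub> = s<sub>j</sub> | z<sub>t</sub> = s<sub>i</sub>))
links the minutes, with Gaussian emissions per state under two schemes:

* **M1** — bivariate normal with per-state means (µ<sub>HR</sub>, µ<sub>ACT</sub>),
  variances (σ²<sub>HR</sub>, σ²<sub>ACT</sub>) and correlation ρ (13 free parameters);
* **M2** — contemporaneous conditional independence, the product of the
  two univariate normals (11 free parameters);

plus univariate heart-rate-only and activity-only variants (7 each) for
studying what the data fusion adds. Missing minutes stay in the
likelihood: a fully missing minute contributes emission probability 1,
a half-missing minute the observed channel's marginal density.

Fitting is Baum–Welch EM (closed-form M-steps, restarts, monotone log
likelihood), model choice is by AIC/BIC, goodness of fit by ordinary
normal pseudo-residuals, decoding by the Viterbi algorithm. The state
with the higher mean heart rate and activity is wake; decoded labels
pass through the five Webster rescoring rules, which correct the
systematic sleep-overscoring of actigraphy by turning short sleep bouts
adjacent to long wake runs into wake. Per-day refits with weekday vs
weekend Welch t tests expose longitudinal pattern changes.

Because real device studies of this kind are rarely shareable, the
package ships a synthetic generator (`sleephmm.synthetic`) that draws
device-realistic recordings — Markov states, bivariate-normal emissions,
integer bpm, 15-minute step bins, missing heart-rate runs, nonwear days
— from cohort-calibrated defaults, so the whole pipeline is testable end
to end.

## Worked example

Simulate two weeks of a vigorous wearer, preprocess, fit both schemes,
and score:

```sh
sleephmm simulate --preset high_contrast --days 14 --seed 7 --out-dir sim
sleephmm preprocess --hr sim/hr.csv --steps sim/steps.csv \
    --out epochs.csv --nonwear-report nonwear.csv
sleephmm fit --epochs epochs.csv --scheme M1 --seed 1 --out fit_m1.json
sleephmm fit --epochs epochs.csv --scheme M2 --seed 1 --out fit_m2.json
sleephmm score --epochs epochs.csv --fit fit_m1.json --out scored.csv
sleephmm tst --scored scored.csv --bedtime 22:30 --risetime 06:30 --out tst.csv
```

which prints

```
simulated 14 days to sim
wrote 20160 minutes over 14 wear days to epochs.csv
M1: loglik=-90887.4 AIC=181800.8 BIC=181903.7 df=13
M2: loglik=-92053.3 AIC=184128.6 BIC=184215.6 df=11
scored 20160 minutes (4309 sleep) to scored.csv
```

Both criteria prefer M1 — the heart-rate/activity correlation carries
real signal. The fitted M1 parameters (state 0 = sleep, state 1 = wake)
are µ_HR = (74.5, 107.0) bpm, σ²_HR = (158, 323), µ_ACT = (0.35, 3.21),
ρ = (0.01, 0.38), and Γ has per-minute exit probabilities
γ(sleep→wake) = 0.018 and γ(wake→sleep) = 0.006: the wearer's resting
heart rate is ~74 bpm, waking activity is high and strongly coupled to
heart rate, and states persist for hours. `scored.csv` holds the
per-minute labels before and after Webster rescoring, and `tst.csv` the
nightly sleep minutes inside the 22:30–06:30 bedtime window.

The same steps are available as library calls (`fit_hmm`,
`viterbi_decode`, `score_series`, `total_sleep_time`, ...); see
`docs/methods.md` for the model details and design choices.

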