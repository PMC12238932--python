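# Methods

## Task and stimuli

The simulated task is two-interval same/different pitch discrimination on
a steady /ɑ/ vowel. The reference has fo = 239 Hz and lasts 500 ms; the
comparison is identical except for an upward fo shift of Δ cents
(f = 239·2^(Δ/1200)). Both stimuli carry 10-ms raised-cosine onset/offset
ramps (gain 0.5·(1 − cos(πt/10 ms))), interval order is randomized with
probability 0.5, and the silent gap between intervals is 500 ms.

The original experiment used a recorded human vowel pitch-shifted by an
outboard harmonizer. The package instead synthesizes the vowel
deterministically — a harmonic source with −12 dB/octave roll-off shaped
by a fixed formant envelope (F1/F2/F3 = 700/1100/2600 Hz, bandwidths
90/110/170 Hz, harmonics up to 5 kHz) — and produces comparisons by
re-synthesizing at the shifted fo under the same envelope (pitch shift
without formant shift). This keeps the pipeline free of audio assets;
`read_wav` lets users substitute a recording. Audio is interchanged as
16-bit PCM WAV at 44.1 kHz. The bundled fo estimator (FFT autocorrelation
with parabolic peak interpolation) is used only to verify synthesized
stimuli; it is accurate to well under 0.1 Hz on steady harmonic signals.
Shifts are applied upward only; whether the original procedure ever
shifted downward is undocumented, and a one-sided choice keeps "different"
well-defined at every level.

## Staircase

Transformed up-down, 2-down/1-up: the shift starts at +60 cents and moves
in 4-cent steps, down after two consecutive correct ("different")
responses, up after one incorrect ("same"). The track stops at 10
reversals or 60 adaptive trials; the threshold is the arithmetic mean of
the shift levels at the last four reversals. Sessions ending with fewer
than four reversals are flagged unusable and carried as missing values —
never dropped silently.

Bookkeeping choices the procedure description leaves open, fixed here and
configurable through `StaircaseConfig`:

* A reversal is a direction change between successive *realized* shift
  adjustments; the initial descent is not a reversal. The level recorded
  at a reversal is the one presented on the trial whose adjustment changed
  direction.
* The consecutive-correct counter resets after every realized step and
  after any incorrect response (standard 2-down/1-up semantics).
* The 60-trial cap counts adaptive trials only; catch trials are drawn
  independently per trial (Bernoulli 0.2) and are invisible to the track.
* The shift is floored at one step (4 cents), so every adaptive trial
  contains a physical difference; there is no ceiling — runaway tracks end
  at the trial cap and are retained.

## Observer model and calibration

Same/different responses follow a differencing rule with a fixed
criterion: internal difference D ~ N(Δ, σ) cents, respond "different" iff
|D| > c, with lapse rate λ mixing toward chance. The psychometric function
is

    p(Δ) = (1 − λ)·[1 − Φ((c − Δ)/σ) + Φ((−c − Δ)/σ)] + λ/2,

strictly increasing in Δ for λ < 0.5. This is the simplest observer whose
false-alarm rate (catch-trial accuracy) and staircase behavior can be
controlled independently — both are observable quantities in the reference
experiment.

Calibration maps a nominal JND J and a catch-accuracy target A to (σ, c).
The Δ = 0 constraint p(0) = 1 − A fixes the ratio r = c/σ in closed form,
r = Φ⁻¹(1 − b₀/2) with b₀ the lapse-corrected false-alarm rate; the
constraint p(J) = 2^(−1/2) (the 2-down/1-up convergence point) is then a
monotone one-dimensional equation in σ, solved by bracketed Brent
iteration to residuals below 1e−10. Defaults: λ = 0.02, catch-accuracy
targets 0.94 for controls and 0.95 for the HVD group (the published group
averages). Calibration fails loudly when the targets are incompatible
(e.g. λ/2 alone exceeds the permitted false-alarm rate).

Validated behavior: for observers calibrated at J ∈ {15, 25, 45} cents,
the mean estimated threshold over 500 sessions lies within 2 cents of J.
The estimator carries a small (< 1 cent) upward bias from the 4-cent floor
and the finite step size, which the tests' tolerances absorb.

## Synthetic cohorts

Four cells with the published composition:

| cell | n | male | age (yr) | threshold moments (cents) |
|---|---|---|---|---|
| control non-singers | 17 | 5 | 39 ± 15 | 25.5 ± 15.7 |
| control singers | 43 | 5 | 23 ± 5 | 18.9 ± 7.5 |
| HVD non-singers | 17 | 5 | 39 ± 13 | 45.1 ± 24.4 |
| HVD singers | 43 | 5 | 26 ± 10 | 25.0 ± 12.8 |

Each participant's true JND is drawn from a shifted gamma: 2 cents plus a
gamma whose shape/scale are moment-matched so the cell mean and SD are
exact. The gamma choice supplies positive support and right skew — the
realistic shape for individual acuity — but the true distributional form
is unknown; only the first two moments are constrained by the published
statistics. Ages are normal truncated at 18 (adult cohort, rejection
sampling); sex labels are assigned to match the per-cell male counts
exactly. Age has no generative effect on JND — the reference analysis
found none — but `age_slope_cents_per_yr` exposes a slope for power
exploration (default 0).

`generate_study` calibrates one observer per participant and runs a full
session, producing a participant table (CSV-exportable). What the
generator does **not** emulate: criterion drift, interval-order bias,
learning across the session, hearing-threshold variation, or any
dependence of acuity on voice quality. Passing tests therefore validate
the measurement procedure and analysis under an idealized stationary
listener, not the human response process.

## Statistics

* Cell summaries: mean, SD (n−1), 95% CI via Student t quantiles; missing
  (flagged) thresholds are excluded listwise with an audit count.
* ANCOVA: threshold ~ group × singer status + age, fit by OLS with
  sum-to-zero factor coding and Type III sums of squares — the convention
  for unbalanced designs (17 vs 43 per stratum) reporting main effects
  alongside an interaction. Residual df is N − 5 (115 for a complete
  120-participant study). Partial η² = F·df1/(F·df1 + df2).
* Pairwise follow-ups: pooled-variance two-sided t tests of control vs.
  HVD within each stratum, df = n₁ + n₂ − 2, Bonferroni m = 2, Cohen's
  d = Δmean / pooled SD. The published pairwise df (58 in both strata) and
  d values (0.59 non-singers, 0.98 singers) are inconsistent with the
  published cell ns/means/SDs (which give df 32/84 and d ≈ 0.96/0.58,
  apparently transposed); this package computes df and d from the data by
  the formulas above and does not treat those published values as
  reference points.

The type-I error of the group term is verified by simulation (1,000 null
cohorts: rejection rate within 3 binomial SE of α = 0.05), and the Type
III machinery is checked against an independent full-versus-reduced
least-squares oracle to 1e−8.

## Reproducibility and problem sizes

All randomness flows from a master integer seed through named
`SeedSequence` substreams (per cell, per participant, and per session,
with separate streams for trial-kind draws and observer responses), so a
configuration plus seed reproduces every output byte. The acceptance
script uses 200 sessions for the catch-trial aggregate and 100 replicate
cohorts per cell for parameter recovery — sizes at which the Monte-Carlo
error of each reported mean is well under the comparison tolerances while
the whole script completes in seconds. The test suite uses 500 sessions
per convergence check and 1,000 response sequences for the staircase
replay oracle.

## Known limitations

* The observer is stationary; real listeners lapse non-uniformly, drift,
  and learn. Recovery results quantify procedure bias, not human bias.
* The vowel is fully deterministic (no jitter, shimmer, or aspiration
  noise); fo estimation on it is easier than on natural voice.
* The gamma JND distribution is a modeling choice constrained only by two
  moments; tail behavior (and hence the rate of flagged or runaway
  sessions) is not pinned down by the published statistics.
* Published F statistics and raw-data quantities (per-subject ages and
  thresholds) cannot be reproduced exactly without the restricted data;
  the pipeline reproduces derived quantities and recovers generative
  parameters instead.
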