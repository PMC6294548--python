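# Methods

This note documents the generative model behind `meploop`, the procedures
the engine and pipelines implement, how the defaults were calibrated, and
what the synthetic experiments do and do not establish about real data.

## The paradigm being simulated

A participant sits at rest while single TMS pulses over the motor hotspot
evoke MEPs in the first dorsal interosseous (FDI). Each closed-loop trial
runs: EMG gate → fixation → pulse → immediate amplitude feedback → reward.
On UP days the reward is delivered when the MEP peak-to-peak amplitude
strictly exceeds the criterion; on DOWN days when it stays strictly below
(exact equality is never rewarded). The criterion starts at the session's
20-trial resting baseline mean and an adaptive staircase multiplies it by
1.10 (UP; 0.90 DOWN) after a block with > 70 % success and by 1.20 (0.80)
after > 90 %, compounding across the four 30-trial blocks of a day; no
downward adjustment is made on poor performance, and the staircase is
memoryless. Control-group participants receive the same display but the
rewards follow the fixed cyclic triple (reward, reward, no-reward) — 66 %
within rounding — independent of the MEPs.

## The generative participant

### Corticomotor excitability and MEPs

MEP generation follows a logistic recruitment curve,

    MEP_mean(I) = MEPmax / (1 + exp(-k (I * e - I50))),

where `I` is stimulator intensity (% of maximal output), `e` the latent
excitability multiplier (1.0 at rest), and a unit-mean log-normal factor
with coefficient of variation `mep_noise_cv` (default 0.25) multiplies
every draw. Excitability acts on the *effective intensity*, so trained
up-regulation saturates at the recruitment plateau rather than growing
without bound. A small additive zero-mean excitability jitter
(`exc_jitter_sd`, default 0.015) makes single trials fluctuate coherently
with the EEG (below).

Defaults: RMT 43 %MSO (cohorts draw N(43, 4)), MEPmax 4 mV (log-normal
between-subject spread), I50 = 1.3 × RMT so the half-maximum test intensity
lands at the conventional 130 % RMT, and `k` derived so that the *median*
MEP at RMT is exactly 50 µV — which makes the 5-of-10 threshold rule land
on RMT by construction.

### Operant learning

Skill in the active direction grows by `learn_rate` (default 0.01) on every
veridically rewarded trial, capped at 1; sham rewards teach nothing.
Expected excitability is `1 + skill_up * (up_asymptote - 1)` under UP,
`1 - skill_down * (1 - down_asymptote)` under DOWN, and exactly 1 at REST.
With the default reward rates the skill caps midway through the second
training day of a condition, so the final-session blocks express the full
trained gain. The linear operant rule is a stand-in: the source paradigm
describes learning only qualitatively, and `learn_rate` is a calibration
knob, not a claim about human learning rates.

The asymptotes are not free parameters. Each participant carries latent
trained gains (`latent_up_pct`, `latent_down_pct`): once calibration has
chosen the test intensity, the asymptotes are re-anchored so that full
skill moves the expected MEP by exactly those percentages of the subject's
own baseline *at the tested intensity* (capped at 99.5 % of the recruitment
plateau). Anchoring at the measured test intensity reflects how operant
learning works — the modulation is shaped against the feedback signal
actually used — and it removes an otherwise dominant noise source: the
half-max intensity is estimated from only 60 pulses, and the %-change from
baseline is extremely sensitive (about −25 points per %MSO) to where that
estimate lands on the sigmoid.

`latent_up_pct = 86.9` and `latent_down_pct = 33.0` were calibrated once so
that the *measured, cleaned* group changes of a default experimental cohort
reproduce the published +83.8 % / −30.6 %. They sit slightly above those
targets because per-block trimming, the exclusion cascade and plateau
saturation in subjects whose test intensity lands above the true half-max
shave a few percent off the measured group change.

### Background EMG and the gate

Resting EMG is zero-mean Gaussian noise at 2000 Hz with per-muscle RMS
4 µV; "tense" episodes multiply chosen channels so the 100 ms RMS exceeds
the 7 µV gate. The gate passes at the first instant all four trailing
100 ms RMS values have been below 7 µV continuously for 500 ms (the monitor
is live from the first sample, with an expanding window). During fixation
the same monitor re-arms; with default settings a tension episode occurs on
5 % of trials and extends the trial. Because relaxed 4 µV noise essentially
never crosses 7 µV, the fixation monitor is simulated explicitly only when
a tension episode is scheduled — statistically equivalent and much cheaper.

### EEG epochs

Each 1.5 s pre-pulse epoch (1000 Hz) is synthesised in the spectral domain:
a 1/f background (PSD ∝ 1/f, amplitude scale `bg_amp`) plus one narrowband
Gaussian process per published band (Gaussian spectral bump at `osc_freqs`
with width `osc_bw`), then an inverse FFT. Per epoch, each band's log
amplitude is

    log A_b = log A0_b + side * shift_b / 2 + u * link_b + eps_b,

with `side` +1 (UP) / −1 (DOWN) / 0 (REST), `u` the trial's shared latent
fluctuation (the same draw that jitters excitability, so band power
predicts single-trial MEP amplitude; `band_link_scale = 0.25` with signs
following `band_d`), and `eps_b ~ N(0, epoch_log_amp_sd)` per band
(default 0.40). The subject's state shift per band, `shift_b`, is drawn
once at construction from N(`band_mu`, `band_tau`²). Non-hotspot channels
carry the shift attenuated by `eeg_attenuation = 0.4`.

`band_d` is the *target* cohort-level paired effect size on relative band
power (+0.754 delta, −0.947 theta, −0.805 low alpha, −0.714 high alpha, 0
for both betas, +0.753 low gamma, +0.712 high gamma). Relative power is
zero-sum across the analysed spectrum: a drop in alpha mechanically
inflates every other band's share, and bands with no effect of their own
would inherit a strongly correlated pseudo-effect from the big
theta/alpha/gamma shifts. The amplitude-domain means (`band_mu`) and
between-subject spreads (`band_tau`) therefore differ from the nominal
targets; they were calibrated by iterating the generator against its own
spectral pipeline (per-cohort n = 14 paired d, averaged over replicate
cohorts) until every band recovered its target within about ±0.17 — inside
the ±0.25 acceptance band. Users who set a custom `band_d` get the identity
mapping (`band_mu = 0.32 * band_d`, `band_tau = 0.32`), which is exact for
the null case `band_d = 0, band_tau = 0`.

`epoch_log_amp_sd` sets single-trial discriminability and was calibrated
last, so that the 9-feature hotspot linear SVM averages 81.5 % 10-fold CV
accuracy over 14 default subjects (measured 81–82 % across replicate
cohorts; the permutation null sits at 50 % without calibration).

### Paired pulses

SICI and LICI scale the single-pulse mean by a logistic, monotone-in-CS
inhibition map anchored so the conditioned/test ratio equals 50 % at the
reference CS (75 %RMT for SICI, 110 %RMT for LICI) and saturating at
`pp_floor = 0.15`; the maps are state-independent. LCD multiplies the
single-pulse mean by `1 + gain`, with gain `skill_up * 50.9 %` in the UP
state, `skill_down * (−5.2 %)` in DOWN (the small negative DOWN default
mirrors the published non-significant DOWN-vs-baseline difference and makes
both published LCD mean differences, +50.9 and +56.1 points, generator
defaults) and 0 at rest.

## Procedures and numerical choices

* **Recruitment-curve fit.** 6 pulses at 10 intensities (90–190 % RMT, no
  170 %) in randomised order. The plateau and half-max point are read off a
  logistic fitted to the *log amplitudes of all 60 pulses* — equal-weight
  log-space least squares is the natural estimator under multiplicative
  noise and roughly halves the error of a fit to the per-intensity means.
  The raw maximum of per-intensity means is recorded alongside; a warning
  flags curves still rising steeply at the top intensity. If the fit fails,
  linear interpolation of the means to half the maximum is used.
* **Trial measurement.** The pre-pulse and post-pulse segments are filtered
  separately (30–800 Hz, 4th-order zero-phase Butterworth) so the MEP
  cannot smear into the background window; the post segment starts 5 ms
  after the pulse, excluding the stimulus artifact by construction.
  Background RMS uses 110–10 ms pre-pulse; peak-to-peak uses 20–45 ms
  post-pulse (conventional FDI latency window).
* **Cleaning order.** Per-block min/max trimming first (ties: first
  occurrence; blocks under 3 trials skipped with a warning), then the
  cascade on the post-trim pool: absolute background > 0.01 mV; background
  > subject mean + 2.5 SD over all of the subject's trials; amplitude >
  Q3 + 1.5 IQR with quartiles by linear interpolation of order statistics.
  Each excluded trial carries the first failing rule. The amplitude rule
  judges outliers against condition-matched pools (trial type × condition)
  by default, so rejection rates do not depend on feedback type — matching
  the source study's reported rejection diagnostics; `iqr_pool="subject"`
  switches to the pooled variant. Re-running the cascade on retained trials
  excludes nothing new under the absolute rule; the statistical rules are
  defined on the original pool and are not recomputed.
* **Spectra.** Welch with 1.0 s Hann segments and 50 % overlap gives 1 Hz
  bins from the 1.5 s epoch. The nominal delta band starts at 0.1 Hz, but a
  1.5 s epoch cannot resolve below ~1 Hz, so delta is computed over 1–4 Hz.
  Band edges are inclusive integer bins; the eight bands exactly tile
  1–80 Hz. Relative power expresses each bin as a percentage of the total
  spectrum power from 1 Hz to Nyquist, so the band shares sum to *less*
  than 100 % and the broadband tail keeps the eight compositional
  predictors identifiable in the trial-wise regression (an intercept plus
  eight shares that summed exactly to 100 would be perfectly collinear).
  The "1/f transform" multiplies each bin's relative power by its frequency
  (exponent configurable) — a declared convention, one of several the
  phrase admits.
* **Classification.** Stratified 10-fold CV, linear SVM with C = 1,
  features z-scored inside training folds only. Stratification and the
  z-scoring are our choices (the source protocol states only "10-fold");
  both are toggleable. RFE removes one feature per refit on globally
  z-scored data; constant features z-score to zero weight and rank last;
  ties break by column order. The permutation p is rank-based,
  (1 + #{null ≥ true}) / (n_perm + 1).
* **Trend null test.** The control-group check fits a least-squares slope
  of UP−DOWN modulation on block position per subject and applies an exact
  sign test of the slopes against a zero median — a conservative,
  distribution-free trend test whose discrete level at n = 13 is ~0.022.
* **Paired-pulse analysis.** Ratios are 100 × mean(conditioned)/mean(SP)
  per state and phase, with the SP denominator from the same blocks. The
  time × state interaction is tested by a seeded subject-level sign-flip
  permutation with FDR across the three protocols. CS search grids: 50–90
  %RMT in 5 % steps (SICI), 106–114 in 2 % steps (LICI), 10 trials per
  candidate, ties to the lowest intensity; LCD inherits LICI's CS.

## Problem sizes used by the recovery suite

Trained-gain recovery pools three replicate 15-participant cohorts run in
full trace mode (the per-cohort mean is unbiased but has ~3.7 points of
Monte-Carlo spread, so a single cohort's CI misses its own expectation at
the usual rate). The control null uses 100 replicate 13-participant sham
cohorts in lite mode (amplitude-level simulation, identical generative
law). Band-effect recovery averages 200 replicate 14-subject cohorts;
classification checks use 14 subjects with 60 + 60 epochs; the paired-pulse
recovery uses 32 trained subjects (baseline 20 trials per protocol plus
three 24-trial interleaved blocks per condition).

## What the synthetic experiments do not show

The generator is artifact-free by construction: no eye blinks, cardiac or
muscle contamination, no electrode drift, and therefore no ICA stage (a
pass-through hook exists). Band oscillators are stationary narrowband
Gaussian processes — no bursting, cross-frequency coupling or 1/f-slope
state changes. MEP physiology is a one-dimensional excitability scalar on a
fixed recruitment curve — no I-wave structure, no fatigue or time-of-day
drift, and hemispheric coupling is a single spillover coefficient. Passing
recoveries therefore demonstrate that the *pipelines* are correct and that
the published effect sizes are mutually consistent under this model; they
do not validate the model against real neurophysiology.
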