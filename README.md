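# meploop

Closed-loop TMS–MEP neurofeedback, simulated end to end.

Operant neurofeedback of motor evoked potential (MEP) amplitude lets people
learn to volitionally up- or down-regulate their own corticomotor
excitability: a TMS pulse over the motor hotspot evokes an MEP in a hand
muscle, the peak-to-peak amplitude is displayed immediately, and a reward is
delivered when the amplitude beats (UP) or stays under (DOWN) a criterion
that an adaptive staircase tightens block by block. `meploop` implements
that whole experiment — and its complete offline analysis chain — as a
tested, reusable pipeline driven by a generative model of a synthetic
participant, so every stage can be exercised and verified without hardware
or human data.

The package is aimed at methodologists who want to prototype or stress-test
closed-loop TMS/EEG analysis code: the trial engine, the cleaning rules, the
spectral features and the decoders all run against ground truth whose
effect sizes are calibrated to the published group results of this paradigm.

## What is inside

| module | contents |
| --- | --- |
| `meploop.participant` | generative subject: sigmoid recruitment curve `MEP(I) = MEPmax / (1 + e^{-k (I·e - I50)})` with latent excitability `e`, operant skill learning, 4-channel background EMG at 2000 Hz, 1.5 s pre-pulse EEG epochs at 1000 Hz (1/f background + one band-limited oscillator per band), conditioned MEPs for SICI / LICI / LCD |
| `meploop.engine` | calibration (resting motor threshold by the 50 µV, 5-of-10 rule; recruitment curve, 6 pulses × 10 intensities; half-max test intensity), the 7 µV / 500 ms EMG gate, 5.5–8.5 s fixation, reward rule, ×1.1 / ×1.2 staircase, fixed-rate sham schedule, and all block types (training, EEG session, retention, feedback-free, dual-coil opposite hemisphere) |
| `meploop.mep` | offline MEP pipeline: 30–800 Hz zero-phase filtering, background RMS (110–10 ms pre-pulse), peak-to-peak in 20–45 ms, per-block min/max trimming, the exclusion cascade (0.01 mV absolute, mean + 2.5 SD background, Q3 + 1.5 IQR amplitude), %-change from baseline and UP−DOWN modulation, Cohen's d |
| `meploop.eeg` | Welch spectra (1 s Hann segments, 50 % overlap), relative power per bin (% of total spectrum power), the eight published bands (delta … high gamma), low-gamma:high-alpha ratio, 1/f scaling, Wilcoxon + FDR state contrasts, robust (Huber) trial-wise regression of MEP amplitude on band powers |
| `meploop.classify` | stratified 10-fold linear SVM (C = 1) with within-fold standardisation, label-permutation null, recursive feature elimination, cross-subject modal feature ranking |
| `meploop.pp` | paired-pulse protocols (SICI: 1.97 ms ISI, sub-threshold CS; LICI: 100 ms; LCD: 220 ms with LICI's CS), personalised conditioning-stimulus search, 25 %-interleaved blocks, conditioned/single-pulse ratios and state×time contrasts |
| `meploop.study` | cohort orchestration and the recovery analyses used by the acceptance script |
| `meploop.io`, `meploop.cli` | CSV trial logs, HDF5 array containers, YAML configs; `meploop simulate / classify / pp` |

## Worked example

Simulate one synthetic participant through a five-day experiment (two UP
days, two DOWN days, an EEG day), clean the trials and recover the trained
modulation:

```python
from meploop import study, mep
from meploop.participant import Participant, ParticipantParams

part = Participant(ParticipantParams(seed=3))
trials, artifacts, cal = study.simulate_participant(part)
print(f"RMT {cal.rmt:.0f} %MSO, test intensity {cal.test_intensity:.1f} %MSO"
      f" ({cal.test_intensity / cal.rmt:.2f} x RMT)")

recovery = study.up_down_recovery(trials)          # cleaned, day-5 blocks
print(recovery.round(1))
```

prints (seed 3):

```
RMT 43 %MSO, test intensity 55.9 %MSO (1.30 x RMT)
condition  DOWN    UP
subject
0         -28.5  72.1
```

i.e. this subject's resting motor threshold was 43 % of maximal stimulator
output, the half-maximum test intensity landed at the conventional ~130 %
RMT, and after training the cleaned MEP amplitude in the final UP blocks sat
72.1 % above the same-day resting baseline while the DOWN blocks sat 28.5 %
below it — single-subject scatter around the cohort-level +83.8 % / −30.6 %
the generator is calibrated to.

Decode the brain state from the pre-pulse EEG features of the same kind of
subject:

```python
from meploop import classify as clf

feats = study.subject_feature_table(part)          # 60 UP + 60 DOWN epochs
X, y, names = clf.build_feature_matrix(feats)      # 8 scaled bands + ratio
cv = clf.crossval_classify(X, y, seed=3)
print(f"10-fold accuracy {cv.mean_accuracy_pct:.1f} %")
```

```
10-fold accuracy 86.7 %
```

From the shell, the same things:

```bash
meploop simulate --participants 3 --seed 1 --out out/      # trials.csv, summary.csv, HDF5 arrays
meploop classify --features features.csv --perms 100 --seed 1 --out out/
meploop pp --state UP --seed 1 --out out/
```

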