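"""The closed-loop neurofeedback experiment.

Calibration (resting motor threshold, recruitment curve, baseline), the
EMG-gated trial state machine, feedback/reward logic, the adaptive
staircase, the fixed-rate sham schedule for the control group, and the
block/session scheduling for every block type (training, EEG session,
retention, after-effect rest, feedback-free, dual-coil opposite-hemisphere).

Timing model: the simulator advances per trial event (gate pass, fixation,
pulse) on the 2000 Hz EMG clock; absolute wall-clock time is not simulated.
Two signal modes are supported:

* ``trace`` (default): every trial synthesises raw EMG (gate stream and a
  peri-pulse trace); background RMS and MEP size are measured by the same
  offline filtering path the analysis uses.
* ``lite``: amplitudes and background RMS are drawn from the identical
  generative laws without sample-level traces - used for replicate-heavy
  Monte-Carlo studies.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.special import expit

from . import mep as mep_pipeline
from .participant import (EMG_FS, Participant, generate_background_emg,
                          generate_mep)

#: recruitment-curve intensities as multiples of RMT (no 170 % step)
RECRUITMENT_MULTIPLES = (0.9, 1.0, 1.1, 1.2, 1.3, 1.4, 1.5, 1.6, 1.8, 1.9)
PULSES_PER_INTENSITY = 6
RMT_CRITERION_MV = 0.05
RMT_HITS_REQUIRED = 5
RMT_PULSES = 10

#: fraction of broadband white-noise power passed by the 30-800 Hz filter
_BAND_POWER_FRAC = 0.77


class CalibrationError(RuntimeError):
    """No grid intensity satisfied the threshold criterion."""


@dataclass
class SessionConfig:
    condition: str = "UP"              # UP | DOWN
    group: str = "experimental"        # experimental | control
    trials_per_block: int = 30
    blocks_per_day: int = 4
    baseline_trials: int = 20
    post_trials: int = 12
    gate_threshold_uv: float = 7.0
    gate_window_ms: float = 100.0
    gate_sustain_ms: float = 500.0
    fixation_range_s: tuple[float, float] = (5.5, 8.5)
    staircase_thresholds: tuple[float, float] = (0.70, 0.90)
    staircase_steps: tuple[float, float] = (0.10, 0.20)
    sham_rate: float = 0.66
    tense_prob: float = 0.05           # chance of a muscle-tension episode per trial
    trace_mode: str = "trace"          # trace | lite
    emg_fs: float = EMG_FS
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.sham_rate < 1:
            raise ValueError("sham_rate must be in (0, 1)")
        if self.fixation_range_s[0] > self.fixation_range_s[1]:
            raise ValueError("fixation range must be non-decreasing")
        if not self.staircase_thresholds[0] < self.staircase_thresholds[1]:
            raise ValueError("staircase thresholds must be strictly increasing")
        if self.condition not in ("UP", "DOWN"):
            raise ValueError("condition must be UP or DOWN")
        if self.group not in ("experimental", "control"):
            raise ValueError("group must be experimental or control")
        if self.trace_mode not in ("trace", "lite"):
            raise ValueError("trace_mode must be 'trace' or 'lite'")


@dataclass
class StaircaseState:
    """Reward criterion plus its full multiplicative audit trail."""

    criterion_mv: float
    block_success_history: list[float] = field(default_factory=list)
    step_factors: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.criterion_mv <= 0:
            raise ValueError("criterion must be positive")


@dataclass
class CalibrationResult:
    rmt: float
    recruitment: list[tuple[float, float]]  # (intensity %MSO, mean mV)
    mep_max: float                          # fitted recruitment plateau, mV
    test_intensity: float                   # %MSO evoking half of mep_max
    baseline_mean: float = float("nan")     # mean of 20 rest MEPs at test intensity
    max_mean_mv: float = float("nan")       # raw maximum of per-intensity means
    plateau_warning: bool = False


@dataclass(frozen=True)
class GateEvent:
    passed: bool
    pass_sample: int | None
    fs: float = EMG_FS

    @property
    def pass_time_s(self) -> float | None:
        return None if self.pass_sample is None else (self.pass_sample + 1) / self.fs


# --------------------------------------------------------------- calibration

def estimate_rmt(participant: Participant,
                 intensity_grid: np.ndarray | None = None,
                 rng: np.random.Generator | None = None) -> float:
    """Lowest grid intensity evoking >=50 uV MEPs in >=5 of 10 pulses.

    The search ascends the sorted grid from below threshold.
    """
    rng = rng or participant.rng
    if intensity_grid is None:
        intensity_grid = np.arange(25.0, 71.0, 1.0)
    grid = np.sort(np.asarray(intensity_grid, dtype=float))
    participant.set_strategy("REST")
    for intensity in grid:
        hits = 0
        for _ in range(RMT_PULSES):
            participant.fluctuate(rng=rng)
            if participant.mep(intensity, rng=rng) >= RMT_CRITERION_MV:
                hits += 1
        if hits >= RMT_HITS_REQUIRED:
            return float(intensity)
    raise CalibrationError("no grid intensity reached the RMT criterion")


def _logistic(i, m, i50, k):
    return m * expit(k * (i - i50))


def _log_logistic(i, ln_m, i50, k):
    return ln_m + np.log(expit(k * (i - i50)))


def measure_recruitment_curve(participant: Participant, rmt: float,
                              rng: np.random.Generator | None = None
                              ) -> CalibrationResult:
    """Recruitment curve: 6 pulses at 10 intensities relative to RMT in
    randomised order; the plateau and the half-max test intensity are read
    off a fitted logistic curve."""
    rng = rng or participant.rng
    participant.set_strategy("REST")
    intensities = np.array([rmt * m for m in RECRUITMENT_MULTIPLES])
    pulses = [(i, p) for i in intensities for p in range(PULSES_PER_INTENSITY)]
    order = rng.permutation(len(pulses))
    amps: dict[float, list[float]] = {i: [] for i in intensities}
    for j in order:
        intensity, _ = pulses[j]
        participant.fluctuate(rng=rng)
        amps[intensity].append(participant.mep(intensity, rng=rng))
    means = np.array([np.mean(amps[i]) for i in intensities])
    max_mean = float(means.max())

    plateau_warning = False
    try:
        # fit on log-amplitudes of all 60 pulses: variance-stabilising for
        # the multiplicative MEP noise, so every pulse carries equal weight
        # and the half-max point is located much more precisely than from
        # the per-intensity means
        all_i = np.array([i for i in intensities for _ in amps[i]])
        all_ln = np.log(np.concatenate([amps[i] for i in intensities]))
        p0 = (math.log(max_mean),
              float(intensities[np.argmin(np.abs(means - max_mean / 2))]), 0.3)
        popt, _ = curve_fit(_log_logistic, all_i, all_ln, p0=p0,
                            bounds=([math.log(max_mean) - 3.0, intensities[0],
                                     1e-3],
                                    [math.log(max_mean) + 3.0,
                                     2 * intensities[-1], 5.0]),
                            maxfev=10000)
        ln_m, i50_fit, k_fit = (float(v) for v in popt)
        m_fit = math.exp(ln_m)
        # plateau not reached if the curve is still rising steeply at the top
        top_slope = m_fit * k_fit * float(
            expit(k_fit * (intensities[-1] - i50_fit))
            * (1 - expit(k_fit * (intensities[-1] - i50_fit))))
        if np.argmax(means) == len(means) - 1 and top_slope > 0.02 * m_fit:
            plateau_warning = True
            warnings.warn("recruitment curve may not have plateaued")
        mep_max, test_intensity = m_fit, i50_fit
    except RuntimeError:
        # fall back to linear interpolation of the per-intensity means
        mep_max = max_mean
        half = mep_max / 2.0
        above = np.nonzero(means >= half)[0]
        j = int(above[0]) if len(above) else len(means) - 1
        if j == 0:
            test_intensity = float(intensities[0])
        else:
            x0, x1 = intensities[j - 1], intensities[j]
            y0, y1 = means[j - 1], means[j]
            test_intensity = float(x0 + (half - y0) * (x1 - x0) / max(y1 - y0, 1e-12))
        plateau_warning = True

    return CalibrationResult(
        rmt=float(rmt),
        recruitment=[(float(i), float(m)) for i, m in zip(intensities, means)],
        mep_max=float(mep_max),
        test_intensity=float(np.clip(test_intensity, intensities[0], intensities[-1])),
        max_mean_mv=max_mean,
        plateau_warning=plateau_warning,
    )


def calibrate_participant(participant: Participant,
                          rng: np.random.Generator | None = None
                          ) -> CalibrationResult:
    """RMT, recruitment curve and a 20-MEP rest baseline at the chosen
    test intensity."""
    rng = rng or participant.rng
    rmt = estimate_rmt(participant, rng=rng)
    cal = measure_recruitment_curve(participant, rmt, rng=rng)
    participant.set_strategy("REST")
    amps = []
    for _ in range(20):
        participant.fluctuate(rng=rng)
        amps.append(participant.mep(cal.test_intensity, rng=rng))
    cal.baseline_mean = float(np.mean(amps))
    participant.anchor_training_intensity(cal.test_intensity)
    return cal


# ---------------------------------------------------------------------- gate

def _trailing_rms(x: np.ndarray, window: int) -> np.ndarray:
    """Trailing-window RMS per channel; the window expands from the first
    sample so the monitor is live immediately."""
    sq = np.cumsum(x ** 2, axis=-1)
    sq = np.concatenate([np.zeros((x.shape[0], 1)), sq], axis=-1)
    n = x.shape[-1]
    t = np.arange(n)
    start = np.maximum(t + 1 - window, 0)
    counts = (t + 1 - start).astype(float)
    tot = sq[:, t + 1] - sq[:, start]
    return np.sqrt(tot / counts)


def run_gate(emg_stream: np.ndarray, config: SessionConfig) -> GateEvent:
    """First instant at which every channel's trailing 100 ms RMS has been
    below threshold continuously for the sustain period."""
    x = np.atleast_2d(np.asarray(emg_stream, dtype=float))
    window = int(round(config.gate_window_ms * config.emg_fs / 1000.0))
    sustain = int(round(config.gate_sustain_ms * config.emg_fs / 1000.0))
    rms = _trailing_rms(x, window)
    ok = np.all(rms < config.gate_threshold_uv, axis=0)
    bad = np.concatenate([[0], np.cumsum(~ok)])
    t = np.arange(sustain - 1, x.shape[-1])
    good = bad[t + 1] - bad[t + 1 - sustain] == 0
    hits = np.nonzero(good)[0]
    if len(hits) == 0:
        return GateEvent(False, None, config.emg_fs)
    return GateEvent(True, int(t[hits[0]]), config.emg_fs)


def sample_fixation(config: SessionConfig, rng: np.random.Generator) -> float:
    lo, hi = config.fixation_range_s
    return float(rng.uniform(lo, hi))


# ----------------------------------------------------------- feedback/reward

def decide_feedback(mep_mv: float, criterion_mv: float, condition: str) -> bool:
    """UP: rewarded iff MEP strictly exceeds the criterion; DOWN reversed.
    Exact equality is never rewarded."""
    if mep_mv <= 0 or criterion_mv <= 0:
        raise ValueError("amplitudes must be positive")
    if condition == "UP":
        return mep_mv > criterion_mv
    if condition == "DOWN":
        return mep_mv < criterion_mv
    raise ValueError(f"unknown condition {condition!r}")


def update_staircase(stair: StaircaseState, block_success: float,
                     condition: str,
                     thresholds: tuple[float, float] = (0.70, 0.90),
                     steps: tuple[float, float] = (0.10, 0.20)) -> StaircaseState:
    """Multiplicative difficulty adjustment after a block: >90 % success
    moves the criterion by 20 %, >70 % by 10 % (raised for UP, lowered for
    DOWN), otherwise unchanged.  Memoryless across blocks."""
    if not 0 <= block_success <= 1:
        raise ValueError("success fraction must lie in [0, 1]")
    if block_success > thresholds[1]:
        step = steps[1]
    elif block_success > thresholds[0]:
        step = steps[0]
    else:
        step = 0.0
    factor = 1.0 + step if condition == "UP" else 1.0 - step
    return StaircaseState(
        criterion_mv=stair.criterion_mv * factor,
        block_success_history=stair.block_success_history + [block_success],
        step_factors=stair.step_factors + [factor],
    )


def sham_schedule(n_trials: int, sham_rate: float = 0.66) -> np.ndarray:
    """Deterministic fixed-rate reward sequence for the control group: the
    cyclic triple (reward, reward, no-reward), 66 % within rounding."""
    if n_trials < 1:
        raise ValueError("need at least one trial")
    if not 0 < sham_rate < 1:
        raise ValueError("sham_rate must be in (0, 1)")
    return np.resize(np.array([True, True, False]), n_trials)


# --------------------------------------------------------------- trial level

def _mep_waveform(amp_mv: float, fs: float, rng: np.random.Generator
                  ) -> tuple[np.ndarray, int]:
    """Biphasic MEP-shaped wavelet (uV) with the requested peak-to-peak
    amplitude, plus its onset latency in samples (20-24 ms)."""
    dur_s = 0.012
    n = int(round(dur_s * fs))
    t = np.arange(n) / fs
    w = np.sin(2 * np.pi * 150.0 * t) * np.hanning(n)
    w /= (w.max() - w.min())
    latency = int(round((0.020 + rng.uniform(0.0, 0.004)) * fs))
    return w * amp_mv * 1000.0, latency


_PRE_MS = 150.0
_POST_MS = 60.0


def _simulate_trial_trace(participant: Participant, intensity: float,
                          rng: np.random.Generator) -> tuple[np.ndarray, int, float]:
    """Peri-pulse 4-channel EMG trace with injected MEP and stimulus
    artifact.  Returns (trace uV, pulse sample index, true amplitude mV)."""
    fs = EMG_FS
    trace = generate_background_emg(participant.params, _PRE_MS + _POST_MS, rng)
    pulse_index = int(round(_PRE_MS * fs / 1000.0))
    amp = generate_mep(participant.state, intensity, participant.params, rng)
    w, latency = _mep_waveform(amp, fs, rng)
    start = pulse_index + latency
    trace[0, start:start + len(w)] += w[: trace.shape[1] - start]
    trace[:, pulse_index:pulse_index + 3] += 3000.0  # stimulus artifact
    return trace, pulse_index, amp


def _lite_background_rms(participant: Participant,
                         rng: np.random.Generator) -> np.ndarray:
    """Sampling-law draw of the filtered 100 ms background RMS per muscle
    (chi-square with the filter-reduced effective dof)."""
    rest = np.asarray(participant.params.emg_rest_rms)
    dof = max(int(200 * _BAND_POWER_FRAC), 1)
    scale = rng.chisquare(dof, size=len(rest)) / dof
    return rest * math.sqrt(_BAND_POWER_FRAC) * np.sqrt(scale)


def _run_mep_trial(participant: Participant, config: SessionConfig,
                   intensity: float, rng: np.random.Generator,
                   collect_eeg: bool = False, n_eeg_channels: int = 2,
                   state_override=None) -> dict:
    """One gated TMS trial: gate -> fixation -> pulse -> measurement."""
    p = participant
    tense_pre = rng.random() < config.tense_prob

    if config.trace_mode == "trace" or tense_pre:
        if tense_pre:
            ch = int(rng.integers(0, 4))
            seg1 = generate_background_emg(p.params, 400.0, rng, tense=True,
                                           tense_channels=(ch,))
            seg2 = generate_background_emg(
                p.params, config.gate_sustain_ms + 200.0, rng)
            stream = np.concatenate([seg1, seg2], axis=-1)
        else:
            stream = generate_background_emg(
                p.params, config.gate_sustain_ms + 100.0, rng)
        gate = run_gate(stream, config)
        gate_wait_s = gate.pass_time_s if gate.passed else float("nan")
    else:
        gate_wait_s = config.gate_sustain_ms / 1000.0

    fixation_s = sample_fixation(config, rng)
    pauses = 0
    if rng.random() < config.tense_prob:  # tension during fixation re-arms the gate
        ch = int(rng.integers(0, 4))
        seg = np.concatenate([
            generate_background_emg(p.params, 300.0, rng, tense=True,
                                    tense_channels=(ch,)),
            generate_background_emg(p.params, config.gate_sustain_ms + 200.0, rng),
        ], axis=-1)
        regate = run_gate(seg, config)
        pauses = 1
        if regate.passed:
            fixation_s += regate.pass_time_s

    u = float(rng.standard_normal())
    if state_override is not None:
        state = state_override
        amp_state = state
    else:
        p.fluctuate(rng=rng, u=u)
        amp_state = p.state

    if config.trace_mode == "trace":
        saved = p.state
        if state_override is not None:
            p.state = state_override
        trace, pulse_index, _ = _simulate_trial_trace(p, intensity, rng)
        p.state = saved
        bg, mep_mv = mep_pipeline.measure_trial(trace, pulse_index)
    else:
        trace, pulse_index = None, None
        bg = _lite_background_rms(p, rng)
        mep_mv = generate_mep(amp_state, intensity, p.params, rng)

    rec = {
        "fixation_s": fixation_s,
        "gate_wait_s": gate_wait_s,
        "gated_pause_count": pauses,
        "bg_rms_ch0_uv": float(bg[0]),
        "bg_rms_ch1_uv": float(bg[1]),
        "bg_rms_ch2_uv": float(bg[2]),
        "bg_rms_ch3_uv": float(bg[3]),
        "bg_rms_max_uv": float(np.max(bg)),
        "mep_mv": float(mep_mv),
        "excitability": float(amp_state.excitability),
        "_trace": trace,
        "_pulse_index": pulse_index,
        "_u": u,
    }
    if collect_eeg:
        rec["_epoch"] = p.eeg_epoch(n_channels=n_eeg_channels, hotspot_index=0,
                                    rng=rng, u=u)
    return rec


# --------------------------------------------------------------- block level

def run_block(participant: Participant, config: SessionConfig,
              calibration: CalibrationResult, block_type: str,
              rng: np.random.Generator,
              condition: str | None = None,
              n_trials: int | None = None,
              stair: StaircaseState | None = None,
              collect_eeg: bool = False,
              veridical: bool | None = None) -> tuple[list[dict], StaircaseState | None]:
    """Run one block of trials of the given type and return its records.

    ``feedback`` blocks drive reward + learning (or the sham schedule for
    the control group); rest-type blocks stimulate at rest with no feedback.
    """
    condition = condition or config.condition
    intensity = calibration.test_intensity
    if veridical is None:
        veridical = config.group == "experimental"
    records: list[dict] = []

    if block_type in ("baseline_rest", "post_rest", "aftereffect_rest"):
        n = n_trials or (config.baseline_trials if block_type == "baseline_rest"
                         else config.post_trials)
        participant.set_strategy("REST")
        for i in range(n):
            rec = _run_mep_trial(participant, config, intensity, rng)
            rec.update(trial=i, trial_type=block_type, condition=condition,
                       strategy="REST", criterion_mv=float("nan"), rewarded=None)
            records.append(rec)
        return records, stair

    if block_type in ("feedback", "retention", "feedback_free"):
        n = n_trials or (20 if block_type in ("retention", "feedback_free")
                         else config.trials_per_block)
        participant.set_strategy(condition)
        sham = sham_schedule(n, config.sham_rate)
        n_rewarded = 0
        for i in range(n):
            rec = _run_mep_trial(participant, config, intensity, rng,
                                 collect_eeg=collect_eeg)
            if block_type == "feedback_free":
                rewarded = None      # display suppressed: nothing delivered
            elif config.group == "control":
                rewarded = bool(sham[i])
            else:
                rewarded = decide_feedback(rec["mep_mv"], stair.criterion_mv,
                                           condition)
            if rewarded:
                n_rewarded += 1
            if rewarded is not None:
                participant.learn(rewarded, veridical)
            rec.update(trial=i, trial_type=block_type, condition=condition,
                       strategy=condition,
                       criterion_mv=stair.criterion_mv if stair else float("nan"),
                       rewarded=rewarded)
            records.append(rec)
        if block_type == "feedback" and stair is not None:
            stair = update_staircase(stair, n_rewarded / n, condition,
                                     config.staircase_thresholds,
                                     config.staircase_steps)
        return records, stair

    if block_type == "opposite_hemisphere":
        n = n_trials or 40
        participant.set_strategy(condition)
        hemis = rng.permutation(np.array(["trained"] * (n // 2)
                                         + ["opposite"] * (n - n // 2)))
        for i, hemi in enumerate(hemis):
            if hemi == "opposite":
                participant.fluctuate(rng=rng)
                rec = _run_mep_trial(
                    participant, config, intensity, rng,
                    state_override=participant.opposite_hemisphere_state())
                rewarded = None
            else:
                rec = _run_mep_trial(participant, config, intensity, rng)
                rewarded = (decide_feedback(rec["mep_mv"], stair.criterion_mv,
                                            condition)
                            if stair is not None and config.group == "experimental"
                            else None)
                if rewarded is not None:
                    participant.learn(rewarded, veridical)
            rec.update(trial=i, trial_type="opposite_hemisphere",
                       condition=condition, strategy=condition, hemisphere=hemi,
                       criterion_mv=stair.criterion_mv if stair else float("nan"),
                       rewarded=rewarded)
            records.append(rec)
        return records, stair

    raise ValueError(f"unknown block type {block_type!r}")


# -------------------------------------------------------------- session level

def run_training_day(participant: Participant, config: SessionConfig,
                     calibration: CalibrationResult, day: int,
                     rng: np.random.Generator,
                     collect_eeg: bool = False) -> list[dict]:
    """One training day: 20-MEP baseline, then 4 x (30 feedback + 12 post)."""
    condition = config.condition
    rows: list[dict] = []
    base, _ = run_block(participant, config, calibration, "baseline_rest", rng,
                        condition=condition)
    for r in base:
        r.update(day=day, half=0, block=0)
    rows += base
    baseline_mean = float(np.mean([r["mep_mv"] for r in base]))
    stair = StaircaseState(criterion_mv=baseline_mean)
    for b in range(1, config.blocks_per_day + 1):
        fb, stair = run_block(participant, config, calibration, "feedback", rng,
                              condition=condition, stair=stair,
                              collect_eeg=collect_eeg)
        for r in fb:
            r.update(day=day, half=0, block=b)
        rows += fb
        post, _ = run_block(participant, config, calibration, "post_rest", rng,
                            condition=condition)
        for r in post:
            r.update(day=day, half=0, block=b)
        rows += post
    return rows


def run_eeg_day(participant: Participant, config: SessionConfig,
                calibration: CalibrationResult, day: int,
                rng: np.random.Generator,
                n_eeg_channels: int = 2) -> list[dict]:
    """The EEG session: per condition half, a fresh baseline followed by two
    feedback blocks (with 12-MEP posts), EEG epochs collected on every
    feedback trial.  Condition order is counterbalanced by the seed."""
    first = "UP" if rng.random() < 0.5 else "DOWN"
    order = (first, "DOWN" if first == "UP" else "UP")
    rows: list[dict] = []
    block_no = 0
    for half, condition in enumerate(order):
        cfg = SessionConfig(**{**config.__dict__, "condition": condition})
        base, _ = run_block(participant, cfg, calibration, "baseline_rest", rng,
                            condition=condition)
        for r in base:
            r.update(day=day, half=half, block=block_no)
        rows += base
        baseline_mean = float(np.mean([r["mep_mv"] for r in base]))
        stair = StaircaseState(criterion_mv=baseline_mean)
        for _ in range(2):
            block_no += 1
            fb, stair = run_block(participant, cfg, calibration, "feedback", rng,
                                  condition=condition, stair=stair,
                                  collect_eeg=True)
            for r in fb:
                r.update(day=day, half=half, block=block_no)
            rows += fb
            post, _ = run_block(participant, cfg, calibration, "post_rest", rng,
                                condition=condition)
            for r in post:
                r.update(day=day, half=half, block=block_no)
            rows += post
        block_no += 1
    return rows


def records_to_frame(rows: list[dict], subject: int, group: str
                     ) -> tuple[pd.DataFrame, list[dict]]:
    """Split raw records into a tidy trial table and an artifact list
    (traces/epochs keyed by trial id)."""
    artifacts = []
    clean_rows = []
    for i, r in enumerate(rows):
        r = dict(r)
        trial_id = f"s{subject:03d}_t{i:05d}"
        art = {"trial_id": trial_id}
        for key in ("_trace", "_pulse_index", "_epoch", "_u"):
            if key in r:
                art[key.lstrip("_")] = r.pop(key)
        artifacts.append(art)
        r.update(subject=subject, group=group, trial_id=trial_id)
        clean_rows.append(r)
    return pd.DataFrame(clean_rows), artifacts
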