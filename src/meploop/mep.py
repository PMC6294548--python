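"""Offline MEP/EMG processing.

Filtering, background-EMG quantification, the exclusion cascade, per-block
trimming, baseline normalisation and effect summaries.  All functions work
either on raw traces (uV at 2000 Hz) or on a tidy per-trial table produced
by the closed-loop engine.

Processing conventions
----------------------
* Band-pass: zero-phase 4th-order Butterworth, 30-800 Hz, applied
  *separately* to the pre-pulse segment and to the MEP segment so the MEP
  cannot smear into the background-EMG window.
* Background EMG: RMS of the filtered samples 110 to 10 ms before the pulse.
* MEP size: peak-to-peak amplitude in a 20-45 ms post-pulse window
  (conventional FDI latency; the stimulus-artifact samples at pulse time are
  excluded from the filtered MEP segment by construction).
* Cleaning order: per-block min/max trimming first, then the exclusion
  rules - (1) absolute background > 0.01 mV, (2) background > subject mean
  + 2.5 SD over all of that subject's (post-trim) trials, (3) amplitude >
  Q3 + 1.5 IQR over the subject's whole (post-trim) trial set; quartiles by
  linear interpolation of order statistics.  Each excluded trial carries the
  first failing rule as its reason.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

EMG_FS = 2000.0

#: absolute background-EMG exclusion threshold, mV
BG_ABS_LIMIT_MV = 0.01
#: relative background-EMG threshold, SDs above the subject mean
BG_SD_LIMIT = 2.5
#: MEP measurement window relative to the pulse, ms
MEP_WINDOW_MS = (20.0, 45.0)
#: background-EMG window relative to the pulse, ms (110 to 10 ms before)
BG_WINDOW_MS = (-110.0, -10.0)
#: MEP filter segment starts this long after the pulse (excludes the artifact)
MEP_SEGMENT_START_MS = 5.0

EXCLUSION_REASONS = ("trimmed", "bg_abs", "bg_sd", "amp_iqr", "none")


def bandpass(x: np.ndarray, fs: float = EMG_FS, low: float = 30.0,
             high: float = 800.0, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the last axis."""
    if fs <= 2 * high:
        raise ValueError("sampling rate must exceed twice the upper edge")
    sos = signal.butter(order, (low, high), btype="bandpass", fs=fs, output="sos")
    n_sections = sos.shape[0]
    padlen = 3 * (2 * n_sections + 1)
    if np.shape(x)[-1] <= padlen:
        raise ValueError(f"segment too short for filter stability (need > {padlen} samples)")
    return signal.sosfiltfilt(sos, x, axis=-1)


def background_rms(trace: np.ndarray, pulse_index: int,
                   fs: float = EMG_FS) -> np.ndarray:
    """RMS (same units as the trace) over [pulse-110 ms, pulse-10 ms)."""
    lo = pulse_index + int(round(BG_WINDOW_MS[0] * fs / 1000.0))
    hi = pulse_index + int(round(BG_WINDOW_MS[1] * fs / 1000.0))
    if lo < 0 or hi > np.shape(trace)[-1] or hi <= lo:
        raise ValueError("pre-pulse window not available in trace")
    seg = np.asarray(trace)[..., lo:hi]
    return np.sqrt(np.mean(seg ** 2, axis=-1))


def peak_to_peak(trace: np.ndarray, window: tuple[int, int]) -> float:
    """max - min over the sample window [lo, hi)."""
    lo, hi = window
    if hi <= lo or lo < 0 or hi > np.shape(trace)[-1]:
        raise ValueError("empty or out-of-range window")
    seg = np.asarray(trace)[..., lo:hi]
    return float(seg.max(axis=-1) - seg.min(axis=-1))


def measure_trial(trace: np.ndarray, pulse_index: int,
                  fs: float = EMG_FS, mep_channel: int = 0
                  ) -> tuple[np.ndarray, float]:
    """Full single-trial measurement path.

    Filters the pre-pulse and post-pulse segments independently, then
    returns (per-channel background RMS in uV, MEP peak-to-peak in mV for
    ``mep_channel``).  The trace is expected in uV.
    """
    trace = np.atleast_2d(np.asarray(trace, dtype=float))
    pre = bandpass(trace[:, :pulse_index], fs=fs)
    start = pulse_index + int(round(MEP_SEGMENT_START_MS * fs / 1000.0))
    post = bandpass(trace[:, start:], fs=fs)
    bg = background_rms(np.concatenate([pre, trace[:, pulse_index:]], axis=-1),
                        pulse_index, fs=fs)
    w_lo = int(round(MEP_WINDOW_MS[0] * fs / 1000.0)) - (start - pulse_index)
    w_hi = int(round(MEP_WINDOW_MS[1] * fs / 1000.0)) - (start - pulse_index)
    amp_uv = peak_to_peak(post[mep_channel], (w_lo, w_hi))
    return bg, amp_uv / 1000.0


def trim_block_extremes(amplitudes: np.ndarray) -> np.ndarray:
    """Boolean mask keeping all but one maximum and one minimum.

    Ties are broken by first occurrence.  Blocks with fewer than 3 trials
    are returned untrimmed with a warning.
    """
    a = np.asarray(amplitudes, dtype=float)
    keep = np.ones(len(a), dtype=bool)
    if len(a) < 3:
        warnings.warn("block has fewer than 3 trials; trimming skipped")
        return keep
    keep[int(np.argmax(a))] = False
    # ensure the minimum is a different trial even if all values tie
    order = np.argsort(a, kind="stable")
    i_min = int(order[0]) if keep[int(order[0])] else int(order[1])
    keep[i_min] = False
    return keep


@dataclass
class CleanedTrials:
    """Per-trial retention flags plus bookkeeping counts."""

    table: pd.DataFrame  # original rows + 'retained' (bool) + 'reason'

    @property
    def retained(self) -> pd.DataFrame:
        return self.table[self.table["retained"]]

    @property
    def counts(self) -> dict[str, int]:
        return self.table["reason"].value_counts().to_dict()


def apply_exclusions(df: pd.DataFrame, bg_col: str = "bg_rms_max_uv",
                     amp_col: str = "mep_mv",
                     iqr_group_cols: tuple[str, ...] | None = None
                     ) -> pd.DataFrame:
    """Exclusion cascade for one subject's (already trimmed) trial pool.

    Adds 'retained'/'reason' columns.  Background values are in uV in the
    table; the absolute rule threshold is 0.01 mV = 10 uV.  The background
    rules (absolute and mean + 2.5 SD) always use the subject's whole trial
    pool.  The amplitude-outlier rule judges each trial against a
    condition-matched pool when ``iqr_group_cols`` is given (so trained-UP
    MEPs are not wholesale flagged as outliers of the pooled bimodal
    distribution - rejection rates then do not depend on feedback type);
    with ``None`` the quartiles come from the whole pool.
    """
    out = df.copy()
    bg = out[bg_col].to_numpy(dtype=float)
    amp = out[amp_col].to_numpy(dtype=float)
    reason = np.full(len(out), "none", dtype=object)

    rule1 = bg > BG_ABS_LIMIT_MV * 1000.0
    reason[rule1] = "bg_abs"

    mu, sd = bg.mean(), bg.std(ddof=1) if len(bg) > 1 else 0.0
    rule2 = (bg > mu + BG_SD_LIMIT * sd) & (reason == "none")
    reason[rule2] = "bg_sd"

    if iqr_group_cols:
        groups = out.groupby(list(iqr_group_cols)).indices.values()
    else:
        groups = [np.arange(len(out))]
    for idx in groups:
        idx = np.asarray(idx)
        if len(idx) < 4:
            warnings.warn("fewer than 4 trials in pool; quartile rule skipped")
            continue
        q1, q3 = np.percentile(amp[idx], [25, 75])  # linear interpolation
        rule3 = (amp[idx] > q3 + 1.5 * (q3 - q1)) & (reason[idx] == "none")
        reason[idx[rule3]] = "amp_iqr"

    out["reason"] = reason
    out["retained"] = reason == "none"
    return out


def clean_trials(trials: pd.DataFrame,
                 block_keys: tuple[str, ...] = ("subject", "day", "block"),
                 subject_key: str = "subject",
                 bg_col: str = "bg_rms_max_uv",
                 amp_col: str = "mep_mv",
                 iqr_pool: str = "condition") -> CleanedTrials:
    """Full cleaning chain: per-block trimming, then the per-subject
    exclusion cascade on the post-trim pool.

    ``iqr_pool``: 'condition' (default) judges amplitude outliers against
    the subject's condition-matched trials (rejection rates independent of
    feedback type); 'subject' uses the subject's whole pooled trial set.
    """
    if iqr_pool not in ("condition", "subject"):
        raise ValueError("iqr_pool must be 'condition' or 'subject'")
    df = trials.copy().reset_index(drop=True)
    df["reason"] = "none"
    df["retained"] = True

    for _, idx in df.groupby(list(block_keys)).groups.items():
        idx = np.asarray(idx)
        if len(idx) < 3:
            continue
        keep = trim_block_extremes(df.loc[idx, amp_col].to_numpy())
        df.loc[idx[~keep], "reason"] = "trimmed"
        df.loc[idx[~keep], "retained"] = False

    group_cols = None
    if iqr_pool == "condition":
        group_cols = tuple(c for c in ("trial_type", "condition")
                           if c in df.columns) or None

    for _, sub_idx in df[df["retained"]].groupby(subject_key).groups.items():
        sub_idx = np.asarray(sub_idx)
        res = apply_exclusions(df.loc[sub_idx], bg_col=bg_col, amp_col=amp_col,
                               iqr_group_cols=group_cols)
        df.loc[sub_idx, "reason"] = res["reason"].to_numpy()
        df.loc[sub_idx, "retained"] = res["retained"].to_numpy()

    return CleanedTrials(df)


def percent_change_from_baseline(block_mean: float, baseline_mean: float) -> float:
    """100 * (block - baseline) / baseline."""
    if baseline_mean <= 0:
        raise ValueError("baseline mean must be positive")
    return 100.0 * (block_mean - baseline_mean) / baseline_mean


def up_down_modulation(up_pct: float, down_pct: float) -> float:
    """UP minus DOWN %-change: larger means stronger bidirectional control."""
    return up_pct - down_pct


def cohens_d(x, y=None, paired: bool = True) -> float:
    """Cohen's d.

    ``paired=True`` (default): d_z = mean(x - y) / SD(x - y); pass the
    differences directly as ``x`` with ``y=None``.  ``paired=False``:
    two-group form, mean difference over the pooled SD.
    """
    x = np.asarray(x, dtype=float)
    if paired:
        d = x if y is None else x - np.asarray(y, dtype=float)
        if len(d) < 2:
            raise ValueError("need at least 2 observations")
        sd = d.std(ddof=1)
        if sd <= 1e-12 * max(abs(d.mean()), 1.0):
            raise ValueError("zero variance: effect size undefined")
        return float(d.mean() / sd)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least 2 observations per group")
    sp = np.sqrt(((len(x) - 1) * x.var(ddof=1) + (len(y) - 1) * y.var(ddof=1))
                 / (len(x) + len(y) - 2))
    if sp == 0:
        raise ValueError("zero variance: effect size undefined")
    return float((x.mean() - y.mean()) / sp)


def block_summary(clean: CleanedTrials,
                  feedback_types: tuple[str, ...] = ("feedback",),
                  baseline_type: str = "baseline_rest") -> pd.DataFrame:
    """Per (subject, day, half, block) mean amplitude and %-change from the
    matching same-day baseline.  Expects engine-format trial tables."""
    df = clean.retained
    if "half" not in df.columns:
        df = df.assign(half=0)
    base = (df[df["trial_type"] == baseline_type]
            .groupby(["subject", "day", "half"])["mep_mv"].mean()
            .rename("baseline_mv"))
    fb = (df[df["trial_type"].isin(feedback_types)]
          .groupby(["subject", "day", "half", "block", "condition"])["mep_mv"]
          .agg(["mean", "size"]).reset_index()
          .rename(columns={"mean": "mean_mv", "size": "n"}))
    fb = fb.join(base, on=["subject", "day", "half"])
    fb["pct_change"] = [
        percent_change_from_baseline(m, b)
        for m, b in zip(fb["mean_mv"], fb["baseline_mv"])
    ]
    return fb
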