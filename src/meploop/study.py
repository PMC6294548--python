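"""Cohort-level orchestration and recovery analyses.

Glue between the generative participant model, the closed-loop engine and
the offline pipelines: run whole multi-day experiments for cohorts, build
per-subject EEG feature matrices, and compute the group-level recovery
summaries (trained UP/DOWN %-changes, band contrasts, classification
accuracies, paired-pulse state modulation).
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
from scipy import stats

from . import classify as clf
from . import eeg, mep, pp
from .bands import BAND_NAMES
from .engine import (CalibrationResult, SessionConfig, calibrate_participant,
                     records_to_frame, run_eeg_day, run_training_day)
from .participant import Participant, PPProtocol, make_cohort

DEFAULT_DAYS = ("UP", "DOWN", "UP", "DOWN", "EEG")


def simulate_participant(participant: Participant, subject: int = 0,
                         group: str = "experimental",
                         days: tuple[str, ...] = DEFAULT_DAYS,
                         trace_mode: str = "trace",
                         tense_prob: float = 0.05,
                         ) -> tuple[pd.DataFrame, list[dict], CalibrationResult]:
    """Calibrate one participant, then run the full multi-day protocol.

    Returns (trial table, per-trial artifacts incl. EEG epochs on the EEG
    day, calibration).
    """
    rng = participant.rng
    cal = calibrate_participant(participant, rng=rng)
    rows: list[dict] = []
    for day, kind in enumerate(days, start=1):
        n_before = len(rows)
        if kind == "EEG":
            cfg = SessionConfig(group=group, trace_mode=trace_mode,
                                tense_prob=tense_prob)
            rows += run_eeg_day(participant, cfg, cal, day, rng)
        else:
            cfg = SessionConfig(condition=kind, group=group,
                                trace_mode=trace_mode, tense_prob=tense_prob)
            rows += run_training_day(participant, cfg, cal, day, rng)
        for r in rows[n_before:]:
            r["day_kind"] = kind
    trials, artifacts = records_to_frame(rows, subject, group)
    return trials, artifacts, cal


def simulate_cohort(n: int, group: str = "experimental", master_seed: int = 0,
                    days: tuple[str, ...] = DEFAULT_DAYS,
                    trace_mode: str = "trace", tense_prob: float = 0.05,
                    **participant_overrides
                    ) -> tuple[pd.DataFrame, dict[int, list[dict]]]:
    """Independent cohort run through the full protocol; returns the pooled
    trial table and per-subject artifact lists."""
    cohort = make_cohort(n, master_seed, **participant_overrides)
    frames, artifacts = [], {}
    for s, part in enumerate(cohort):
        t, a, _ = simulate_participant(part, subject=s, group=group, days=days,
                                       trace_mode=trace_mode,
                                       tense_prob=tense_prob)
        frames.append(t)
        artifacts[s] = a
    return pd.concat(frames, ignore_index=True), artifacts


# --------------------------------------------------------- MEP recovery

def up_down_recovery(trials: pd.DataFrame, day: int | None = None
                     ) -> pd.DataFrame:
    """Cleaned per-subject %-change from same-day baseline per condition on
    the chosen day (default: the last day, i.e. the trained state)."""
    day = day if day is not None else int(trials["day"].max())
    clean = mep.clean_trials(trials)
    summ = mep.block_summary(clean)
    summ = summ[summ["day"] == day]
    per_subj = (summ.groupby(["subject", "condition"])["pct_change"]
                .mean().unstack("condition"))
    return per_subj


def modulation_by_block(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-subject UP-DOWN modulation per training-block position (1..8).

    Training blocks are ordered within condition across the training days,
    so position k pairs the k-th UP block with the k-th DOWN block.  The
    EEG session (if present) is excluded.
    """
    sel = trials
    if "day_kind" in trials.columns:
        sel = trials[trials["day_kind"] != "EEG"]
    clean = mep.clean_trials(sel)
    summ = mep.block_summary(clean)
    summ = summ.sort_values(["subject", "condition", "day", "block"])
    summ["position"] = summ.groupby(["subject", "condition"]).cumcount() + 1
    wide = summ.pivot_table(index=["subject", "position"], columns="condition",
                            values="pct_change").reset_index().dropna()
    wide["modulation"] = [
        mep.up_down_modulation(u, d) for u, d in zip(wide["UP"], wide["DOWN"])]
    return wide


def modulation_trend_test(modulation: pd.DataFrame) -> dict[str, float]:
    """Null check for a cohort: is there a trend of UP-DOWN modulation over
    training blocks?

    Fits a per-subject least-squares slope of modulation on block position
    and applies an exact sign test of the subject slopes against a zero
    median (a conservative distribution-free trend test).  Also reports the
    cohort mean modulation.
    """
    slopes = []
    for _, grp in modulation.groupby("subject"):
        if grp["position"].nunique() < 2:
            continue
        slopes.append(float(np.polyfit(grp["position"], grp["modulation"], 1)[0]))
    slopes = np.asarray(slopes)
    k = int(np.sum(slopes > 0))
    n = int(np.sum(slopes != 0))
    p = float(stats.binomtest(k, n, 0.5).pvalue) if n else 1.0
    return {"mean_modulation": float(modulation["modulation"].mean()),
            "p_trend": p, "n_subjects": len(slopes)}


# --------------------------------------------------------- EEG features

def _batch_feature_frame(epochs: np.ndarray, sides: np.ndarray,
                         mep_mv: np.ndarray | None = None,
                         electrodes: tuple[str, ...] = ("hotspot",),
                         hotspot_index: int = 0) -> pd.DataFrame:
    """Vectorised feature table for a stack of epochs (n, ch, 1500)."""
    rows = {}
    for el_i, el in enumerate(electrodes):
        ch = hotspot_index if el == "hotspot" else (hotspot_index + 1 + el_i - 1)
        freqs, psd = eeg.welch_spectrum(epochs[:, ch, :])
        f, rel = eeg.relative_power_bins(freqs, psd)
        bands = eeg.band_powers(f, rel)
        scaled = eeg.band_powers(f, eeg.one_over_f_scale(f, rel))
        suffix = "" if el == "hotspot" else f"_{el}"
        for b in BAND_NAMES:
            rows[b + suffix] = bands[b]
            rows[eeg.SCALED_PREFIX + b + suffix] = scaled[b]
        rows[eeg.RATIO_NAME + suffix] = bands["low_gamma"] / bands["high_alpha"]
    df = pd.DataFrame(rows)
    df["condition"] = np.where(np.asarray(sides) > 0, "UP",
                               np.where(np.asarray(sides) < 0, "DOWN", "REST"))
    if mep_mv is not None:
        df["mep_mv"] = np.asarray(mep_mv, dtype=float)
    return df


def subject_feature_table(participant: Participant, n_per_state: int = 60,
                          electrodes: tuple[str, ...] = ("hotspot",),
                          trained: bool = True) -> pd.DataFrame:
    """60 UP + 60 DOWN epoch features for one (trained) subject, drawn
    directly from the generator in its trained state."""
    if trained:
        participant.state = replace(participant.state, skill_up=1.0,
                                    skill_down=1.0)
    sides = np.concatenate([np.ones(n_per_state), -np.ones(n_per_state)])
    n_ch = 1 if electrodes == ("hotspot",) else 2
    epochs = participant.eeg_epochs(sides, n_channels=n_ch, hotspot_index=0)
    return _batch_feature_frame(epochs, sides, electrodes=electrodes)


def eeg_day_feature_table(trials: pd.DataFrame, artifacts: list[dict],
                          electrodes: tuple[str, ...] = ("hotspot",)
                          ) -> pd.DataFrame:
    """Feature table for the EEG-session feedback trials of one subject,
    joined with the measured MEP amplitudes."""
    by_id = {a["trial_id"]: a for a in artifacts if "epoch" in a}
    sel = trials[trials["trial_id"].isin(by_id)].reset_index(drop=True)
    epochs = np.stack([by_id[t]["epoch"] for t in sel["trial_id"]])
    sides = np.where(sel["condition"] == "UP", 1.0, -1.0)
    df = _batch_feature_frame(epochs, sides, sel["mep_mv"].to_numpy(),
                              electrodes=electrodes)
    df["trial_id"] = sel["trial_id"]
    return df


def band_contrast_recovery(n_subjects: int = 14, master_seed: int = 0,
                           n_per_state: int = 60) -> pd.DataFrame:
    """Subject-level UP/DOWN band contrast on freshly generated cohorts:
    the route used to check that the generator's band_d defaults are
    recovered by the spectral pipeline."""
    cohort = make_cohort(n_subjects, master_seed)
    ups, downs = [], []
    for part in cohort:
        feats = subject_feature_table(part, n_per_state=n_per_state)
        g = feats.groupby("condition")[list(BAND_NAMES)].mean()
        ups.append(g.loc["UP"])
        downs.append(g.loc["DOWN"])
    return eeg.contrast_states(pd.DataFrame(ups).reset_index(drop=True),
                               pd.DataFrame(downs).reset_index(drop=True))


# ------------------------------------------------------- classification

def cohort_classification(n_subjects: int = 14, master_seed: int = 0,
                          electrodes: tuple[str, ...] = ("hotspot",),
                          folds: int = 10) -> pd.DataFrame:
    """Per-subject 10-fold CV accuracy on generator-calibrated features."""
    cohort = make_cohort(n_subjects, master_seed)
    rows = []
    for s, part in enumerate(cohort):
        feats = subject_feature_table(part, electrodes=electrodes)
        X, y, _ = clf.build_feature_matrix(feats, electrodes=electrodes)
        res = clf.crossval_classify(X, y, folds=folds,
                                    seed=int(part.params.seed % (2 ** 31)))
        rows.append({"subject": s, "accuracy_pct": res.mean_accuracy_pct})
    return pd.DataFrame(rows)


# -------------------------------------------------------- paired pulse

def trained_pp_experiment(n_subjects: int = 11, master_seed: int = 0,
                          search: bool = True) -> pd.DataFrame:
    """Paired-pulse follow-up for a trained cohort: CS search at rest, then
    baseline + three interleaved blocks per condition; returns one row per
    (subject, protocol) with the four state/phase ratios."""
    cohort = make_cohort(n_subjects, master_seed)
    rows = []
    for s, part in enumerate(cohort):
        part.state = replace(part.state, skill_up=1.0, skill_down=1.0)
        ts = part.params.i50  # the neurofeedback test intensity
        cs_sici = (pp.search_conditioning_intensity(part, "SICI", ts)
                   if search else part.params.sici_cs_ref)
        cs_lici = (pp.search_conditioning_intensity(part, "LICI", ts)
                   if search else part.params.lici_cs_ref)
        protocols = {
            "SICI": PPProtocol.make("SICI", cs_sici, ts),
            "LICI": PPProtocol.make("LICI", cs_lici, ts),
            "LCD": PPProtocol.make("LCD", cs_lici, ts),
        }
        frames = [pp.run_pp_state_blocks(part, cond, protocols)
                  for cond in ("UP", "DOWN")]
        summ = pp.summarize_pp(pd.concat(frames, ignore_index=True))
        for proto in pp.PROTOCOLS:
            sel = summ[summ["protocol"] == proto].set_index(["condition", "phase"])
            rows.append({
                "subject": s, "protocol": proto,
                "up_nf": sel.loc[("UP", "nf"), "ratio_pct"],
                "up_base": sel.loc[("UP", "baseline"), "ratio_pct"],
                "down_nf": sel.loc[("DOWN", "nf"), "ratio_pct"],
                "down_base": sel.loc[("DOWN", "baseline"), "ratio_pct"],
            })
    return pd.DataFrame(rows)
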