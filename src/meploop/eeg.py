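"""Pre-stimulus EEG spectral pipeline.

Epoching (the 1.5 s immediately preceding each TMS pulse), Welch spectra,
relative band power, the low-gamma:high-alpha ratio, 1/f scaling, UP/DOWN
state contrasts and trial-wise robust amplitude regression.

Spectral conventions
--------------------
Welch estimates use 1.0 s Hann segments with 50 % overlap, giving 1 Hz bins
from a 1.5 s epoch; the denominator is the total power of the whole spectrum (1 Hz to Nyquist)
while band edges run up to 80 Hz.  Relative power
expresses every bin as a percentage of the total power over the analysed
range, per channel per epoch, so all features are invariant to per-epoch amplitude
rescaling.  The "1/f transform" multiplies each bin's relative power by its
frequency (exponent configurable) before band aggregation, whitening the
spectrum against a 1/f background.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal, stats
from statsmodels.robust.norms import HuberT
from statsmodels.robust.robust_linear_model import RLM
from statsmodels.stats.multitest import multipletests

from .bands import BAND_EDGES, BAND_NAMES, FMAX_TOTAL, FMIN

EEG_FS = 1000.0
EPOCH_SAMPLES = 1500
WELCH_NPERSEG = 1000
WELCH_OVERLAP = 500

RATIO_NAME = "lg_ha_ratio"
SCALED_PREFIX = "scaled_"


@dataclass
class EEGEpoch:
    """1.5 s multichannel pre-pulse EEG segment (uV at 1000 Hz)."""

    data: np.ndarray            # (n_channels, 1500)
    hotspot: int                # channel index nearest the TMS hotspot
    condition: str = "REST"     # UP | DOWN | REST
    trial_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.shape[-1] != EPOCH_SAMPLES:
            raise ValueError(f"epoch must hold exactly {EPOCH_SAMPLES} samples")
        if not 0 <= self.hotspot < self.data.shape[0]:
            raise ValueError("hotspot channel out of range")


def extract_pre_tms_epoch(recording: np.ndarray, pulse_sample: int,
                          hotspot: int = 0, condition: str = "REST",
                          trial_id: str = "") -> EEGEpoch:
    """The 1500 samples ending one sample before the pulse."""
    recording = np.atleast_2d(np.asarray(recording))
    if pulse_sample < EPOCH_SAMPLES:
        raise ValueError("insufficient pre-pulse data for a 1.5 s epoch")
    if pulse_sample > recording.shape[-1]:
        raise ValueError("pulse sample beyond end of recording")
    seg = recording[:, pulse_sample - EPOCH_SAMPLES:pulse_sample]
    return EEGEpoch(seg, hotspot=hotspot, condition=condition, trial_id=trial_id)


def welch_spectrum(x: np.ndarray, fs: float = EEG_FS
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Averaged periodogram (Hann, 1 s segments, 50 % overlap -> 1 Hz bins).

    Accepts a single channel or any leading batch shape; the spectrum is
    computed along the last axis.
    """
    freqs, psd = signal.welch(np.asarray(x, dtype=float), fs=fs,
                              nperseg=WELCH_NPERSEG, noverlap=WELCH_OVERLAP,
                              window="hann", detrend="constant", axis=-1)
    return freqs, psd


def _analysis_mask(freqs: np.ndarray) -> np.ndarray:
    return (freqs >= FMIN) & (freqs <= FMAX_TOTAL)


def relative_power_bins(freqs: np.ndarray, psd: np.ndarray
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin relative power (% of the total spectrum power, 1 Hz to
    Nyquist; the eight bands cover 1-80 Hz, so their shares sum to less
    than 100 % and the remainder sits in the broadband tail)."""
    mask = _analysis_mask(freqs)
    f = freqs[mask]
    p = np.asarray(psd)[..., mask]
    total = p.sum(axis=-1, keepdims=True)
    if np.any(total <= 0):
        raise ValueError("zero total power in the analysed range")
    return f, 100.0 * p / total


def band_powers(freqs: np.ndarray, rel_bins: np.ndarray) -> dict[str, np.ndarray]:
    """Sum per-bin relative power within each band (closed integer edges)."""
    out = {}
    for name in BAND_NAMES:
        lo, hi = BAND_EDGES[name]
        sel = (freqs >= lo) & (freqs <= hi)
        out[name] = np.asarray(rel_bins)[..., sel].sum(axis=-1)
    return out


def relative_power(freqs: np.ndarray, psd: np.ndarray) -> dict[str, float]:
    """BandPowerVector for one spectrum: 8 relative band powers (%) plus
    the low-gamma : high-alpha ratio."""
    f, rel = relative_power_bins(freqs, psd)
    bands = {k: float(v) for k, v in band_powers(f, rel).items()}
    bands[RATIO_NAME] = gamma_alpha_ratio(bands)
    return bands


def gamma_alpha_ratio(bands: dict[str, float]) -> float:
    """low_gamma / high_alpha relative power."""
    ha = bands["high_alpha"]
    if ha <= 0:
        raise ValueError("high-alpha power is zero; ratio undefined")
    return float(bands["low_gamma"] / ha)


def one_over_f_scale(freqs: np.ndarray, rel_bins: np.ndarray,
                     exponent: float = 1.0) -> np.ndarray:
    """Whitening against a 1/f background: multiply each bin's relative
    power by its frequency (to the configured exponent)."""
    return np.asarray(rel_bins) * np.asarray(freqs) ** exponent


def epoch_features(epoch: EEGEpoch, channel: int | None = None) -> dict[str, float]:
    """All spectral features for one channel (default: hotspot): raw band
    powers, the ratio, and the 1/f-scaled band powers."""
    ch = epoch.hotspot if channel is None else channel
    freqs, psd = welch_spectrum(epoch.data[ch])
    f, rel = relative_power_bins(freqs, psd)
    feats = {k: float(v) for k, v in band_powers(f, rel).items()}
    feats[RATIO_NAME] = gamma_alpha_ratio(feats)
    scaled = band_powers(f, one_over_f_scale(f, rel))
    feats.update({SCALED_PREFIX + k: float(v) for k, v in scaled.items()})
    return feats


def features_table(epochs: list[EEGEpoch],
                   mep_mv: np.ndarray | None = None,
                   channels: dict[str, int] | None = None) -> pd.DataFrame:
    """Tidy per-epoch feature table.

    ``channels`` maps a role name (e.g. ``hotspot``, ``opposite``) to a
    channel index; defaults to the hotspot channel only.  Feature columns
    are suffixed with the role for non-hotspot channels.
    """
    rows = []
    for i, ep in enumerate(epochs):
        roles = channels or {"hotspot": ep.hotspot}
        row: dict = {"trial_id": ep.trial_id or str(i), "condition": ep.condition}
        for role, ch in roles.items():
            feats = epoch_features(ep, channel=ch)
            suffix = "" if role == "hotspot" else f"_{role}"
            row.update({k + suffix: v for k, v in feats.items()})
        if mep_mv is not None:
            row["mep_mv"] = float(mep_mv[i])
        rows.append(row)
    return pd.DataFrame(rows)


# ------------------------------------------------------------------ contrasts

def paired_cohens_d(diffs: np.ndarray) -> float:
    diffs = np.asarray(diffs, dtype=float)
    sd = diffs.std(ddof=1)
    return float(diffs.mean() / sd) if sd > 0 else 0.0


def contrast_states(up_means: pd.DataFrame, down_means: pd.DataFrame,
                    bands: tuple[str, ...] = BAND_NAMES) -> pd.DataFrame:
    """Per-band Wilcoxon signed-rank contrast of subject-level UP vs DOWN
    mean relative power, Benjamini-Hochberg corrected across bands.

    Both inputs are subject x band tables aligned on their index.
    """
    if len(up_means) < 6:
        raise ValueError("need at least 6 paired subjects")
    rows = []
    pvals = []
    for band in bands:
        d = (up_means[band] - down_means.loc[up_means.index, band]).to_numpy()
        if np.allclose(d, 0):
            stat, p = 0.0, 1.0
        else:
            stat, p = stats.wilcoxon(d)
        rows.append({"band": band, "delta_rel_power": float(np.mean(d)),
                     "statistic": float(stat), "p": float(p),
                     "d_paired": paired_cohens_d(d)})
        pvals.append(p)
    adj = multipletests(pvals, method="fdr_bh")[1]
    out = pd.DataFrame(rows)
    out["p_fdr"] = adj
    return out


# ----------------------------------------------------------------- regression

def trialwise_regression(band_df: pd.DataFrame, amplitudes: np.ndarray,
                         predictors: tuple[str, ...] = BAND_NAMES
                         ) -> pd.Series:
    """Robust (iteratively reweighted, Huber loss) regression of single-trial
    MEP amplitude on the per-trial relative band powers; returns one slope
    per predictor."""
    X = band_df.loc[:, list(predictors)].to_numpy(dtype=float)
    y = np.asarray(amplitudes, dtype=float)
    if len(y) < 2 * (X.shape[1] + 1):
        raise ValueError("need at least twice as many trials as predictors")
    # the 8 relative band powers are compositional (they sum to 100 %), so
    # an explicit intercept is perfectly collinear with them; absorb it
    design = np.column_stack([np.ones(len(y)), X])
    offset = 1
    if np.linalg.matrix_rank(design) < design.shape[1]:
        design, offset = X, 0
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient design matrix (collinear band powers)")
    fit = RLM(y, design, M=HuberT()).fit()
    return pd.Series(fit.params[offset:], index=list(predictors))


def group_slope_test(slopes: pd.DataFrame) -> pd.DataFrame:
    """Signed-rank test of per-subject regression slopes against zero per
    predictor, with FDR correction across predictors."""
    rows, pvals = [], []
    for col in slopes.columns:
        v = slopes[col].to_numpy(dtype=float)
        if np.allclose(v, 0):
            stat, p = 0.0, 1.0
        else:
            stat, p = stats.wilcoxon(v)
        rows.append({"predictor": col, "median_slope": float(np.median(v)),
                     "statistic": float(stat), "p": float(p)})
        pvals.append(p)
    out = pd.DataFrame(rows)
    out["p_fdr"] = multipletests(pvals, method="fdr_bh")[1]
    return out
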