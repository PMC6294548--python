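"""Paired-pulse TMS protocol logic.

Conditioning-stimulus search, interleaved paired-pulse scheduling inside
neurofeedback blocks, conditioned-to-single-pulse ratio analysis, and
state-dependence contrasts for SICI (ISI 1.97 ms, sub-threshold CS), LICI
(ISI 100 ms, supra-threshold CS) and LCD (ISI 220 ms, LICI's CS).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .participant import Participant, PPProtocol, ProtocolError

#: conditioning-intensity search grids, % RMT
SICI_GRID = tuple(np.arange(50.0, 91.0, 5.0))
LICI_GRID = tuple(np.arange(106.0, 115.0, 2.0))
SEARCH_TRIALS = 10
TARGET_INHIBITION_PCT = 50.0

PROTOCOLS = ("SICI", "LICI", "LCD")


def search_conditioning_intensity(participant: Participant, protocol_name: str,
                                  ts_intensity: float,
                                  rng: np.random.Generator | None = None,
                                  n_trials: int = SEARCH_TRIALS) -> float:
    """Personalised CS search: evaluate each grid candidate with
    ``n_trials`` conditioned and single-pulse trials at rest, return the
    candidate whose mean conditioned/SP ratio is closest to 50 %.

    Ties go to the lowest intensity (conservative stimulation).  If no
    candidate inhibits at all (< 100 %), the nearest candidate is returned
    with a warning.  LCD inherits the LICI result by construction.
    """
    rng = rng or participant.rng
    if protocol_name == "SICI":
        grid = SICI_GRID
    elif protocol_name in ("LICI", "LCD"):
        grid = LICI_GRID
        protocol_name = "LICI"
    else:
        raise ProtocolError(f"unknown protocol {protocol_name!r}")
    participant.set_strategy("REST")
    ratios = []
    for cs in grid:
        proto = PPProtocol.make(protocol_name, cs, ts_intensity)
        cond = [participant.conditioned_mep(proto, rng=rng) for _ in range(n_trials)]
        sp = [participant.mep(ts_intensity, rng=rng) for _ in range(n_trials)]
        ratios.append(100.0 * np.mean(cond) / np.mean(sp))
    ratios = np.asarray(ratios)
    if np.all(ratios >= 100.0):
        warnings.warn(f"no {protocol_name} candidate achieved inhibition; "
                      "returning the nearest grid point")
    return float(grid[int(np.argmin(np.abs(ratios - TARGET_INHIBITION_PCT)))])


def build_interleaved_block(n_trials: int = 24, seed: int = 0) -> list[str]:
    """Randomised trial-type sequence with exactly n/4 each of SP, SICI,
    LICI and LCD; feedback is attached to SP trials only."""
    if n_trials % 4 != 0:
        raise ValueError("interleaved block size must be divisible by 4")
    q = n_trials // 4
    seq = np.array(["SP"] * q + ["SICI"] * q + ["LICI"] * q + ["LCD"] * q)
    return list(np.random.default_rng(seed).permutation(seq))


def pp_ratio(conditioned: np.ndarray, single_pulse: np.ndarray) -> float:
    """100 x mean(conditioned) / mean(single pulse)."""
    conditioned = np.asarray(conditioned, dtype=float)
    single_pulse = np.asarray(single_pulse, dtype=float)
    if len(conditioned) < 1 or len(single_pulse) < 1:
        raise ValueError("need at least one trial of each type")
    sp = single_pulse.mean()
    if sp <= 0:
        raise ValueError("non-positive single-pulse mean")
    return float(100.0 * conditioned.mean() / sp)


def run_pp_state_blocks(participant: Participant, condition: str,
                        protocols: dict[str, PPProtocol],
                        rng: np.random.Generator | None = None,
                        n_blocks: int = 3, block_trials: int = 24,
                        baseline_trials: int = 20) -> pd.DataFrame:
    """One paired-pulse day for one neurofeedback condition.

    A resting baseline (``baseline_trials`` of each paired-pulse protocol
    plus as many single pulses) immediately precedes ``n_blocks``
    interleaved 24-trial neurofeedback blocks in which only 25 % of trials
    are single-pulse feedback trials.
    """
    rng = rng or participant.rng
    ts = next(iter(protocols.values())).ts_intensity
    rows = []
    participant.set_strategy("REST")
    for name, proto in protocols.items():
        for i in range(baseline_trials):
            participant.fluctuate(rng=rng)
            rows.append({"phase": "baseline", "condition": condition,
                         "protocol": name,
                         "amp_mv": participant.conditioned_mep(proto, rng=rng)})
    for i in range(baseline_trials):
        participant.fluctuate(rng=rng)
        rows.append({"phase": "baseline", "condition": condition,
                     "protocol": "SP", "amp_mv": participant.mep(ts, rng=rng)})

    participant.set_strategy(condition)
    for b in range(n_blocks):
        seq = build_interleaved_block(block_trials,
                                      seed=int(rng.integers(2 ** 31)))
        for trial_type in seq:
            participant.fluctuate(rng=rng)
            if trial_type == "SP":
                amp = participant.mep(ts, rng=rng)
            else:
                amp = participant.conditioned_mep(protocols[trial_type], rng=rng)
            rows.append({"phase": "nf", "condition": condition,
                         "protocol": trial_type, "amp_mv": amp, "block": b})
    return pd.DataFrame(rows)


def summarize_pp(trials: pd.DataFrame) -> pd.DataFrame:
    """Conditioned/SP ratio per (condition, phase, protocol); the SP
    denominator comes from the same condition and phase."""
    rows = []
    for (condition, phase), grp in trials.groupby(["condition", "phase"]):
        sp = grp.loc[grp["protocol"] == "SP", "amp_mv"].to_numpy()
        for proto in PROTOCOLS:
            cond = grp.loc[grp["protocol"] == proto, "amp_mv"].to_numpy()
            if len(cond) == 0:
                continue
            rows.append({"condition": condition, "phase": phase,
                         "protocol": proto, "n": len(cond),
                         "ratio_pct": pp_ratio(cond, sp)})
    return pd.DataFrame(rows)


def state_modulation_contrast(subject_ratios: pd.DataFrame, seed: int = 0,
                              n_perm: int = 2000) -> pd.DataFrame:
    """Time (baseline vs during-NF) x state (UP vs DOWN) interaction per
    protocol, tested by a seeded sign-flip permutation of the state labels
    at the subject level; FDR across the three protocols.

    Expects one row per (subject, protocol) with columns ``up_nf``,
    ``up_base``, ``down_nf``, ``down_base`` (ratios in % of SP).
    """
    required = {"subject", "protocol", "up_nf", "up_base", "down_nf", "down_base"}
    missing = required - set(subject_ratios.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    rows, pvals = [], []
    for proto in PROTOCOLS:
        grp = subject_ratios[subject_ratios["protocol"] == proto]
        if grp.empty:
            continue
        inter = ((grp["up_nf"] - grp["up_base"])
                 - (grp["down_nf"] - grp["down_base"])).to_numpy(dtype=float)
        obs = float(np.mean(inter))
        flips = rng.choice([-1.0, 1.0], size=(n_perm, len(inter)))
        null = (flips * inter[None, :]).mean(axis=1)
        p = float((1 + np.sum(np.abs(null) >= abs(obs))) / (n_perm + 1))
        rows.append({"protocol": proto, "interaction_pct": obs,
                     "up_minus_down_nf": float(np.mean(grp["up_nf"] - grp["down_nf"])),
                     "up_nf_minus_base": float(np.mean(grp["up_nf"] - grp["up_base"])),
                     "p": p})
        pvals.append(p)
    out = pd.DataFrame(rows)
    out["p_fdr"] = multipletests(pvals, method="fdr_bh")[1] if pvals else []
    return out
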