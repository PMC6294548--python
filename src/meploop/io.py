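"""On-disk formats: CSV trial logs, HDF5 array containers, YAML configs.

Trial logs are plain CSV (one row per trial; see the column dictionary in
the README).  Per-trial EMG traces and EEG epochs go into one HDF5 file
each, keyed by trial id.  Session/cohort configuration round-trips through
YAML.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .engine import SessionConfig


def save_trials_csv(trials: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    trials.to_csv(path, index=False)
    return path


def load_trials_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def save_artifacts_h5(artifacts: list[dict], path: str | Path) -> Path:
    """Store per-trial arrays (EMG trace + pulse index, EEG epoch) keyed by
    trial id."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        for art in artifacts:
            grp = f.create_group(art["trial_id"])
            if art.get("trace") is not None:
                ds = grp.create_dataset("emg_uv", data=art["trace"])
                ds.attrs["fs_hz"] = 2000.0
                ds.attrs["pulse_index"] = art["pulse_index"]
            if art.get("epoch") is not None:
                ds = grp.create_dataset("eeg_uv", data=art["epoch"])
                ds.attrs["fs_hz"] = 1000.0
                ds.attrs["hotspot"] = 0
    return path


def load_artifacts_h5(path: str | Path) -> list[dict]:
    out = []
    with h5py.File(path, "r") as f:
        for trial_id in f:
            grp = f[trial_id]
            art: dict = {"trial_id": trial_id}
            if "emg_uv" in grp:
                art["trace"] = np.asarray(grp["emg_uv"])
                art["pulse_index"] = int(grp["emg_uv"].attrs["pulse_index"])
            if "eeg_uv" in grp:
                art["epoch"] = np.asarray(grp["eeg_uv"])
            out.append(art)
    return out


def cohort_from_yaml(path: str | Path):
    """Build a cohort from a YAML spec::

        n: 15
        master_seed: 0
        heterogeneity: true
        params:            # optional ParticipantParams overrides
          mep_noise_cv: 0.25
    """
    from .participant import make_cohort

    d = yaml.safe_load(Path(path).read_text()) or {}
    params = d.get("params") or {}
    params = {k: tuple(v) if isinstance(v, list) else v for k, v in params.items()}
    return make_cohort(int(d.get("n", 1)), int(d.get("master_seed", 0)),
                       heterogeneity=bool(d.get("heterogeneity", True)), **params)


def config_to_yaml(config: SessionConfig, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    d = dict(config.__dict__)
    for k, v in d.items():
        if isinstance(v, tuple):
            d[k] = list(v)
    path.write_text(yaml.safe_dump(d, sort_keys=False))
    return path


def config_from_yaml(path: str | Path) -> SessionConfig:
    d = yaml.safe_load(Path(path).read_text()) or {}
    for k in ("fixation_range_s", "staircase_thresholds", "staircase_steps"):
        if k in d and isinstance(d[k], list):
            d[k] = tuple(d[k])
    return SessionConfig(**d)
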