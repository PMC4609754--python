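"""Readers and writers for the package's on-disk formats.

Tabular data (trial logs, participant tables, binned entropy, model tables)
is plain CSV/TSV via pandas.  Epoched EEG uses a documented container: a
``.npz`` archive holding the epoch array and stimulus-onset index, plus a
JSON sidecar with channel labels, sampling rate and identifiers.
Continuous EEG is read from EDF/EDF+ through mne (optional dependency,
``pip install erpentropy[edf]``).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .epochs import EpochSet

__all__ = [
    "read_trials",
    "write_trials",
    "read_participants",
    "write_participants",
    "read_binned",
    "write_binned",
    "read_events",
    "write_events",
    "save_epochset",
    "load_epochset",
    "read_raw_edf",
]

_TRIAL_COLUMNS = [
    "participant", "session", "block", "trial_index", "stimulus_string",
    "congruency", "trialtype", "responded", "rt_ms", "correct",
    "artifact_flag",
]


def read_trials(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(_TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trial log {path} lacks columns {sorted(missing)}")
    for col in ("responded", "correct", "artifact_flag"):
        df[col] = df[col].astype(bool)
    return df


def write_trials(trials: pd.DataFrame, path) -> None:
    trials.to_csv(path, index=False)


def read_participants(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_participants(participants: pd.DataFrame, path) -> None:
    participants.to_csv(path, index=False)


def read_binned(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_binned(binned: pd.DataFrame, path) -> None:
    binned.to_csv(path, sep="\t", index=False)


def read_events(path) -> pd.DataFrame:
    """Two-column TSV: sample_index, trial_id."""
    df = pd.read_csv(path, sep="\t")
    if not {"sample_index", "trial_id"} <= set(df.columns):
        raise ValueError(
            f"events file {path} must have columns sample_index, trial_id"
        )
    return df


def write_events(events: pd.DataFrame, path) -> None:
    events.to_csv(path, sep="\t", index=False)


def save_epochset(es: EpochSet, path) -> None:
    """Write an EpochSet as ``<path>.npz`` + ``<path>.json`` sidecar."""
    path = Path(path)
    np.savez_compressed(
        path.with_suffix(".npz"),
        epochs=es.epochs,
        t0_sample=np.array(es.t0_sample),
    )
    sidecar = {
        "participant_id": es.participant_id,
        "session": es.session,
        "channel_labels": list(es.channel_labels),
        "sampling_rate_hz": es.sampling_rate_hz,
        "trial_keys": es.trial_keys.to_dict(orient="list"),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_epochset(path) -> EpochSet:
    path = Path(path)
    with np.load(path.with_suffix(".npz")) as arch:
        epochs = arch["epochs"]
        t0 = int(arch["t0_sample"])
    meta = json.loads(path.with_suffix(".json").read_text())
    return EpochSet(
        participant_id=meta["participant_id"],
        session=meta["session"],
        channel_labels=meta["channel_labels"],
        sampling_rate_hz=meta["sampling_rate_hz"],
        epochs=epochs,
        t0_sample=t0,
        trial_keys=pd.DataFrame(meta["trial_keys"]),
    )


def read_raw_edf(path):
    """Continuous EEG from EDF/EDF+: returns (data, fs, channel_labels).

    Requires mne (``erpentropy[edf]``).
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError(
            "reading EDF requires mne; install with 'pip install "
            "erpentropy[edf]'"
        ) from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return raw.get_data(), float(raw.info["sfreq"]), list(raw.ch_names)
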