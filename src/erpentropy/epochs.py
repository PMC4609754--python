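"""Epoch handling: extraction, exclusion, windowed entropy, regional binning.

Turns continuous or epoched multi-channel EEG plus a behavioral trial log
into the long-format table the trajectory models consume: one entropy value
per participant x session x trialtype x congruency x region x hemisphere x
500 ms bin.

Processing order (linear averages, so the order of the two means commutes):

1. epoch the recording at stimulus onset (``extract_epochs``),
2. drop incorrect and artifact-contaminated trials (``filter_usable_epochs``),
3. drop participants with fewer than 10 usable epochs in any condition type
   (``screen_participants``),
4. windowed sample entropy per channel, averaged over the epochs of each
   stimulus type (``entropy_per_condition``),
5. average channels within the six regional electrode groups
   (``regional_average``),
6. average window centers within the three 500 ms bins (``bin_trajectory``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .entropy import SampEnParams, WindowSchedule, sample_entropy_batch

logger = logging.getLogger(__name__)

__all__ = [
    "EpochSet",
    "DEFAULT_REGION_MAP",
    "BIN_LABELS",
    "extract_epochs",
    "filter_usable_epochs",
    "screen_participants",
    "entropy_per_condition",
    "regional_average",
    "bin_trajectory",
    "binned_entropy_table",
]

#: The six regional electrode groups (extended 10-20 labels).
DEFAULT_REGION_MAP: dict[tuple[str, str], tuple[str, ...]] = {
    ("frontal", "left"): ("Fp1", "F3", "F7"),
    ("frontal", "right"): ("Fp2", "F4", "F8"),
    ("temporal", "left"): ("T7", "TP7", "FT7"),
    ("temporal", "right"): ("T8", "TP8", "FT8"),
    ("parietal", "left"): ("P3", "P7"),
    ("parietal", "right"): ("P4", "P8"),
}

#: Post-stimulus 500 ms bins, labelled by their half-open ms interval.
BIN_LABELS = ("0-500", "500-1000", "1000-1500")
_BIN_EDGES_MS = (0.0, 500.0, 1000.0, 1500.0)


@dataclass
class EpochSet:
    """Stimulus-locked EEG epochs for one participant and session.

    ``epochs`` has shape (n_epochs, n_channels, n_samples); ``t0_sample`` is
    the index of stimulus onset within every epoch.  ``trial_keys`` carries
    one row of trial metadata per epoch (at minimum ``trialtype`` and
    ``congruency``; ``correct`` and ``artifact_flag`` when exclusion has not
    yet been applied).
    """

    participant_id: str
    session: str
    channel_labels: list[str]
    sampling_rate_hz: float
    epochs: np.ndarray
    t0_sample: int
    trial_keys: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be 3-D (epochs, channels, samples)")
        if self.epochs.shape[1] != len(self.channel_labels):
            raise ValueError(
                f"{self.epochs.shape[1]} channels in data but "
                f"{len(self.channel_labels)} labels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if len(self.trial_keys) not in (0, self.epochs.shape[0]):
            raise ValueError("trial_keys must have one row per epoch")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    def select(self, mask) -> "EpochSet":
        """New EpochSet keeping the epochs where ``mask`` is True."""
        mask = np.asarray(mask, dtype=bool)
        keys = (
            self.trial_keys.loc[mask].reset_index(drop=True)
            if len(self.trial_keys)
            else self.trial_keys
        )
        return EpochSet(
            self.participant_id,
            self.session,
            list(self.channel_labels),
            self.sampling_rate_hz,
            self.epochs[mask],
            self.t0_sample,
            keys,
        )


def extract_epochs(
    continuous,
    event_samples,
    pre_ms: float = 0.0,
    post_ms: float = 1500.0,
    fs: float = 250.0,
    *,
    participant_id: str = "",
    session: str = "",
    channel_labels=None,
    trial_keys: pd.DataFrame | None = None,
) -> EpochSet:
    """Cut stimulus-locked epochs out of a continuous (channels, samples) array.

    Each epoch spans ``[-pre_ms, +post_ms)`` around its event sample, with
    lengths converted by ``round(ms * fs / 1000)``; the defaults give 375
    post-stimulus samples at 250 Hz.  Events whose window would cross the
    edge of the recording are dropped with a logged warning, not an error.
    """
    data = np.asarray(continuous, dtype=float)
    if data.ndim != 2:
        raise ValueError("continuous must be 2-D (channels, samples)")
    n_pre = int(round(pre_ms * fs / 1000.0))
    n_len = int(round((pre_ms + post_ms) * fs / 1000.0))
    n_samples = data.shape[1]
    kept, keep_idx = [], []
    for i, ev in enumerate(event_samples):
        start = int(ev) - n_pre
        if start < 0 or start + n_len > n_samples:
            logger.warning(
                "dropping event %d at sample %d: epoch [%d, %d) outside "
                "recording of %d samples",
                i, ev, start, start + n_len, n_samples,
            )
            continue
        kept.append(data[:, start : start + n_len])
        keep_idx.append(i)
    epochs = (
        np.stack(kept)
        if kept
        else np.empty((0, data.shape[0], n_len))
    )
    if channel_labels is None:
        channel_labels = [f"ch{i}" for i in range(data.shape[0])]
    keys = pd.DataFrame()
    if trial_keys is not None:
        keys = trial_keys.iloc[keep_idx].reset_index(drop=True)
    return EpochSet(
        participant_id, session, list(channel_labels), fs, epochs, n_pre, keys
    )


def filter_usable_epochs(epochs: EpochSet, trials: pd.DataFrame | None = None) -> EpochSet:
    """Keep only epochs from correct, artifact-free trials.

    ``trials`` needs columns ``correct`` and ``artifact_flag`` aligned
    one-to-one with the epochs; by default the EpochSet's own ``trial_keys``
    are used.
    """
    if trials is None:
        trials = epochs.trial_keys
    if len(trials) != epochs.n_epochs:
        raise ValueError(
            f"{len(trials)} trial records for {epochs.n_epochs} epochs"
        )
    usable = trials["correct"].to_numpy(dtype=bool) & ~trials[
        "artifact_flag"
    ].to_numpy(dtype=bool)
    return epochs.select(usable)


def screen_participants(
    usable_counts: dict, min_epochs: int = 10
) -> tuple[list, list]:
    """Remove participants with fewer than ``min_epochs`` usable epochs in
    any condition type.

    ``usable_counts`` maps participant -> {condition type -> count}.  The
    rule is strict ("fewer than"): a count equal to ``min_epochs`` keeps the
    participant.  Returns ``(kept_ids, removed_ids)`` in input order.
    """
    kept, removed = [], []
    for pid, counts in usable_counts.items():
        if any(c < min_epochs for c in counts.values()):
            removed.append(pid)
        else:
            kept.append(pid)
    return kept, removed


def entropy_per_condition(
    epochs: EpochSet,
    schedule: WindowSchedule = WindowSchedule(),
    params: SampEnParams = SampEnParams(),
    grouping=("trialtype", "congruency"),
) -> pd.DataFrame:
    """Windowed sample entropy per channel, averaged over epochs of each
    stimulus type.

    Returns a long DataFrame with columns: the grouping keys, ``channel``,
    ``center_ms``, ``entropy`` (mean over that stimulus type's epochs, nan
    values from degenerate windows excluded) and ``n_epochs`` (the number of
    non-missing epoch values entering each mean).
    """
    if epochs.n_epochs == 0:
        raise ValueError("EpochSet contains no epochs")
    grouping = list(grouping)
    if grouping and len(epochs.trial_keys) == 0:
        raise ValueError("grouping requested but EpochSet has no trial_keys")
    wlen = schedule.window_samples
    centers = schedule.centers_ms
    starts = [schedule.start_index(c, epochs.t0_sample) for c in centers]
    if min(starts) < 0 or max(starts) + wlen > epochs.epochs.shape[2]:
        raise ValueError(
            "epochs too short for the window schedule: need samples "
            f"[{min(starts)}, {max(starts) + wlen}) but epochs have "
            f"{epochs.epochs.shape[2]}"
        )
    n_ep, n_ch, _ = epochs.epochs.shape
    n_win = len(centers)
    # (epochs*channels*windows, wlen) batch, chunked to bound memory
    wins = np.empty((n_ep, n_ch, n_win, wlen))
    for wi, s in enumerate(starts):
        wins[:, :, wi, :] = epochs.epochs[:, :, s : s + wlen]
    flat = wins.reshape(-1, wlen)
    values = np.empty(flat.shape[0])
    chunk = 192  # keeps pairwise-distance temporaries ~30 MB
    for lo in range(0, flat.shape[0], chunk):
        values[lo : lo + chunk], _ = sample_entropy_batch(
            flat[lo : lo + chunk], params
        )
    values = values.reshape(n_ep, n_ch, n_win)

    if grouping:
        key_df = epochs.trial_keys[grouping]
        group_keys = list(key_df.itertuples(index=False, name=None))
    else:
        group_keys = [()] * n_ep
    rows = []
    for key in sorted(set(group_keys)):
        sel = np.array([k == key for k in group_keys])
        if not sel.any():
            continue
        vals = values[sel]  # (n_sel, n_ch, n_win)
        with np.errstate(invalid="ignore"):
            mean = np.nanmean(vals, axis=0)
        n_used = np.sum(~np.isnan(vals), axis=0)
        n_missing = int(np.isnan(vals).sum())
        if n_missing:
            logger.info(
                "condition %s: %d degenerate window values excluded from "
                "epoch averaging", key, n_missing,
            )
        for ci, ch in enumerate(epochs.channel_labels):
            for wi, c in enumerate(centers):
                rows.append(
                    dict(zip(grouping, key))
                    | {
                        "channel": ch,
                        "center_ms": float(c),
                        "entropy": float(mean[ci, wi]),
                        "n_epochs": int(n_used[ci, wi]),
                    }
                )
    return pd.DataFrame(rows)


def regional_average(
    per_channel: pd.DataFrame,
    regions: dict[tuple[str, str], tuple[str, ...]] | None = None,
) -> pd.DataFrame:
    """Average channel trajectories within each regional electrode group.

    Input is the output of :func:`entropy_per_condition`; the ``channel``
    column is replaced by ``region`` and ``hemisphere``.  Raises if a mapped
    electrode is absent from the table.
    """
    if regions is None:
        regions = DEFAULT_REGION_MAP
    present = set(per_channel["channel"].unique())
    frames = []
    keys = [
        c
        for c in per_channel.columns
        if c not in ("channel", "entropy", "n_epochs")
    ]
    for (region, hemisphere), electrodes in regions.items():
        missing = [e for e in electrodes if e not in present]
        if missing:
            raise ValueError(
                f"electrode(s) {missing} required for {hemisphere} {region} "
                "are missing from the trajectory"
            )
        sub = per_channel[per_channel["channel"].isin(electrodes)]
        agg = sub.groupby(keys, as_index=False, sort=True).agg(
            entropy=("entropy", "mean"), n_epochs=("n_epochs", "min")
        )
        agg["region"] = region
        agg["hemisphere"] = hemisphere
        frames.append(agg)
    out = pd.concat(frames, ignore_index=True)
    cols = [c for c in keys if c != "center_ms"] + [
        "region",
        "hemisphere",
        "center_ms",
        "entropy",
        "n_epochs",
    ]
    return out[cols]


def bin_trajectory(
    traj: pd.DataFrame, bin_mode: str = "mean_windows"
) -> pd.DataFrame:
    """Reduce window-center trajectories to the three post-stimulus bins.

    ``bin_mode="mean_windows"`` (default) averages every window whose center
    falls in the bin's half-open interval (0,500], (500,1000], (1000,1500] —
    3, 5 and 3 windows on the default schedule.  ``"center_window_only"``
    instead takes the single window whose span matches the bin (centers 250,
    750 and 1250 ms).  A bin with no window yields a missing value and a
    logged warning.
    """
    if bin_mode not in ("mean_windows", "center_window_only"):
        raise ValueError(f"unknown bin_mode {bin_mode!r}")
    df = traj.copy()
    centers = df["center_ms"].to_numpy(dtype=float)
    labels = np.full(len(df), "", dtype=object)
    for lo, hi, lab in zip(_BIN_EDGES_MS[:-1], _BIN_EDGES_MS[1:], BIN_LABELS):
        labels[(centers > lo) & (centers <= hi)] = lab
    df["bin"] = labels
    df = df[df["bin"] != ""]
    if bin_mode == "center_window_only":
        df = df[np.isin(df["center_ms"].to_numpy(), (250.0, 750.0, 1250.0))]
    keys = [
        c for c in df.columns if c not in ("center_ms", "entropy", "n_epochs")
    ]
    out = df.groupby(keys, as_index=False, sort=True).agg(
        entropy=("entropy", "mean")
    )
    n_expected = (
        out[[k for k in keys if k != "bin"]].drop_duplicates().shape[0]
        * len(BIN_LABELS)
    )
    if len(out) < n_expected:
        logger.warning(
            "%d bin cells missing (no window in bin)", n_expected - len(out)
        )
    return out


def binned_entropy_table(
    epoch_sets,
    participants: pd.DataFrame | None = None,
    schedule: WindowSchedule = WindowSchedule(),
    params: SampEnParams = SampEnParams(),
    regions: dict | None = None,
    grouping=("trialtype", "congruency"),
    bin_mode: str = "mean_windows",
    min_epochs: int = 10,
) -> pd.DataFrame:
    """Full pipeline from usable EpochSets to the model-ready long table.

    ``epoch_sets`` is an iterable of (already artifact/accuracy-filtered)
    :class:`EpochSet`; ``participants`` optionally supplies ``fitness_group``
    per ``participant_id``.  Participants with fewer than ``min_epochs``
    usable epochs for any session x trialtype condition are screened out.

    Returns long-format rows: participant, group, session, trialtype,
    congruency, region, hemisphere, bin, entropy.
    """
    epoch_sets = list(epoch_sets)
    counts: dict = {}
    for es in epoch_sets:
        c = counts.setdefault(es.participant_id, {})
        for tt, n in es.trial_keys["trialtype"].value_counts().items():
            c[(es.session, tt)] = c.get((es.session, tt), 0) + int(n)
    kept, removed = screen_participants(counts, min_epochs=min_epochs)
    if removed:
        logger.info("screened out participants %s (<%d usable epochs)",
                    removed, min_epochs)
    group_by_pid = {}
    if participants is not None:
        group_by_pid = dict(
            zip(participants["participant_id"], participants["fitness_group"])
        )
    frames = []
    for es in epoch_sets:
        if es.participant_id not in kept:
            continue
        per_channel = entropy_per_condition(es, schedule, params, grouping)
        regional = regional_average(per_channel, regions)
        binned = bin_trajectory(regional, bin_mode=bin_mode)
        binned.insert(0, "participant", es.participant_id)
        binned.insert(1, "group", group_by_pid.get(es.participant_id, ""))
        binned.insert(2, "session", es.session)
        frames.append(binned)
    if not frames:
        return pd.DataFrame(
            columns=["participant", "group", "session", *grouping,
                     "region", "hemisphere", "bin", "entropy"]
        )
    return pd.concat(frames, ignore_index=True)
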