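"""Session -> analysis-ready epochs: epoching, trial rejection, channel selection.

The analysis never corrects artifacts; it only *rejects* trials whose
stimulation ran too long (amplifier still saturated) and drops the
controller pair and known-bad channels.  Epochs are cut from -5 to +5 s
around stimulation onsets and offsets; the stimulation period itself is
excised later by keeping the pre-onset half and the post-offset half.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .channels import ChannelMap
from .session import Session

__all__ = [
    "EpochSet",
    "epoch_events",
    "reject_trials",
    "select_channels",
    "build_prepost",
    "REJECT_LIMIT",
]

logger = logging.getLogger(__name__)

#: default trial-rejection limits (seconds between onset and offset events)
REJECT_LIMIT = {"in_vivo": 11.0, "in_vitro": 20.0}


@dataclass
class EpochSet:
    """Trials x channels x time voltage snippets with labels and provenance.

    ``times`` is the axis in seconds relative to the alignment event,
    half-open at sample resolution ([-5, +5) for the default window).
    ``provenance`` records the processing trail; artifact handling is
    rejection-only by construction, and the flag ``"rejection_only"`` is
    asserted on by downstream stages.
    """

    data: np.ndarray  # (n_trials, n_channels, n_times) microvolt
    times: np.ndarray  # (n_times,) seconds relative to alignment
    fs: float
    labels: np.ndarray  # (n_trials,) condition strings
    trial_ids: np.ndarray  # (n_trials,)
    channels: ChannelMap
    alignment: str  # "onset" | "offset" | "concatenated"
    provenance: tuple[str, ...] = ("rejection_only",)
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if self.data.shape[0] != len(self.labels) or self.data.shape[0] != len(
            self.trial_ids
        ):
            raise ValueError("labels/trial_ids length must equal trial count")
        if self.data.shape[2] != len(self.times):
            raise ValueError("time axis length must equal data time dimension")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    def save(self, path) -> None:
        """Serialize to an .npz container with axes, labels and provenance."""
        import json

        np.savez_compressed(
            path,
            data=self.data,
            times=self.times,
            fs=self.fs,
            labels=np.asarray(self.labels, dtype=str),
            trial_ids=np.asarray(self.trial_ids),
            alignment=self.alignment,
            provenance=np.asarray(self.provenance, dtype=str),
            channels=json.dumps(self.channels.to_records()),
        )

    @classmethod
    def load(cls, path) -> "EpochSet":
        import json

        from .channels import ChannelMap as _CM

        with np.load(path, allow_pickle=False) as z:
            return cls(
                data=z["data"],
                times=z["times"],
                fs=float(z["fs"]),
                labels=z["labels"],
                trial_ids=z["trial_ids"],
                channels=_CM.from_records(json.loads(str(z["channels"]))),
                alignment=str(z["alignment"]),
                provenance=tuple(z["provenance"]),
            )

    def select_trials(self, mask_or_ids: np.ndarray) -> "EpochSet":
        idx = np.asarray(mask_or_ids)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return EpochSet(
            data=self.data[idx],
            times=self.times,
            fs=self.fs,
            labels=self.labels[idx],
            trial_ids=self.trial_ids[idx],
            channels=self.channels,
            alignment=self.alignment,
            provenance=self.provenance,
        )


def paired_trials(events: pd.DataFrame) -> pd.DataFrame:
    """Pair on/off events per trial id -> frame (trial_id, condition, block, t_on, t_off).

    Raises ``ValueError`` on unpaired events.
    """
    rows = []
    for trial_id, grp in events.groupby("trial_id"):
        ons = grp[grp["kind"] == "stim_on"]
        offs = grp[grp["kind"] == "stim_off"]
        if len(ons) != 1 or len(offs) != 1:
            raise ValueError(
                f"trial {trial_id}: expected exactly one stim_on and one stim_off, "
                f"got {len(ons)} and {len(offs)}"
            )
        rows.append(
            {
                "trial_id": trial_id,
                "condition": ons["condition"].iloc[0],
                "block": ons["block"].iloc[0],
                "t_on": float(ons["time_s"].iloc[0]),
                "t_off": float(offs["time_s"].iloc[0]),
            }
        )
    return pd.DataFrame(rows).sort_values("trial_id", ignore_index=True)


def epoch_events(
    session: Session,
    align: str = "onset",
    window: tuple[float, float] = (-5.0, 5.0),
    channel_indices: np.ndarray | None = None,
) -> EpochSet:
    """Cut one epoch per stimulation event, aligned to onsets or offsets.

    The window is half-open at sample resolution: ``[t + window[0], t +
    window[1])``, i.e. exactly ``(window[1] - window[0]) * fs`` samples.
    Events whose window extends beyond the recording are dropped; the count
    is logged and stored on the returned set.
    """
    if align not in ("onset", "offset"):
        raise ValueError("align must be 'onset' or 'offset'")
    kind = "stim_on" if align == "onset" else "stim_off"
    ev = session.events[session.events["kind"] == kind]
    if ev.empty:
        raise ValueError(f"session has no {kind} events")
    fs = session.fs
    n_times = int(round((window[1] - window[0]) * fs))
    offsets = np.arange(n_times) + int(round(window[0] * fs))
    if channel_indices is None:
        channel_indices = np.arange(session.n_channels)
    chans = np.asarray(channel_indices)

    keep_rows, snippets = [], []
    n_dropped = 0
    for _, row in ev.iterrows():
        center = int(round(row["time_s"] * fs))
        i0, i1 = center + offsets[0], center + offsets[-1] + 1
        if i0 < 0 or i1 > session.n_samples:
            n_dropped += 1
            continue
        keep_rows.append(row)
        snippets.append(session.data[np.ix_(chans, np.arange(i0, i1))])
    if n_dropped:
        logger.info("epoch_events: dropped %d events at recording edges", n_dropped)
    if not snippets:
        raise ValueError("all events fell within %g s of a recording edge" % window[1])
    kept = pd.DataFrame(keep_rows)
    cmap = (
        session.channels
        if len(chans) == session.n_channels
        else session.channels.subset(chans)
    )
    return EpochSet(
        data=np.stack(snippets).astype(np.float32),
        times=offsets / fs,
        fs=fs,
        labels=kept["condition"].to_numpy(),
        trial_ids=kept["trial_id"].to_numpy(),
        channels=cmap,
        alignment=align,
        n_dropped=n_dropped,
    )


def reject_trials(
    events: pd.DataFrame, max_duration: float | None = None, kind: str = "in_vivo"
) -> np.ndarray:
    """Trial ids whose elapsed on->off time is within the rejection limit.

    The limit is 11 s for in vivo sessions and 20 s in vitro (the amplifier
    desaturates more slowly in a bath); pass ``max_duration`` to override.
    """
    if max_duration is None:
        max_duration = REJECT_LIMIT[kind]
    trials = paired_trials(events)
    ok = (trials["t_off"] - trials["t_on"]) <= max_duration
    return trials.loc[ok, "trial_id"].to_numpy()


def select_channels(
    session_or_map: Session | ChannelMap,
    drop_controller: bool = True,
    drop_bad: bool = True,
    array: int | None = None,
) -> np.ndarray:
    """Channel indices for analysis: controller pair and bad channels excluded.

    Set the flags to False to keep everything (e.g. for controller-channel
    spectra); restrict to a single array with ``array=``.
    """
    cmap = (
        session_or_map.channels
        if isinstance(session_or_map, Session)
        else session_or_map
    )
    idx = cmap.indices(array=array, drop_controller=drop_controller, drop_bad=drop_bad)
    if len(idx) == 0:
        raise ValueError("channel selection is empty")
    return idx


def build_prepost(onset: EpochSet, offset: EpochSet) -> EpochSet:
    """Concatenate pre-onset and post-offset halves into 10-s epochs.

    Keeps the first half of each onset epoch ([-5, 0) s before stimulation)
    and the second half of the matching offset epoch ([0, +5) s after the
    offset event), excising the stimulation period.  Trials are paired by
    trial id; a mismatch raises.  On the concatenated axis t = 0 is the
    stimulation offset, so the post-stimulation analysis window (0.5-1 s)
    reads directly off this axis.
    """
    if onset.alignment != "onset" or offset.alignment != "offset":
        raise ValueError("expected an onset-aligned and an offset-aligned EpochSet")
    ids_on = list(onset.trial_ids)
    ids_off = list(offset.trial_ids)
    if set(ids_on) != set(ids_off):
        raise ValueError(
            f"trial ids differ between onset and offset sets: "
            f"{sorted(set(ids_on) ^ set(ids_off))}"
        )
    order = [ids_off.index(i) for i in ids_on]
    half_on = np.flatnonzero(onset.times < 0)
    half_off = np.flatnonzero(offset.times >= 0)
    data = np.concatenate(
        [onset.data[:, :, half_on], offset.data[order][:, :, half_off]], axis=2
    )
    times = np.concatenate([onset.times[half_on], offset.times[half_off]])
    return EpochSet(
        data=data,
        times=times,
        fs=onset.fs,
        labels=onset.labels,
        trial_ids=onset.trial_ids,
        channels=onset.channels,
        alignment="concatenated",
        provenance=onset.provenance + ("concatenated",),
    )
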