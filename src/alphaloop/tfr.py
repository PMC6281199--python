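"""Morlet wavelet power and the total / phase-locked / non-phase-locked streams.

Power is the squared magnitude of the complex Morlet convolution of each
trial.  The low-frequency family rises linearly in both frequency (5-30 Hz,
1 Hz steps) and cycle count (5-30 cycles, matched index-wise), which makes
every wavelet span exactly one second; samples within half a wavelet of an
epoch edge are flagged invalid rather than dropped.  A separate high-gamma
family (80-200 Hz in 5 Hz steps, cycles = freq/2, i.e. a fixed 0.5 s span)
covers the 80-200 Hz band.

Streams: *total* power transforms single trials; *phase-locked* (PL) power
transforms the across-trial median voltage (an evoked potential);
*non-phase-locked* (NPL) power transforms trials after subtracting that
evoked median.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from mne.time_frequency import tfr_array_morlet

from .prep import EpochSet

__all__ = ["TFRConfig", "TFRSet", "morlet_power", "evoked_median", "pl_npl_power",
           "concat_prepost_power"]


@dataclass(frozen=True)
class TFRConfig:
    """Wavelet families and output decimation.

    ``freqs``/``n_cycles`` define the low-frequency family (defaults:
    5..30 Hz with matching 5..30 cycles).  ``hf_freqs``/``hf_cycles`` define
    the high-gamma family.  ``decim`` keeps every decim-th output sample;
    power below 30 Hz varies slowly, so moderate decimation (10 at 1 kHz)
    leaves band summaries unchanged while cutting memory tenfold.
    """

    freqs: np.ndarray = field(default_factory=lambda: np.arange(5.0, 31.0))
    n_cycles: np.ndarray = field(default_factory=lambda: np.arange(5.0, 31.0))
    hf_freqs: np.ndarray = field(default_factory=lambda: np.arange(80.0, 201.0, 5.0))
    hf_cycles: np.ndarray | None = None
    decim: int = 1

    def __post_init__(self) -> None:
        freqs = np.asarray(self.freqs, dtype=float)
        cycles = np.asarray(self.n_cycles, dtype=float)
        if np.any(np.diff(freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")
        if len(cycles) != len(freqs):
            raise ValueError("n_cycles must match freqs element-wise")
        if np.any(cycles < 3):
            raise ValueError("all cycle counts must be >= 3")
        if self.hf_cycles is None:
            object.__setattr__(self, "hf_cycles", np.asarray(self.hf_freqs) / 2.0)

    def restricted(self, lo: float, hi: float) -> "TFRConfig":
        """Config keeping only low-frequency wavelets within [lo, hi] Hz."""
        freqs = np.asarray(self.freqs, dtype=float)
        keep = (freqs >= lo) & (freqs <= hi)
        return TFRConfig(
            freqs=freqs[keep],
            n_cycles=np.asarray(self.n_cycles, dtype=float)[keep],
            hf_freqs=self.hf_freqs,
            hf_cycles=self.hf_cycles,
            decim=self.decim,
        )


@dataclass
class TFRSet:
    """Trials x channels x freqs x times power with axes and tags."""

    power: np.ndarray  # (n_trials, n_channels, n_freqs, n_times)
    freqs: np.ndarray
    times: np.ndarray
    fs: float  # output sampling rate (input fs / decim)
    stream: str  # "total" | "PL" | "NPL"
    norm: str  # "raw" | "normalized_db"
    valid: np.ndarray  # (n_freqs, n_times) bool: outside wavelet edge zones
    labels: np.ndarray
    trial_ids: np.ndarray
    alignment: str

    def __post_init__(self) -> None:
        if self.norm == "raw" and np.any(self.power < 0):
            raise ValueError("raw power must be non-negative")

    def save(self, path) -> None:
        """Serialize to an .npz container with axes and stream/norm tags."""
        np.savez_compressed(
            path,
            power=self.power,
            freqs=self.freqs,
            times=self.times,
            fs=self.fs,
            stream=self.stream,
            norm=self.norm,
            valid=self.valid,
            labels=np.asarray(self.labels, dtype=str),
            trial_ids=np.asarray(self.trial_ids),
            alignment=self.alignment,
        )

    @classmethod
    def load(cls, path) -> "TFRSet":
        with np.load(path, allow_pickle=False) as z:
            return cls(
                power=z["power"],
                freqs=z["freqs"],
                times=z["times"],
                fs=float(z["fs"]),
                stream=str(z["stream"]),
                norm=str(z["norm"]),
                valid=z["valid"],
                labels=z["labels"],
                trial_ids=z["trial_ids"],
                alignment=str(z["alignment"]),
            )


def _edge_valid(
    times: np.ndarray, freqs: np.ndarray, n_cycles: np.ndarray
) -> np.ndarray:
    """Validity mask: False within half a wavelet span of either epoch edge."""
    half = np.asarray(n_cycles) / (2.0 * np.asarray(freqs))
    t0, t1 = times[0], times[-1]
    return (times[None, :] >= t0 + half[:, None]) & (times[None, :] <= t1 - half[:, None])


def morlet_power(
    epochs: EpochSet,
    cfg: TFRConfig | None = None,
    family: str = "lf",
    channel_chunk: int = 8,
) -> TFRSet:
    """Total Morlet wavelet power of each trial.

    Parameters
    ----------
    epochs : EpochSet
    cfg : TFRConfig
    family : {"lf", "hf"}
        Low-frequency (5-30 Hz) or high-gamma (80-200 Hz) wavelet family.
    channel_chunk : int
        Channels transformed per call, to bound peak memory.

    Raises
    ------
    ValueError
        If the epoch is shorter than the longest wavelet; the message names
        the offending frequency.
    """
    cfg = cfg or TFRConfig()
    if family == "lf":
        freqs, cycles = np.asarray(cfg.freqs, float), np.asarray(cfg.n_cycles, float)
    elif family == "hf":
        freqs, cycles = np.asarray(cfg.hf_freqs, float), np.asarray(cfg.hf_cycles, float)
    else:
        raise ValueError("family must be 'lf' or 'hf'")
    duration = epochs.times[-1] - epochs.times[0]
    spans = cycles / freqs
    too_long = spans > duration
    if np.any(too_long):
        f_bad = freqs[too_long][0]
        raise ValueError(
            f"epoch of {duration:.2f} s is shorter than the {f_bad:g} Hz wavelet "
            f"({spans[too_long][0]:.2f} s); lengthen the epoch or drop the frequency"
        )
    decim = cfg.decim
    out = []
    for c0 in range(0, epochs.n_channels, channel_chunk):
        chunk = epochs.data[:, c0 : c0 + channel_chunk].astype(np.float64)
        p = tfr_array_morlet(
            chunk,
            sfreq=epochs.fs,
            freqs=freqs,
            n_cycles=cycles,
            zero_mean=True,
            output="power",
            decim=decim,
        )
        out.append(p.astype(np.float32))
    power = np.concatenate(out, axis=1)
    times = epochs.times[::decim]
    return TFRSet(
        power=power,
        freqs=freqs,
        times=times,
        fs=epochs.fs / decim,
        stream="total",
        norm="raw",
        valid=_edge_valid(times, freqs, cycles),
        labels=epochs.labels,
        trial_ids=epochs.trial_ids,
        alignment=epochs.alignment,
    )


def evoked_median(epochs: EpochSet) -> EpochSet:
    """Across-trial median voltage at each timepoint (an evoked potential).

    The median (rather than mean) is robust to the occasional extreme trial;
    for identical trials it returns the trial itself, and for trials with
    uniformly random oscillatory phase it shrinks toward zero as the trial
    count grows.
    """
    if epochs.n_trials < 1:
        raise ValueError("need at least one trial")
    med = np.median(epochs.data, axis=0, keepdims=True)
    return EpochSet(
        data=med.astype(np.float32),
        times=epochs.times,
        fs=epochs.fs,
        labels=np.array(["evoked"]),
        trial_ids=np.array([-1]),
        channels=epochs.channels,
        alignment=epochs.alignment,
        provenance=epochs.provenance + ("evoked_median",),
    )


def pl_npl_power(
    epochs: EpochSet, cfg: TFRConfig | None = None, family: str = "lf"
) -> tuple[TFRSet, TFRSet]:
    """Phase-locked and non-phase-locked power streams.

    PL is the wavelet power of the evoked median (a single pseudo-trial);
    NPL transforms each trial after subtracting the evoked median.  The
    caller is expected to pass a single condition's epochs — the evoked
    potential is only meaningful within a condition.
    """
    if epochs.n_trials < 2:
        raise ValueError("PL/NPL decomposition needs at least two trials")
    evoked = evoked_median(epochs)
    pl = morlet_power(evoked, cfg, family=family)
    pl.stream = "PL"
    residual = EpochSet(
        data=epochs.data - evoked.data,
        times=epochs.times,
        fs=epochs.fs,
        labels=epochs.labels,
        trial_ids=epochs.trial_ids,
        channels=epochs.channels,
        alignment=epochs.alignment,
        provenance=epochs.provenance + ("evoked_subtracted",),
    )
    npl = morlet_power(residual, cfg, family=family)
    npl.stream = "NPL"
    return pl, npl


def concat_prepost_power(tfr_on: TFRSet, tfr_off: TFRSet) -> TFRSet:
    """Excise the stimulation period in the power domain.

    Wavelet power is computed on the full onset- and offset-aligned epochs
    separately (so no concatenation seam contaminates the transform); this
    then keeps the pre-onset half ([-5, 0) s) of the onset power and the
    post-offset half ([0, +5) s) of the offset power, pairing trials by id.
    On the result t >= 0 is time since stimulation offset.
    """
    if tfr_on.alignment != "onset" or tfr_off.alignment != "offset":
        raise ValueError("expected onset- and offset-aligned TFRSets")
    if tfr_on.norm != "raw" or tfr_off.norm != "raw":
        raise ValueError("concatenate raw power before normalization")
    ids_on, ids_off = list(tfr_on.trial_ids), list(tfr_off.trial_ids)
    if set(ids_on) != set(ids_off):
        raise ValueError("trial ids differ between onset and offset TFRs")
    order = [ids_off.index(i) for i in ids_on]
    pre = tfr_on.times < 0
    post = tfr_off.times >= 0
    power = np.concatenate(
        [tfr_on.power[:, :, :, pre], tfr_off.power[order][:, :, :, post]], axis=3
    )
    times = np.concatenate([tfr_on.times[pre], tfr_off.times[post]])
    valid = np.concatenate([tfr_on.valid[:, pre], tfr_off.valid[:, post]], axis=1)
    return TFRSet(
        power=power,
        freqs=tfr_on.freqs,
        times=times,
        fs=tfr_on.fs,
        stream=tfr_on.stream,
        norm="raw",
        valid=valid,
        labels=tfr_on.labels,
        trial_ids=tfr_on.trial_ids,
        alignment="concatenated",
    )
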