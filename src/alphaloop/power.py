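"""Median-based dB normalization, band summaries, and the spotlight selection.

Normalization follows a single-trial median baseline procedure: for each
wavelet frequency (1) every epoch is divided by its own median power over
the epoch, (2) the median across epochs is taken at each timepoint, (3) the
resulting trace is divided by the grand median of a -5 to -1 s pre-onset
baseline, and (4) the ratio is converted to decibels (10*log10).  Medians
are taken over edge-valid samples only, so wavelet edge attenuation cannot
bias the baseline.  The step-1 per-trial tensor is retained: resampling
procedures redraw trials and recompute steps 2-4 within every draw.

Bands are closed intervals on the discrete 1 Hz wavelet grid — alpha
8-15 Hz, beta 15-30 Hz, high gamma 80-200 Hz (15 Hz belongs to both alpha
and beta, as the ranges read).  Channel aggregation averages the normalized
dB traces across the selected electrodes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .channels import ChannelMap
from .tfr import TFRSet

__all__ = [
    "BandDef",
    "ALPHA",
    "BETA",
    "HGP",
    "BANDS",
    "NormalizedPower",
    "TrialBandPower",
    "normalize_median_db",
    "band_mean",
    "window_summary",
    "spotlight",
    "trial_band_power",
]


@dataclass(frozen=True)
class BandDef:
    """Closed frequency interval on the discrete wavelet grid."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError("band must satisfy lo < hi")

    def mask(self, freqs: np.ndarray) -> np.ndarray:
        m = (freqs >= self.lo) & (freqs <= self.hi)
        if not m.any():
            raise ValueError(
                f"band {self.name} [{self.lo}, {self.hi}] Hz is outside the "
                f"computed frequency grid {freqs.min():g}-{freqs.max():g} Hz"
            )
        return m


ALPHA = BandDef("alpha", 8.0, 15.0)
BETA = BandDef("beta", 15.0, 30.0)
HGP = BandDef("hgp", 80.0, 200.0)
BANDS = {"alpha": ALPHA, "beta": BETA, "hgp": HGP}


def _collapse(
    step1: np.ndarray,
    valid: np.ndarray,
    times: np.ndarray,
    baseline: tuple[float, float],
    trial_idx: np.ndarray | None = None,
) -> np.ndarray:
    """Steps 2-4 on a step-1 tensor: across-epoch median, baseline division, dB.

    ``step1``: (trials, ch, f, t); returns dB traces (ch, f, t).  Used both
    for the point estimate and inside every bootstrap/permutation draw.
    """
    sub = step1 if trial_idx is None else step1[trial_idx]
    med = np.median(sub, axis=0)  # (ch, f, t)
    in_base = (times >= baseline[0]) & (times <= baseline[1])
    n_f = med.shape[1]
    grand = np.empty(med.shape[:2])
    for fi in range(n_f):
        cols = in_base & valid[fi]
        if not cols.any():
            raise ValueError("baseline window has no valid samples")
        grand[:, fi] = np.median(med[:, fi, cols], axis=-1)
    if np.any(grand <= 0):
        raise ValueError("degenerate input: non-positive baseline median power")
    with np.errstate(divide="ignore"):
        return 10.0 * np.log10(med / grand[:, :, None])


def _median_last(a: np.ndarray) -> np.ndarray:
    """Median along the (contiguous) last axis via a single partition.

    Equivalent to ``np.median(a, axis=-1)`` for finite input but without
    the NaN bookkeeping, which dominates inside tight resampling loops.
    """
    n = a.shape[-1]
    k = n // 2
    if n % 2:
        return np.partition(a, k, axis=-1)[..., k]
    part = np.partition(a, (k - 1, k), axis=-1)
    return 0.5 * (part[..., k - 1] + part[..., k])


@dataclass
class NormalizedPower:
    """Per-condition normalized dB traces plus the resampling-ready tensor."""

    db: np.ndarray  # (ch, f, t) median-collapsed dB traces
    step1: np.ndarray  # (trials, ch, f, t) per-epoch-normalized power
    freqs: np.ndarray
    times: np.ndarray
    valid: np.ndarray
    baseline: tuple[float, float]
    stream: str
    labels: np.ndarray
    trial_ids: np.ndarray


def normalize_median_db(
    tfr: TFRSet, baseline: tuple[float, float] = (-5.0, -1.0)
) -> NormalizedPower:
    """Median/median/median-baseline normalization to decibels.

    See the module docstring for the four steps.  Raises on degenerate input
    (non-positive medians, e.g. an identically-zero epoch).
    """
    if tfr.norm != "raw":
        raise ValueError("input TFR is already normalized")
    if baseline[0] < tfr.times[0] or baseline[1] > 0:
        raise ValueError("baseline must lie within the pre-stimulation segment")
    power = tfr.power.astype(np.float64, copy=False)
    n_tr, n_ch, n_f, _ = power.shape
    epoch_med = np.empty((n_tr, n_ch, n_f))
    for fi in range(n_f):
        cols = tfr.valid[fi]
        if not cols.any():
            raise ValueError(f"no valid samples at {tfr.freqs[fi]:g} Hz")
        epoch_med[:, :, fi] = np.median(power[:, :, fi, cols], axis=-1)
    if np.any(epoch_med <= 0):
        raise ValueError("degenerate input: epoch with non-positive median power")
    step1 = (power / epoch_med[..., None]).astype(np.float32)
    db = _collapse(step1, tfr.valid, tfr.times, baseline)
    return NormalizedPower(
        db=db,
        step1=step1,
        freqs=tfr.freqs,
        times=tfr.times,
        valid=tfr.valid,
        baseline=baseline,
        stream=tfr.stream,
        labels=tfr.labels,
        trial_ids=tfr.trial_ids,
    )


def band_mean(
    db: np.ndarray | NormalizedPower, band: BandDef, freqs: np.ndarray | None = None
) -> np.ndarray:
    """Mean dB over the band's frequencies (inclusive endpoints).

    Accepts either a NormalizedPower (uses its own grid) or a raw array with
    frequencies on axis -2; returns the array with that axis averaged out.
    """
    if isinstance(db, NormalizedPower):
        freqs = db.freqs
        db = db.db
    if freqs is None:
        raise ValueError("freqs required when passing a bare array")
    return db[..., band.mask(np.asarray(freqs)), :].mean(axis=-2)


def window_summary(
    series: np.ndarray, times: np.ndarray, window: tuple[float, float] = (0.5, 1.0)
) -> np.ndarray | float:
    """Time-mean of a dB series within the post-offset summary window.

    ``series`` has time on the last axis; the window is a closed interval
    on the discrete time grid.  The default 0.5-1.0 s window summarizes the
    brief post-stimulation effect; a wider (0.5, 1.5) window is the standard
    robustness check.
    """
    times = np.asarray(times)
    if window[0] < times[0] or window[1] > times[-1]:
        raise ValueError(
            f"summary window {window} outside the epoch time range "
            f"[{times[0]:g}, {times[-1]:g}]"
        )
    cols = (times >= window[0]) & (times <= window[1])
    if not cols.any():
        raise ValueError("summary window contains no samples")
    out = np.asarray(series)[..., cols].mean(axis=-1)
    return float(out) if out.ndim == 0 else out


def spotlight(cmap: ChannelMap, radius: int = 2) -> np.ndarray:
    """Electrodes within Manhattan distance ``radius`` of the controller pair.

    Distance is measured on the grid to the nearer of the two controller
    electrodes; the pair itself is excluded, so radius 0 selects nothing.
    Only channels on the controller's own array are considered.
    """
    t = cmap.table
    ctrl_rows = t[t["controller"] | t["controller_ref"]]
    if len(ctrl_rows) != 2:
        raise ValueError("map does not contain the controller pair")
    arr = ctrl_rows["array"].iloc[0]
    pair_pos = list(zip(ctrl_rows["row"], ctrl_rows["col"]))
    out = []
    for idx, row in t.iterrows():
        if row["array"] != arr or bool(row["controller"]) or bool(row["controller_ref"]):
            continue
        d = min(
            abs(row["row"] - r) + abs(row["col"] - c) for r, c in pair_pos
        )
        if d <= radius:
            out.append(idx)
    return np.asarray(out, dtype=int)


class TrialBandPower:
    """Resampling-ready bundle: step-1 band power restricted to needed columns.

    Holds the per-trial normalized power for one condition / channel set /
    band, together with the column masks required to recompute the summary
    (steps 2-4, band mean, channel mean in dB, window mean) for any subset
    of trials — the unit of work inside bootstrap and permutation draws.
    Data is stored trials-last, (channels, freqs, times, trials), so the
    across-trial median inside each draw runs along a contiguous axis.

    ``baseline_stride`` thins the baseline columns used for the grand
    median (the power envelope varies over hundreds of ms, so neighbouring
    columns are nearly redundant); stride 1 uses every column.
    """

    def __init__(
        self,
        step1: np.ndarray,  # (trials, ch, f_band, t_kept)
        times: np.ndarray,
        valid: np.ndarray,  # (f_band, t_kept)
        baseline: tuple[float, float],
        window: tuple[float, float],
        baseline_stride: int = 1,
    ) -> None:
        self.step1 = step1
        self.times = times
        self.valid = valid
        self.baseline = baseline
        self.window = window
        self.baseline_stride = baseline_stride
        in_base = (times >= baseline[0]) & (times <= baseline[1])
        if not valid[:, in_base].all():
            # keep only baseline columns valid at every band frequency, so a
            # single column set serves all frequencies
            in_base &= valid.all(axis=0)
        base_cols = np.flatnonzero(in_base)[::baseline_stride]
        if base_cols.size == 0:
            raise ValueError("baseline window has no valid samples")
        win_cols = np.flatnonzero((times >= window[0]) & (times <= window[1]))
        if win_cols.size == 0:
            raise ValueError("summary window contains no samples")
        # the collapse only ever reads the (strided) baseline and window
        # columns, so store just those, trials-last for contiguous medians
        used = np.unique(np.concatenate([base_cols, win_cols]))
        self._base_cols = np.searchsorted(used, base_cols)
        self._win_cols = np.searchsorted(used, win_cols)
        self.step1T = np.ascontiguousarray(np.moveaxis(step1[:, :, :, used], 0, -1))

    @property
    def n_trials(self) -> int:
        return self.step1T.shape[-1]

    def _collapse_rows(self, idx: np.ndarray, chunk: int = 25) -> np.ndarray:
        """Steps 2-4 + band mean for index rows -> (draws, ch, t) band dB."""
        idx = np.atleast_2d(np.asarray(idx, dtype=int))
        n_ch, _, n_t = self.step1T.shape[:3]
        out = np.empty((idx.shape[0], n_ch, n_t))
        for c0 in range(0, idx.shape[0], chunk):
            rows = idx[c0 : c0 + chunk]
            sub = self.step1T[..., rows]  # (ch, f, t, B, n)
            med = _median_last(sub)  # (ch, f, t, B)
            grand = np.median(med[:, :, self._base_cols, :], axis=2)  # (ch, f, B)
            db = 10.0 * np.log10(med / grand[:, :, None, :])
            out[c0 : c0 + chunk] = np.moveaxis(db.mean(axis=1), -1, 0)
        return out

    def summary(self, trial_idx: np.ndarray | None = None) -> float:
        """Condition summary: window mean of the channel-averaged band dB."""
        idx = np.arange(self.n_trials) if trial_idx is None else trial_idx
        band_db = self._collapse_rows(idx)[0]  # (ch, t)
        return float(band_db.mean(axis=0)[self._win_cols].mean())

    def per_channel(self, trial_idx: np.ndarray | None = None) -> np.ndarray:
        """Per-electrode window summaries (for array-shuffle permutation)."""
        idx = np.arange(self.n_trials) if trial_idx is None else trial_idx
        band_db = self._collapse_rows(idx)[0]
        return band_db[:, self._win_cols].mean(axis=-1)

    def summaries(self, idx: np.ndarray, chunk: int = 25) -> np.ndarray:
        """Vectorized summaries for a (draws, n_sub) trial-index matrix.

        Equivalent to ``[self.summary(row) for row in idx]`` but collapses
        many resampling draws per call; used by the bootstrap and
        permutation schemes.
        """
        band_db = self._collapse_rows(idx, chunk=chunk)  # (B, ch, t)
        return band_db.mean(axis=1)[:, self._win_cols].mean(axis=-1)


def trial_band_power(
    norm: NormalizedPower,
    band: BandDef,
    window: tuple[float, float] = (0.5, 1.0),
    pad: float = 0.0,
    baseline_stride: int = 1,
) -> TrialBandPower:
    """Restrict a NormalizedPower to one band and the baseline+window columns.

    ``pad`` keeps extra seconds around the summary window (useful when a
    wider robustness window will be evaluated later).
    """
    fmask = band.mask(norm.freqs)
    in_base = (norm.times >= norm.baseline[0]) & (norm.times <= norm.baseline[1])
    in_win = (norm.times >= window[0] - pad) & (norm.times <= window[1] + pad)
    cols = in_base | in_win
    win_valid = norm.valid[np.ix_(fmask, (norm.times >= window[0]) & (norm.times <= window[1]))]
    if not win_valid.all():
        raise ValueError("summary window overlaps wavelet edge zones")
    return TrialBandPower(
        step1=norm.step1[:, :, fmask][:, :, :, cols],
        times=norm.times[cols],
        valid=norm.valid[np.ix_(fmask, cols)],
        baseline=norm.baseline,
        window=window,
        baseline_stride=baseline_stride,
    )
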