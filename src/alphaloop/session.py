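"""The Session container: continuous multi-channel recording + metadata.

A session couples a channels x samples voltage matrix (microvolt) with a
channel map (array membership, grid position, controller/bad flags), an
event table (stimulation on/off times with condition and block labels), and
the experiment kind (in vivo / in vitro).  On-disk form is a directory with
a JSON metadata document, a flat little-endian binary signal matrix, a CSV
event table, and an optional ground-truth sidecar.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .channels import ChannelMap

__all__ = ["Session", "read_session", "write_session", "validate_session"]

EVENT_COLUMNS = ["time_s", "kind", "condition", "block", "trial_id"]
CONDITIONS = ("open", "closed", "brain")


@dataclass
class Session:
    """Continuous multi-channel recording with events and channel map.

    Attributes
    ----------
    data : ndarray, shape (n_channels, n_samples), float32
        Voltage in microvolt.
    fs : float
        Sampling rate in Hz.
    channels : ChannelMap
    events : pandas.DataFrame
        Columns ``time_s, kind, condition, block, trial_id`` with kind in
        {stim_on, stim_off}; strictly increasing times, alternating on/off
        per trial.
    kind : str
        ``"in_vivo"`` or ``"in_vitro"`` (selects the trial-rejection limit).
    ground_truth : dict or None
        Sidecar record of injected effects / true stimulation durations.
    """

    data: np.ndarray
    fs: float
    channels: ChannelMap
    events: pd.DataFrame
    kind: str = "in_vivo"
    ground_truth: dict | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


def validate_session(session: Session) -> list[str]:
    """Return a list of violated invariants (empty when the session is valid)."""
    problems: list[str] = []
    if session.data.ndim != 2:
        problems.append(f"signal matrix must be 2-D, got ndim={session.data.ndim}")
        return problems
    if session.n_channels != len(session.channels):
        problems.append(
            f"channel count mismatch: matrix has {session.n_channels}, "
            f"map has {len(session.channels)}"
        )
    if session.kind not in ("in_vivo", "in_vitro"):
        problems.append(f"unknown experiment kind {session.kind!r}")
    ev = session.events
    missing = [c for c in EVENT_COLUMNS if c not in ev.columns]
    if missing:
        problems.append(f"event table missing columns {missing}")
        return problems
    times = ev["time_s"].to_numpy(dtype=float)
    if len(times) and np.any(np.diff(times) <= 0):
        problems.append("event times are not strictly increasing")
    bad_kind = set(ev["kind"]) - {"stim_on", "stim_off"}
    if bad_kind:
        problems.append(f"unknown event kinds {sorted(bad_kind)}")
    bad_cond = set(ev["condition"]) - set(CONDITIONS)
    if bad_cond:
        problems.append(f"unknown conditions {sorted(bad_cond)}")
    for trial_id, grp in ev.groupby("trial_id"):
        kinds = list(grp.sort_values("time_s")["kind"])
        if kinds != ["stim_on", "stim_off"]:
            problems.append(
                f"trial {trial_id}: expected one stim_on followed by one stim_off, "
                f"got {kinds}"
            )
    return problems


def _require_valid(session: Session) -> None:
    problems = validate_session(session)
    if problems:
        raise ValueError(
            "invalid session:\n" + "\n".join(f"  - {p}" for p in problems)
        )


def write_session(session: Session, path: str | Path) -> Path:
    """Write a session container directory; returns the directory path.

    The signal matrix is stored as flat little-endian float32 (C order,
    channels x samples); metadata as JSON; events as CSV.  Round-trips are
    bit-exact on the signal matrix.
    """
    _require_valid(session)
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    data = np.ascontiguousarray(session.data, dtype="<f4")
    data.tofile(path / "signals.dat")
    meta = {
        "sample_rate_hz": session.fs,
        "units": "microvolt",
        "kind": session.kind,
        "n_channels": int(data.shape[0]),
        "n_samples": int(data.shape[1]),
        "dtype": "float32",
        "byte_order": "little",
        "channel_map": session.channels.to_records(),
        "meta": session.meta,
    }
    (path / "metadata.json").write_text(json.dumps(meta, indent=1))
    session.events.to_csv(path / "events.csv", index=False)
    if session.ground_truth is not None:
        (path / "ground_truth.json").write_text(
            json.dumps(session.ground_truth, indent=1)
        )
    return path


def read_session(path: str | Path) -> Session:
    """Read and validate a session container directory.

    Raises ``ValueError`` listing every violated invariant if the container
    is inconsistent (truncated signal matrix, malformed event table, ...).
    """
    path = Path(path)
    meta = json.loads((path / "metadata.json").read_text())
    n_ch, n_samp = meta["n_channels"], meta["n_samples"]
    raw = np.fromfile(path / "signals.dat", dtype="<f4")
    if raw.size != n_ch * n_samp:
        raise ValueError(
            "invalid session:\n  - signal matrix length mismatch: metadata "
            f"declares {n_ch}x{n_samp}={n_ch * n_samp} values, file has {raw.size}"
        )
    data = raw.reshape(n_ch, n_samp)
    events = pd.read_csv(path / "events.csv")
    gt_path = path / "ground_truth.json"
    ground_truth = json.loads(gt_path.read_text()) if gt_path.exists() else None
    session = Session(
        data=data,
        fs=float(meta["sample_rate_hz"]),
        channels=ChannelMap.from_records(meta["channel_map"]),
        events=events,
        kind=meta["kind"],
        ground_truth=ground_truth,
        meta=meta.get("meta", {}),
    )
    _require_valid(session)
    return session
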