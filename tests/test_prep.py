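"""Epoching, trial rejection, channel selection, and pre/post concatenation."""

import numpy as np
import pandas as pd
import pytest

from alphaloop.channels import ChannelMap
from alphaloop.prep import (
    build_prepost,
    epoch_events,
    paired_trials,
    reject_trials,
    select_channels,
)
from alphaloop.session import Session

FS = 1000.0


def make_session(event_times, duration=120.0, n_channels=4, ramp=False):
    """Minimal session whose signal encodes the sample index (for losslessness)."""
    n = int(duration * FS)
    cmap = ChannelMap.grid(arrays=(1,)).subsample(n_channels, seed=0)
    if ramp:
        data = np.tile(np.arange(n, dtype=np.float32), (len(cmap), 1))
    else:
        data = np.zeros((len(cmap), n), dtype=np.float32)
    rows = []
    for tid, (t_on, t_off) in enumerate(event_times):
        rows.append(dict(time_s=t_on, kind="stim_on", condition="closed",
                         block=0, trial_id=tid))
        rows.append(dict(time_s=t_off, kind="stim_off", condition="closed",
                         block=0, trial_id=tid))
    events = pd.DataFrame(rows).sort_values("time_s", ignore_index=True)
    return Session(data=data, fs=FS, channels=cmap, events=events)


class TestEpoching:
    def test_one_epoch_per_event_with_labels(self):
        ses = make_session([(10, 19), (60, 70)])
        on = epoch_events(ses, "onset")
        off = epoch_events(ses, "offset")
        assert on.n_trials == 2 and off.n_trials == 2
        assert list(on.labels) == ["closed", "closed"]
        assert on.data.shape[2] == 10000  # half-open [-5, +5) at 1 kHz

    def test_events_near_edges_are_dropped_and_counted(self):
        ses = make_session([(3, 9), (30, 40), (110, 118)], duration=120.0)
        on = epoch_events(ses, "onset")  # first onset at 3 s lacks a 5 s pre-window
        assert on.n_trials == 2
        assert on.n_dropped == 1
        off = epoch_events(ses, "offset")  # last offset at 118 s lacks post-window
        assert off.n_dropped == 1

    def test_no_events_rejected(self):
        ses = make_session([(10, 19)])
        ses.events = ses.events[ses.events["kind"] == "stim_on"]
        with pytest.raises(ValueError, match="stim_off"):
            epoch_events(ses, "offset")

    def test_provenance_flags_rejection_only(self):
        ses = make_session([(10, 19)])
        assert "rejection_only" in epoch_events(ses, "onset").provenance


class TestRejection:
    def test_limits_in_vivo_and_in_vitro(self):
        ses = make_session([(10, 18.9), (60, 70.7), (110, 121.2)], duration=200.0)
        kept11 = reject_trials(ses.events, kind="in_vivo")
        assert list(kept11) == [0, 1]
        kept20 = reject_trials(ses.events, kind="in_vitro")
        assert list(kept20) == [0, 1, 2]

    def test_unpaired_events_rejected(self):
        ses = make_session([(10, 19)])
        ev = ses.events.drop(index=[1])
        with pytest.raises(ValueError, match="stim_off"):
            reject_trials(ev, kind="in_vivo")

    def test_empty_keep_set_is_allowed(self):
        ses = make_session([(10, 25)])
        assert len(reject_trials(ses.events, kind="in_vivo")) == 0

    def test_paired_trials_table(self):
        ses = make_session([(10, 19), (60, 69)])
        tab = paired_trials(ses.events)
        assert list(tab["t_on"]) == [10, 60]
        assert list(tab["t_off"]) == [19, 69]


class TestChannelSelection:
    def test_defaults_drop_controller_pair_and_bad(self):
        cmap = ChannelMap.grid(arrays=(1, 2, 3), bad=[(2, 3, 3), (3, 5, 5)])
        idx = cmap.indices(drop_controller=True, drop_bad=True)
        assert len(idx) == 96 * 3 - 2 - 2

    def test_array_restriction(self):
        cmap = ChannelMap.grid(arrays=(1, 2))
        idx = cmap.indices(array=1, drop_controller=True)
        assert len(idx) == 94
        assert (cmap.table.iloc[idx]["array"] == 1).all()

    def test_keep_flags_off_returns_everything(self):
        ses = make_session([(10, 19)])
        idx = select_channels(ses, drop_controller=False, drop_bad=False)
        assert len(idx) == ses.n_channels

    def test_empty_selection_rejected(self):
        cmap = ChannelMap.grid(arrays=(1,)).subsample(2, seed=0)  # pair only
        with pytest.raises(ValueError, match="empty"):
            select_channels(cmap, drop_controller=True)


class TestPrepost:
    def test_concatenation_is_lossless_on_raw_samples(self):
        """Concatenated data equals the raw pre-onset and post-offset samples."""
        ses = make_session([(20, 29)], ramp=True)
        on = epoch_events(ses, "onset")
        off = epoch_events(ses, "offset")
        cat = build_prepost(on, off)
        assert cat.data.shape[2] == 10000
        i_on, i_off = int(20 * FS), int(29 * FS)
        expected = np.concatenate(
            [np.arange(i_on - 5000, i_on), np.arange(i_off, i_off + 5000)]
        )
        assert np.array_equal(cat.data[0, 0], expected.astype(np.float32))
        # stimulation-period samples are absent
        stim_samples = set(range(i_on, i_off))
        assert stim_samples.isdisjoint(set(cat.data[0, 0].astype(int)))

    def test_pre_segment_equals_onset_first_half(self):
        ses = make_session([(20, 29)], ramp=True)
        on = epoch_events(ses, "onset")
        off = epoch_events(ses, "offset")
        cat = build_prepost(on, off)
        assert np.array_equal(cat.data[:, :, :5000], on.data[:, :, :5000])
        assert cat.alignment == "concatenated"

    def test_unmatched_trials_rejected(self):
        ses = make_session([(20, 29), (60, 69)], ramp=False)
        on = epoch_events(ses, "onset")
        off = epoch_events(ses, "offset").select_trials(np.array([0]))
        with pytest.raises(ValueError, match="trial ids"):
            build_prepost(on, off)

    def test_constant_fixture_stays_constant(self):
        ses = make_session([(20, 29)])
        ses.data += 7.0
        cat = build_prepost(epoch_events(ses, "onset"), epoch_events(ses, "offset"))
        assert np.all(cat.data == 7.0)


class TestSerialization:
    def test_epochset_roundtrip_preserves_data_and_provenance(self, tmp_path):
        ses = make_session([(20, 29)], ramp=True)
        epochs = epoch_events(ses, "onset")
        path = tmp_path / "epochs.npz"
        epochs.save(path)
        from alphaloop.prep import EpochSet

        back = EpochSet.load(path)
        assert np.array_equal(back.data, epochs.data)
        assert np.array_equal(back.times, epochs.times)
        assert back.provenance == epochs.provenance
        assert list(back.labels) == list(epochs.labels)
        assert back.channels.table.equals(epochs.channels.table)
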