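"""Median-dB normalization, band/window summaries, spotlight selection."""

import numpy as np
import pytest

from alphaloop.channels import ChannelMap
from alphaloop.power import (
    ALPHA,
    BETA,
    BandDef,
    TrialBandPower,
    band_mean,
    normalize_median_db,
    spotlight,
    trial_band_power,
    window_summary,
)
from alphaloop.tfr import TFRSet


def make_tfr(power, t0=-5.0, fs=100.0, freqs=None):
    """Raw TFRSet from a bare (trials, ch, f, t) array, everything valid."""
    power = np.asarray(power, dtype=np.float32)
    n_tr, _, n_f, n_t = power.shape
    freqs = np.asarray(freqs if freqs is not None else np.arange(8.0, 8.0 + n_f))
    times = t0 + np.arange(n_t) / fs
    return TFRSet(
        power=power,
        freqs=freqs,
        times=times,
        fs=fs,
        stream="total",
        norm="raw",
        valid=np.ones((n_f, n_t), dtype=bool),
        labels=np.array(["closed"] * n_tr),
        trial_ids=np.arange(n_tr),
        alignment="concatenated",
    )


class TestNormalization:
    def test_constant_power_normalizes_to_zero_db(self):
        tfr = make_tfr(np.full((4, 2, 3, 1000), 7.0))
        norm = normalize_median_db(tfr)
        assert np.allclose(norm.db, 0.0, atol=1e-6)

    def test_power_doubling_after_offset_reads_3db(self):
        power = np.ones((6, 1, 2, 1000))
        times_mask = np.arange(1000) >= 500  # t >= 0
        power[:, :, :, times_mask] = 2.0
        norm = normalize_median_db(make_tfr(power))
        post = norm.db[..., 600]
        pre = norm.db[..., 200]
        assert np.allclose(post, 10 * np.log10(2.0), atol=1e-6)
        assert np.allclose(pre, 0.0, atol=1e-6)

    def test_hand_computed_toy_tensor(self):
        """3 epochs x 4 timepoints against a literal four-step hand computation."""
        p = np.array(
            [[[[1.0, 2.0, 3.0, 4.0]]], [[[2.0, 4.0, 6.0, 8.0]]], [[[1.0, 1.0, 4.0, 4.0]]]]
        )  # (3 trials, 1 ch, 1 f, 4 t)
        tfr = make_tfr(p, t0=-2.0, fs=1.0)  # times -2, -1, 0, 1
        norm = normalize_median_db(tfr, baseline=(-2.0, -1.0))
        # step 1: per-epoch medians are 2.5, 5.0, 2.5
        s1 = np.array(
            [[0.4, 0.8, 1.2, 1.6], [0.4, 0.8, 1.2, 1.6], [0.4, 0.4, 1.6, 1.6]]
        )
        # step 2: across-epoch median per timepoint
        s2 = np.median(s1, axis=0)  # [0.4, 0.8, 1.2, 1.6]
        # step 3: baseline columns are t in {-2, -1} -> grand median 0.6
        expected = 10 * np.log10(s2 / np.median(s2[:2]))
        assert np.allclose(norm.db[0, 0], expected, atol=1e-6)

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        p = rng.random((5, 2, 3, 400)) + 0.1
        a = normalize_median_db(make_tfr(p))
        b = normalize_median_db(make_tfr(137.0 * p))
        assert np.allclose(a.db, b.db, atol=1e-5)

    def test_degenerate_zero_epoch_rejected(self):
        p = np.ones((3, 1, 1, 100))
        p[1] = 0.0
        with pytest.raises(ValueError, match="degenerate"):
            normalize_median_db(make_tfr(p))

    def test_normalized_input_rejected(self):
        tfr = make_tfr(np.ones((3, 1, 1, 100)))
        tfr.norm = "normalized_db"
        with pytest.raises(ValueError, match="already normalized"):
            normalize_median_db(tfr)


class TestBandAndWindow:
    def test_flat_spectrum_band_mean_equals_any_frequency(self):
        db = np.full((2, 10, 50), 1.7)
        out = band_mean(db, ALPHA, freqs=np.arange(6.0, 16.0))
        assert np.allclose(out, 1.7)

    def test_alpha_band_counts_eight_frequencies(self):
        freqs = np.arange(5.0, 31.0)
        assert ALPHA.mask(freqs).sum() == 8
        assert BETA.mask(freqs).sum() == 16  # 15 Hz belongs to both bands

    def test_band_outside_grid_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            band_mean(np.ones((1, 3, 10)), BandDef("hgp", 80, 200), freqs=np.arange(5.0, 8.0))

    def test_linear_ramp_window_mean(self):
        fs = 1000.0
        times = np.arange(0, 2.0, 1 / fs)
        series = np.clip(times, 0, 1.0)  # 0 -> 1 dB over (0, 1) s
        assert window_summary(series, times, (0.5, 1.0)) == pytest.approx(0.75, abs=1e-3)

    def test_constant_series_unchanged_and_window_validated(self):
        times = np.arange(0, 2.0, 0.01)
        assert window_summary(np.full(200, 0.3), times, (0.5, 1.5)) == pytest.approx(0.3)
        with pytest.raises(ValueError, match="outside"):
            window_summary(np.zeros(200), times, (1.5, 2.5))


class TestSpotlight:
    @staticmethod
    def brute_force(cmap, radius):
        t = cmap.table
        pair = t[t["controller"] | t["controller_ref"]]
        arr = pair["array"].iloc[0]
        pos = list(zip(pair["row"], pair["col"]))
        keep = []
        for idx, row in t.iterrows():
            if row["array"] != arr or row["controller"] or row["controller_ref"]:
                continue
            if min(abs(row["row"] - r) + abs(row["col"] - c) for r, c in pos) <= radius:
                keep.append(idx)
        return keep

    def test_radius_zero_is_empty(self):
        cmap = ChannelMap.grid(arrays=(1,))
        assert len(spotlight(cmap, radius=0)) == 0

    @pytest.mark.parametrize("pair", [(((4, 4), (4, 5))), (((0, 1), (0, 2)))])
    def test_matches_exhaustive_enumeration(self, pair):
        cmap = ChannelMap.grid(arrays=(1, 2), controller_pos=pair)
        got = sorted(spotlight(cmap, radius=2))
        assert got == sorted(self.brute_force(cmap, 2))

    def test_edge_pair_selects_fewer_than_interior(self):
        interior = ChannelMap.grid(arrays=(1,), controller_pos=((4, 4), (4, 5)))
        edge = ChannelMap.grid(arrays=(1,), controller_pos=((0, 1), (0, 2)))
        assert len(spotlight(edge, 2)) < len(spotlight(interior, 2))


class TestTrialBandPower:
    def test_batched_summaries_match_per_row_summary(self):
        rng = np.random.default_rng(4)
        p = rng.random((12, 2, 3, 600)).astype(np.float32) + 0.1
        tfr = make_tfr(p, t0=-5.0, fs=100.0, freqs=np.array([8.0, 10.0, 12.0]))
        tbp = trial_band_power(normalize_median_db(tfr), ALPHA)
        idx = rng.integers(0, 12, size=(7, 12))
        batched = tbp.summaries(idx)
        singles = [tbp.summary(row) for row in idx]
        assert np.allclose(batched, singles, atol=1e-9)

    def test_summary_window_must_be_edge_valid(self):
        p = np.ones((3, 1, 1, 600), dtype=np.float32)
        tfr = make_tfr(p, t0=-5.0, fs=100.0)
        tfr.valid[:, 540:] = False  # invalidate t >= 0.4 s
        with pytest.raises(ValueError, match="edge"):
            trial_band_power(normalize_median_db(tfr), BandDef("alpha", 8, 9))
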