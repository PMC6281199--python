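"""Filter design, frequency/phase response, loop phase, and discrete filtering."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import signal as sp_signal

from alphaloop.circuit import (
    FilterSpec,
    LoopConfig,
    apply_filter,
    design_mfb,
    discretize,
    filter_signal,
    frequency_response,
    loop_phase,
)
from alphaloop.circuit import _filter_phase_unwrapped


class TestDesign:
    def test_requested_parameters_are_realized(self):
        spec = design_mfb(12.0, 1.5, A0_mag=1.0, C=100e-9)
        assert spec.f0 == pytest.approx(12.0, rel=1e-9)
        assert spec.Q == pytest.approx(1.5, rel=1e-9)
        assert spec.A0 == pytest.approx(-1.0, rel=1e-9)
        # gain magnitude realized as R2 / (2 R1)
        assert spec.R2 / (2 * spec.R1) == pytest.approx(1.0, rel=1e-9)

    def test_center_gain_and_phase(self):
        spec = design_mfb(12.0, 1.5)
        mag, phase = frequency_response(spec, [12.0])
        assert mag[0] == pytest.approx(1.0, rel=1e-9)
        assert phase[0] == pytest.approx(180.0, abs=1e-6)

    def test_minus3db_bandwidth_is_f0_over_q(self):
        spec = design_mfb(12.0, 1.5)
        f = np.linspace(0.5, 60.0, 200001)
        mag, _ = frequency_response(spec, f)
        above = f[mag >= 1.0 / np.sqrt(2.0)]
        assert above[-1] - above[0] == pytest.approx(8.0, abs=1e-2)

    def test_unrealizable_design_raises(self):
        with pytest.raises(ValueError, match="2\\*Q\\^2 > A0_mag"):
            design_mfb(12.0, 0.5, A0_mag=1.0)
        for bad in ({"f0": -1}, {"Q": 0}, {"A0_mag": -2}, {"C": 0}):
            kwargs = {"f0": 12.0, "Q": 1.5, "A0_mag": 1.0, "C": 1e-7, **bad}
            with pytest.raises(ValueError):
                design_mfb(**kwargs)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        k=st.floats(0.01, 100.0),
        f0=st.floats(6.0, 25.0),
        q=st.floats(0.8, 5.0),
    )
    def test_impedance_scaling_invariance(self, k, f0, q):
        """Scaling all resistances by k and C by 1/k leaves (f0, Q, A0) fixed."""
        spec = design_mfb(f0, q, A0_mag=1.0)
        scaled = FilterSpec(spec.R1 * k, spec.R2 * k, spec.R3 * k, spec.C / k)
        assert scaled.f0 == pytest.approx(spec.f0, rel=1e-9)
        assert scaled.Q == pytest.approx(spec.Q, rel=1e-9)
        assert scaled.A0 == pytest.approx(spec.A0, rel=1e-9)

    def test_config_roundtrip(self):
        spec = design_mfb(12.0, 1.5)
        back = FilterSpec.from_config(spec.to_config())
        assert back == spec


class TestResponse:
    def test_bandpass_limits(self, alpha_spec):
        mag, _ = frequency_response(alpha_spec, [1e-3, 1e5])
        assert mag[0] < 1e-3 and mag[1] < 1e-3

    def test_center_magnitude_is_r2_over_2r1(self):
        spec = design_mfb(10.0, 2.0, A0_mag=3.0)
        mag, _ = frequency_response(spec, [spec.f0])
        assert mag[0] == pytest.approx(spec.R2 / (2 * spec.R1), rel=1e-9)

    def test_phase_reported_in_0_360(self, alpha_spec):
        _, phase = frequency_response(alpha_spec, np.linspace(1, 100, 500))
        assert np.all((phase >= 0) & (phase < 360))

    def test_phase_monotone_decreasing_across_passband(self, alpha_spec):
        f = np.linspace(8.0, 16.0, 400)
        phi = _filter_phase_unwrapped(alpha_spec, f)
        assert np.all(np.diff(phi) < 0)

    def test_rejects_nonpositive_frequency(self, alpha_spec):
        with pytest.raises(ValueError):
            frequency_response(alpha_spec, [0.0])


class TestLoopPhase:
    def test_delay_contribution(self, alpha_spec):
        loop = LoopConfig(digital_delay=0.042)
        delay_only = loop_phase(alpha_spec, loop, 11.6) - loop_phase(
            alpha_spec, LoopConfig(digital_delay=0.0), 11.6
        )
        assert round(delay_only) == 175

    def test_zero_delay_is_filter_phase_only(self, alpha_spec):
        total = loop_phase(alpha_spec, LoopConfig(digital_delay=0.0), 12.0)
        assert total == pytest.approx(180.0, abs=1e-9)

    def test_delays_add_exactly(self, alpha_spec):
        f = 10.3
        p1 = loop_phase(alpha_spec, LoopConfig(digital_delay=0.02), f)
        p2 = loop_phase(alpha_spec, LoopConfig(digital_delay=0.03), f)
        p12 = loop_phase(alpha_spec, LoopConfig(digital_delay=0.05), f)
        p0 = loop_phase(alpha_spec, LoopConfig(digital_delay=0.0), f)
        assert p1 + p2 - p0 == pytest.approx(p12, abs=1e-9)

    def test_unwrapped_and_increasing_with_frequency(self, alpha_spec):
        f = np.linspace(5.0, 30.0, 200)
        total = loop_phase(alpha_spec, LoopConfig(), f)
        assert np.all(total >= 0)
        assert np.all(np.diff(total) > 0)


class TestDiscrete:
    def test_matches_analytic_response_5_to_30hz(self, alpha_spec):
        fs = 1000.0
        b, a = discretize(alpha_spec, fs)
        f = np.arange(5.0, 30.5, 0.5)
        _, h = sp_signal.freqz(b, a, worN=f, fs=fs)
        mag_a, phase_a = frequency_response(alpha_spec, f)
        assert np.abs(h) == pytest.approx(mag_a, rel=0.01)
        phase_d = np.degrees(np.angle(h)) % 360.0
        diff = (phase_d - phase_a + 180.0) % 360.0 - 180.0
        assert np.max(np.abs(diff)) < 2.0

    def test_low_sample_rate_rejected(self, alpha_spec):
        with pytest.raises(ValueError, match="too low"):
            discretize(alpha_spec, 100.0)

    def test_zero_in_zero_out(self, alpha_spec):
        out = apply_filter(np.zeros(1000), 1000.0, alpha_spec, LoopConfig())
        assert np.all(out == 0)

    def test_sinusoid_steady_state_amplitude_and_phase(self, alpha_spec):
        """A 12 Hz tone passes at unit gain, shifted by the loop phase."""
        fs, f0 = 1000.0, 12.0
        loop = LoopConfig(command_limit=10.0)
        t = np.arange(0, 30.0, 1 / fs)
        x = np.sin(2 * np.pi * f0 * t)
        y = apply_filter(x, fs, alpha_spec, loop)
        tail = slice(int(20 * fs), None)
        assert np.max(np.abs(y[tail])) == pytest.approx(1.0, abs=0.02)
        # phase shift via complex demodulation
        ref = np.exp(-2j * np.pi * f0 * t)
        phase_in = np.angle(np.mean(x[tail] * ref[tail]))
        phase_out = np.angle(np.mean(y[tail] * ref[tail]))
        shift = np.degrees(phase_in - phase_out) % 360.0
        expected = loop_phase(alpha_spec, loop, f0) % 360.0
        diff = (shift - expected + 180.0) % 360.0 - 180.0
        assert abs(diff) < 2.0

    def test_command_clipped_to_limit(self, alpha_spec):
        fs = 1000.0
        loop = LoopConfig(command_limit=0.5)
        t = np.arange(0, 5.0, 1 / fs)
        y = apply_filter(10.0 * np.sin(2 * np.pi * 12.0 * t), fs, alpha_spec, loop)
        assert np.max(np.abs(y)) <= 0.5

    def test_nonfinite_signal_rejected(self, alpha_spec):
        x = np.zeros(100)
        x[3] = np.nan
        with pytest.raises(ValueError):
            filter_signal(x, 1000.0, alpha_spec)
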