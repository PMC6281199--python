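"""Analog feedback electronics: the inverting MFB band-pass filter and loop timing.

The feedback chain is modelled as a single-stage multiple-feedback (MFB)
second-order band-pass filter (equal capacitors), followed by a pure digital
delay and a hard saturation at the stimulator command limit.  The MFB
topology is naturally inverting, so the filter contributes ~180 deg of phase
at its center frequency; the digital recording/DAC chain contributes a pure
delay (42 ms by default).  Around the alpha band the two contributions sum
to ~360 deg, i.e. positive feedback that reinforces an ongoing oscillation.

With both capacitors equal to ``C`` the transfer function is

    H(s) = -(s / (R1 C)) / (s^2 + (2 / (R2 C)) s + (R1 + R3) / (R1 R2 R3 C^2))

from which the derived quantities are

    w0^2 = (R1 + R3) / (R1 R2 R3 C^2)        center frequency
    Q    = w0 R2 C / 2                       quality factor (= f0 / bandwidth)
    A0   = -R2 / (2 R1)                      midband gain (negative: inverting)
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal as sp_signal

__all__ = [
    "FilterSpec",
    "LoopConfig",
    "design_mfb",
    "frequency_response",
    "loop_phase",
    "filter_signal",
    "apply_filter",
]

_TWO_PI = 2.0 * math.pi


@dataclass(frozen=True)
class FilterSpec:
    """Component values of an equal-capacitor MFB band-pass stage.

    Parameters
    ----------
    R1, R2, R3 : float
        Resistances in ohm (input, feedback, and shunt-to-ground resistor).
    C : float
        Capacitance in farad; both capacitors of the stage are equal.
    """

    R1: float
    R2: float
    R3: float
    C: float

    def __post_init__(self) -> None:
        for name in ("R1", "R2", "R3", "C"):
            value = getattr(self, name)
            if not (np.isfinite(value) and value > 0):
                raise ValueError(f"{name} must be strictly positive, got {value!r}")

    # -- derived quantities -------------------------------------------------

    @property
    def w0(self) -> float:
        """Angular center frequency (rad/s)."""
        return math.sqrt((self.R1 + self.R3) / (self.R1 * self.R2 * self.R3)) / self.C

    @property
    def f0(self) -> float:
        """Center frequency (Hz)."""
        return self.w0 / _TWO_PI

    @property
    def Q(self) -> float:
        """Quality factor, f0 divided by the -3 dB bandwidth."""
        return self.w0 * self.R2 * self.C / 2.0

    @property
    def A0(self) -> float:
        """Midband gain; negative because the topology is inverting."""
        return -self.R2 / (2.0 * self.R1)

    @property
    def bandwidth(self) -> float:
        """-3 dB bandwidth in Hz (= f0 / Q)."""
        return self.f0 / self.Q

    # -- s-domain coefficients ---------------------------------------------

    def analog_ba(self) -> tuple[np.ndarray, np.ndarray]:
        """Numerator/denominator of H(s) in physical (rad/s) units."""
        b = np.array([-1.0 / (self.R1 * self.C), 0.0])
        a = np.array(
            [
                1.0,
                2.0 / (self.R2 * self.C),
                (self.R1 + self.R3) / (self.R1 * self.R2 * self.R3 * self.C**2),
            ]
        )
        return b, a

    # -- serialization -------------------------------------------------------

    def to_config(self) -> dict[str, float]:
        """Flat key-value block of the component values in SI units."""
        return {"R1": self.R1, "R2": self.R2, "R3": self.R3, "C": self.C}

    @classmethod
    def from_config(cls, config: dict[str, float]) -> "FilterSpec":
        return cls(R1=config["R1"], R2=config["R2"], R3=config["R3"], C=config["C"])


@dataclass(frozen=True)
class LoopConfig:
    """Timing and scaling of the rest of the feedback chain.

    Parameters
    ----------
    digital_delay : float
        Pure delay of the digital recording/conversion chain in seconds
        (default 42 ms, i.e. 175 deg at 11.6 Hz).
    stim_gain : float
        Stimulator transconductance, ampere per commanded volt
        (default 2e-3: 2 mA per applied volt).
    command_limit : float
        Hard saturation of the command voltage in volt (default 0.5 V,
        giving a +/-1 mA stimulation range at the default gain).
    sample_rate : float
        Sampling rate of the digitized chain in Hz.
    input_gain : float
        Gain from the recorded LFP (microvolt) to the filter input voltage
        (volt); stands in for the titrated DAC/pre-amplifier gain of the
        recording chain.
    """

    digital_delay: float = 0.042
    stim_gain: float = 2e-3
    command_limit: float = 0.5
    sample_rate: float = 1000.0
    input_gain: float = 1e-3

    def __post_init__(self) -> None:
        if self.digital_delay < 0:
            raise ValueError("digital_delay must be >= 0")
        if self.stim_gain <= 0:
            raise ValueError("stim_gain must be > 0")
        if self.command_limit <= 0:
            raise ValueError("command_limit must be > 0")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be > 0")

    @property
    def delay_samples(self) -> int:
        return int(round(self.digital_delay * self.sample_rate))


def design_mfb(f0: float, Q: float, A0_mag: float = 1.0, C: float = 100e-9) -> FilterSpec:
    """Design an equal-capacitor MFB band-pass stage from target parameters.

    Parameters
    ----------
    f0 : float
        Center frequency in Hz.
    Q : float
        Quality factor (f0 / bandwidth); the canonical alpha design uses
        f0 = 12 Hz, Q = 1.5 for an 8 Hz passband (8-16 Hz).
    A0_mag : float
        Magnitude of the midband gain (the realized gain is -A0_mag).
    C : float
        Capacitor value in farad (free design choice).

    Returns
    -------
    FilterSpec

    Raises
    ------
    ValueError
        If any parameter is non-positive or if ``2 Q^2 <= A0_mag`` (shunt
        resistor R3 would be non-positive; the design is unrealizable).
    """
    if f0 <= 0:
        raise ValueError("f0 must be > 0")
    if Q <= 0:
        raise ValueError("Q must be > 0")
    if A0_mag <= 0:
        raise ValueError("A0_mag must be > 0")
    if C <= 0:
        raise ValueError("C must be > 0")
    if 2.0 * Q**2 <= A0_mag:
        raise ValueError(
            f"unrealizable design: requires 2*Q^2 > A0_mag "
            f"(got 2*{Q}^2 = {2 * Q**2} <= {A0_mag}); R3 would be non-positive"
        )
    w0 = _TWO_PI * f0
    R2 = 2.0 * Q / (w0 * C)
    R1 = Q / (A0_mag * w0 * C)
    R3 = Q / (w0 * C * (2.0 * Q**2 - A0_mag))
    return FilterSpec(R1=R1, R2=R2, R3=R3, C=C)


def frequency_response(
    spec: FilterSpec, freqs: np.ndarray | list[float]
) -> tuple[np.ndarray, np.ndarray]:
    """Magnitude and phase of the filter stage at the given frequencies.

    Phase is reported in degrees in [0, 360) with the inversion included,
    so the response at the center frequency is exactly 180 deg.

    Parameters
    ----------
    spec : FilterSpec
    freqs : array-like of float
        Frequencies in Hz, all strictly positive.

    Returns
    -------
    magnitude : ndarray
    phase_deg : ndarray, degrees in [0, 360)
    """
    freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
    if np.any(freqs <= 0):
        raise ValueError("all frequencies must be > 0")
    b, a = spec.analog_ba()
    _, h = sp_signal.freqs(b, a, worN=_TWO_PI * freqs)
    magnitude = np.abs(h)
    phase_deg = np.degrees(np.angle(h)) % 360.0
    return magnitude, phase_deg


def _filter_phase_unwrapped(spec: FilterSpec, freqs: np.ndarray) -> np.ndarray:
    """Continuous filter-stage phase in degrees, inversion counted as +180.

    Runs from 270 deg (f -> 0) through 180 deg at f0 down to 90 deg
    (f -> inf); monotonically decreasing in frequency.
    """
    w = _TWO_PI * freqs
    w0 = spec.w0
    bw = w0 / spec.Q
    # non-inverted band-pass phase: 90 deg - atan2(bw*w, w0^2 - w^2)
    phi = 90.0 - np.degrees(np.arctan2(bw * w, w0**2 - w**2))
    return phi + 180.0


def loop_phase(spec: FilterSpec, loop: LoopConfig, f: float | np.ndarray) -> float | np.ndarray:
    """Total unwrapped loop phase (degrees) at frequency ``f``.

    Sum of the filter-stage phase (inversion included, continuous across the
    passband) and the linear phase of the digital delay, ``360 * f * delay``.
    For the canonical alpha design this is ~360 deg at 11.6 Hz.
    """
    f_arr = np.atleast_1d(np.asarray(f, dtype=float))
    if np.any(f_arr <= 0):
        raise ValueError("f must be > 0")
    total = _filter_phase_unwrapped(spec, f_arr) + 360.0 * f_arr * loop.digital_delay
    return float(total[0]) if np.isscalar(f) or np.ndim(f) == 0 else total


def discretize(spec: FilterSpec, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Bilinear-transform digital (b, a) with frequency pre-warping at f0.

    Pre-warping pins the discrete response at the center frequency to the
    analog one, preserving the 180 deg center phase.
    """
    if fs < 10.0 * spec.f0:
        raise ValueError(
            f"sample rate {fs} Hz too low for f0 = {spec.f0:.3g} Hz; need fs >= 10*f0 "
            "for a valid discretization"
        )
    b, a = spec.analog_ba()
    w0 = spec.w0
    # scipy's bilinear substitutes s = 2*fs_eff*(z-1)/(z+1); choosing
    # 2*fs_eff = w0 / tan(w0 / (2 fs)) maps analog w0 exactly onto digital w0.
    fs_eff = w0 / (2.0 * math.tan(w0 / (2.0 * fs)))
    return sp_signal.bilinear(b, a, fs=fs_eff)


def filter_signal(x: np.ndarray, fs: float, spec: FilterSpec) -> np.ndarray:
    """Causally apply the discretized filter stage alone (no delay, no clip)."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("signal must be finite")
    b, a = discretize(spec, fs)
    return sp_signal.lfilter(b, a, x)


def apply_filter(
    x: np.ndarray, fs: float, spec: FilterSpec, loop: LoopConfig
) -> np.ndarray:
    """Full command chain: filter stage, digital delay, hard saturation.

    The input is filtered causally with the bilinear-discretized stage,
    delayed by ``round(digital_delay * fs)`` samples (zero-padded at the
    start), and clipped to ``+/- command_limit``.

    Parameters
    ----------
    x : ndarray
        Sampled input voltage series (volt).
    fs : float
        Sampling rate in Hz; must be at least 10 * f0.
    spec, loop : FilterSpec, LoopConfig

    Returns
    -------
    ndarray
        Command voltage series, same length as the input.
    """
    y = filter_signal(x, fs, spec)
    d = int(round(loop.digital_delay * fs))
    if d > 0:
        y = np.concatenate([np.zeros(d), y[:-d]])
    return np.clip(y, -loop.command_limit, loop.command_limit)
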