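"""Seeded noise primitives shared by the simulator and the synthetic generator."""

from __future__ import annotations

import numpy as np
from scipy import fft as sp_fft
from scipy import signal as sp_signal


def pink_noise(
    n: int, fs: float, rng: np.random.Generator, exponent: float = 1.0, rms: float = 1.0
) -> np.ndarray:
    """Gaussian noise with a 1/f**exponent power spectrum, scaled to ``rms``.

    Spectral shaping is done in the frequency domain (padded to a fast FFT
    length, then truncated); the DC bin is zeroed.
    """
    n_fft = sp_fft.next_fast_len(n)
    white = rng.standard_normal(n_fft)
    spec = sp_fft.rfft(white)
    freqs = sp_fft.rfftfreq(n_fft, d=1.0 / fs)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-exponent / 2.0)
    x = sp_fft.irfft(spec * shape, n=n_fft)[:n]
    std = x.std()
    if std > 0:
        x *= rms / std
    return x


def band_noise(
    n: int,
    fs: float,
    rng: np.random.Generator,
    lo: float,
    hi: float,
    rms: float = 1.0,
    order: int = 2,
) -> np.ndarray:
    """Narrow-band Gaussian noise: white noise band-passed to [lo, hi] Hz.

    Zero-phase filtering (forward-backward Butterworth) so the band edges do
    not introduce a net phase shift; scaled to the requested ``rms``.
    """
    sos = sp_signal.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = sp_signal.sosfiltfilt(sos, rng.standard_normal(n))
    std = x.std()
    if std > 0:
        x *= rms / std
    return x
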