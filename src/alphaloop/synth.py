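"""Statistical synthetic-session generator with known ground-truth effects.

Unlike the dynamical simulator, this generator has no plant: each channel is
1/f background noise plus a per-array shared alpha rhythm (narrow-band
8-15 Hz filtered Gaussian noise, not a sinusoid, because real post-stimulus
changes are broad-band across alpha).  Injected effects multiply a chosen
band's power by 10^(dB/10) for a fixed interval after each stimulation
offset of a chosen condition and array, which is exactly the quantity the
analysis pipeline estimates — so recovery of ``effect_db`` is a closed-loop
check of the whole pipeline.

During each stimulation period single-ended channels are clamped to an
amplifier rail (saturation artifact); the bipolar controller pair stays
clean.  Event times mark desaturation: immediate in vivo, lagged by several
seconds in the saline (in vitro) generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from ._noise import band_noise, pink_noise
from .channels import ChannelMap
from .plant import TrialSchedule, trials_to_events
from .session import Session

__all__ = ["EffectSpec", "SynthNoise", "generate_session", "generate_saline_session"]

BAND_RANGES = {"alpha": (8.0, 15.0), "beta": (15.0, 30.0), "hgp": (80.0, 200.0)}


@dataclass(frozen=True)
class EffectSpec:
    """Ground-truth band-power perturbation injected after stimulation offsets.

    ``effect_db`` multiplies the band's power by ``10**(effect_db/10)`` on
    every channel of ``array`` from ``onset_after_offset`` to
    ``onset_after_offset + duration`` seconds after each offset of trials in
    ``condition``.  Magnitudes of ~0.1-0.5 dB mimic realistic brief
    after-effects of short stimulation.
    """

    condition: str
    array: int
    band: str
    effect_db: float
    onset_after_offset: float = 0.0
    duration: float = 1.0

    def __post_init__(self) -> None:
        if self.band not in BAND_RANGES:
            raise ValueError(f"band must be one of {sorted(BAND_RANGES)}")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")

    def to_record(self) -> dict:
        return {
            "condition": self.condition,
            "array": self.array,
            "band": self.band,
            "effect_db": self.effect_db,
            "onset_after_offset": self.onset_after_offset,
            "duration": self.duration,
        }


@dataclass(frozen=True)
class SynthNoise:
    """Noise/signal levels of the generator, in microvolt.

    ``alpha_rms`` sets the total alpha-rhythm amplitude per channel;
    ``alpha_shared_frac`` is the fraction of rhythm *power* carried by a
    per-array shared component (inter-electrode alpha coherence — electrodes
    millimetres apart see partially, not perfectly, coherent rhythms);
    ``pink_rms`` the independent per-channel 1/f noise.  Default levels put
    total signals on the few-hundred-microvolt scale typical of array LFP
    recordings, with the alpha peak well above the in-band background.
    """

    alpha_rms: float = 75.0
    alpha_shared_frac: float = 0.5
    pink_rms: float = 50.0
    pink_exponent: float = 1.0
    gain_jitter: float = 0.1
    saturation_rail: float = 3000.0
    bad_channel_noise: float = 0.5


def _effect_envelope(
    n: int,
    fs: float,
    trials: pd.DataFrame,
    effect: EffectSpec,
    ramp: float = 0.02,
) -> np.ndarray:
    """0/1 envelope of the effect windows with raised-cosine edges."""
    env = np.zeros(n)
    n_ramp = max(1, int(ramp * fs))
    edge = 0.5 * (1 - np.cos(np.linspace(0, np.pi, n_ramp)))
    for _, tr in trials.iterrows():
        if tr["condition"] != effect.condition:
            continue
        i0 = int((tr["t_off"] + effect.onset_after_offset) * fs)
        i1 = min(int(i0 + effect.duration * fs), n)
        if i0 >= n:
            continue
        env[i0:i1] = 1.0
        env[i0 : i0 + n_ramp] = edge[: max(0, min(n_ramp, i1 - i0))]
        if i1 - n_ramp > i0:
            env[i1 - n_ramp : i1] = edge[::-1][: i1 - (i1 - n_ramp)]
    return env


def generate_session(
    effects: list[EffectSpec],
    schedule: TrialSchedule,
    cmap: ChannelMap,
    noise: SynthNoise | None = None,
    seed: int = 0,
    fs: float = 1000.0,
    kind: str = "in_vivo",
    alpha_on: bool = True,
    desaturation_lag: tuple[float, float] | None = None,
) -> Session:
    """Build a synthetic session with the given injected effects.

    Parameters
    ----------
    effects : list of EffectSpec
        Ground-truth perturbations; must reference arrays present in the map
        and conditions present in the schedule.
    schedule : TrialSchedule
    cmap : ChannelMap
        Channel layout; use ``ChannelMap.grid(...)`` for full 96-electrode
        arrays or ``.subsample(...)`` for scaled-down studies.
    noise : SynthNoise
    seed : int
        Seeds all randomness; identical seeds give identical sessions.
    alpha_on : bool
        If False no oscillatory component is generated (saline emulation).
    desaturation_lag : (lo, hi) or None
        If set, amplifier desaturation after each stimulation lags by a
        uniform draw from this range (seconds) and the offset *event* is
        marked at desaturation, as in bath recordings.

    Returns
    -------
    Session
        With ``ground_truth`` sidecar recording effects and true trial times.
    """
    noise = noise or SynthNoise()
    rng = np.random.default_rng(seed)
    trials = schedule.realize(rng)
    known_arrays = set(cmap.arrays)
    known_conditions = set(schedule.block_conditions)
    for eff in effects:
        if eff.array not in known_arrays:
            raise ValueError(f"effect references unknown array {eff.array}")
        if eff.condition not in known_conditions:
            raise ValueError(f"effect references unscheduled condition {eff.condition!r}")

    # physical stimulation interval vs marked (desaturation) offset event
    trials = trials.copy()
    trials["t_sat_end"] = trials["t_off"]
    if desaturation_lag is not None:
        lo, hi = desaturation_lag
        lags = rng.uniform(lo, hi, size=len(trials))
        trials["t_sat_end"] = trials["t_off"] + lags
        trials["t_off"] = trials["t_sat_end"]
    n = int(round((trials["t_off"].max() + schedule.rest_duration) * fs))

    table = cmap.table
    n_ch = len(table)
    data = np.empty((n_ch, n), dtype=np.float32)

    sh = np.sqrt(noise.alpha_shared_frac)
    idio = np.sqrt(1.0 - noise.alpha_shared_frac)
    alpha_shared = {
        arr: band_noise(n, fs, rng, 8.0, 15.0, rms=noise.alpha_rms * sh)
        if alpha_on
        else 0.0
        for arr in cmap.arrays
    }

    # per-(array, band) effect gain envelopes, applied to the band component
    env_by_target: dict[tuple[int, str], np.ndarray] = {}
    for eff in effects:
        key = (eff.array, eff.band)
        g_amp = 10.0 ** (eff.effect_db / 20.0)
        env = _effect_envelope(n, fs, trials, eff)
        env_by_target[key] = env_by_target.get(key, np.zeros(n)) + (g_amp - 1.0) * env

    # The injection filter has a flat passband widened by roughly one wavelet
    # spectral sigma beyond the nominal band, so every discrete wavelet inside
    # the band sees fully scaled content (edge wavelets integrate ~1 Hz past
    # the boundary); power strictly inside [lo, hi] scales by exactly
    # 10^(effect_db/10).  Linear-phase FIR applied centred => zero phase.
    band_fir = {}
    for band in {b for (_, b) in env_by_target}:
        lo, hi = BAND_RANGES[band]
        pad = 3.0 if band == "hgp" else 1.2
        taps = 1201 if band == "hgp" else 3501
        band_fir[band] = sp_signal.firwin(
            taps, (lo - pad, hi + pad), pass_zero=False, fs=fs
        )

    sat_windows = [
        (int(tr["t_on"] * fs), int(tr["t_sat_end"] * fs)) for _, tr in trials.iterrows()
    ]
    rail_sign = rng.choice([-1.0, 1.0], size=n_ch)

    ctrl_like = (table["controller"] | table["controller_ref"]).to_numpy()
    bad = table["bad"].to_numpy()
    arrays_col = table["array"].to_numpy()
    gains = 1.0 + noise.gain_jitter * rng.standard_normal(n_ch)

    for i in range(n_ch):
        if bad[i]:
            data[i] = noise.bad_channel_noise * rng.standard_normal(n)
            continue
        x = gains[i] * alpha_shared[arrays_col[i]] + pink_noise(
            n, fs, rng, exponent=noise.pink_exponent, rms=noise.pink_rms
        )
        if alpha_on and idio > 0:
            x = x + gains[i] * band_noise(
                n, fs, rng, 8.0, 15.0, rms=noise.alpha_rms * idio
            )
        for (arr, band), env in env_by_target.items():
            if arr != arrays_col[i]:
                continue
            comp = sp_signal.oaconvolve(x, band_fir[band], mode="same")
            x = x + env * comp
        if not ctrl_like[i]:
            for j0, j1 in sat_windows:
                x[j0:j1] = rail_sign[i] * noise.saturation_rail
        data[i] = x

    ground_truth = {
        "seed": seed,
        "effects": [e.to_record() for e in effects],
        "trials": trials.drop(columns=["t_sat_end"]).to_dict(orient="records"),
    }
    return Session(
        data=data,
        fs=fs,
        channels=cmap,
        events=trials_to_events(trials),
        kind=kind,
        ground_truth=ground_truth,
        meta={"seed": seed, "generator": "synth"},
    )


def generate_saline_session(
    schedule: TrialSchedule,
    cmap: ChannelMap,
    noise: SynthNoise | None = None,
    seed: int = 0,
    fs: float = 1000.0,
    desaturation_lag: tuple[float, float] = (3.0, 9.5),
) -> Session:
    """Saline-beaker control session: no oscillator, slow desaturation.

    Channels carry only 1/f noise; the amplifier takes several extra seconds
    to desaturate after each stimulation (median elapsed on->off time around
    16.5 s), so the in vivo trial-rejection limit of 11 s discards most
    trials while the in vitro limit of 20 s retains them.
    """
    return generate_session(
        effects=[],
        schedule=schedule,
        cmap=cmap,
        noise=noise,
        seed=seed,
        fs=fs,
        kind="in_vitro",
        alpha_on=False,
        desaturation_lag=desaturation_lag,
    )
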