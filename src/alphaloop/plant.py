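"""Closed-loop experiment simulator: stochastic alpha oscillator under feedback.

The "plant" standing in for the cortical alpha generator is an AR(2)
resonator — the sampled equivalent of a noise-driven damped harmonic
oscillator — with a spectral peak at ``natural_freq`` superposed on a 1/f
background.  Feedback current enters as an additive drive term
(``coupling`` converts ampere to drive units); no tissue model is assumed.

When the total loop phase (filter inversion + digital delay) is close to a
multiple of 360 deg at the oscillator frequency, the fed-back stimulation
arrives in phase with the endogenous rhythm and pumps energy into it
(constructive interference); an extra half-cycle of phase reverses the
sign of the effect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from ._noise import pink_noise
from .channels import ChannelMap
from .circuit import FilterSpec, LoopConfig, discretize
from .session import Session

__all__ = [
    "PlantConfig",
    "TrialSchedule",
    "simulate_plant",
    "make_stim_command",
    "run_session",
    "post_offset_alpha_change",
]


@dataclass(frozen=True)
class PlantConfig:
    """Parameters of the stochastic alpha-oscillator plant.

    Parameters
    ----------
    natural_freq : float
        Resonance frequency in Hz (default 11, inside the alpha band).
    damping : float
        Damping ratio zeta in (0, 1); 0.015 gives a ring-down time constant
        of about one second at 11 Hz, long enough for post-offset
        after-effects to be measurable.
    noise_sd : float
        Standard deviation of the white drive noise per sample
        (microvolt-equivalent drive units).
    coupling : float
        Drive units per ampere of stimulation current; absorbs the
        electrode/tissue transfer, which is otherwise treated as identity.
    background_exponent : float
        Slope of the additive 1/f background.
    background_rms : float
        RMS of the 1/f background in microvolt.
    """

    natural_freq: float = 11.0
    damping: float = 0.015
    noise_sd: float = 0.5
    coupling: float = 60.0
    background_exponent: float = 1.0
    background_rms: float = 25.0

    def __post_init__(self) -> None:
        if not 0 < self.damping < 1:
            raise ValueError("damping must be in (0, 1)")
        if not 5 < self.natural_freq < 30:
            raise ValueError("natural_freq must be in (5, 30) Hz")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")

    def ar_coefficients(self, fs: float) -> tuple[float, float]:
        """AR(2) coefficients (a1, a2) of the sampled resonator."""
        wn = 2.0 * np.pi * self.natural_freq
        r = np.exp(-self.damping * wn / fs)
        theta = wn * np.sqrt(1.0 - self.damping**2) / fs
        return 2.0 * r * np.cos(theta), -(r**2)


@dataclass(frozen=True)
class TrialSchedule:
    """Stimulation trial timing: blocks of jittered-duration trials.

    Trials nominally last ``stim_duration`` seconds but, mirroring manual
    stopwatch control, each realized duration is drawn uniformly from
    ``jitter_range``; trials are followed by ``rest_duration`` of rest and
    grouped into blocks of ``trials_per_block`` separated by
    ``inter_block_rest``.
    """

    stim_duration: float = 10.0
    jitter_range: tuple[float, float] = (7.74, 10.74)
    rest_duration: float = 40.0
    trials_per_block: int = 10
    inter_block_rest: float = 120.0
    block_conditions: tuple[str, ...] = ("open", "closed", "brain")
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.stim_duration, self.rest_duration, self.inter_block_rest) <= 0:
            raise ValueError("durations must be positive")
        lo, hi = self.jitter_range
        if not lo <= self.stim_duration <= hi:
            raise ValueError("jitter_range must contain the nominal stim_duration")
        if self.trials_per_block < 1:
            raise ValueError("trials_per_block must be >= 1")

    def realize(self, rng: np.random.Generator | None = None) -> pd.DataFrame:
        """Draw trial times; returns a frame (trial_id, block, condition, t_on, t_off).

        The session starts with one rest interval so that pre-onset epochs of
        the first trial fit inside the recording.
        """
        rng = np.random.default_rng(self.seed) if rng is None else rng
        lo, hi = self.jitter_range
        rows = []
        t = self.rest_duration
        trial_id = 0
        for block, condition in enumerate(self.block_conditions):
            for _ in range(self.trials_per_block):
                dur = rng.uniform(lo, hi)
                rows.append(
                    {
                        "trial_id": trial_id,
                        "block": block,
                        "condition": condition,
                        "t_on": t,
                        "t_off": t + dur,
                    }
                )
                t += dur + self.rest_duration
                trial_id += 1
            t += self.inter_block_rest
        return pd.DataFrame(rows)

    def total_duration(self, trials: pd.DataFrame) -> float:
        return float(trials["t_off"].iloc[-1] + self.rest_duration)


def trials_to_events(trials: pd.DataFrame) -> pd.DataFrame:
    """Expand a trial table into the session event table (on/off rows)."""
    rows = []
    for _, tr in trials.iterrows():
        for kind, t in (("stim_on", tr["t_on"]), ("stim_off", tr["t_off"])):
            rows.append(
                {
                    "time_s": float(t),
                    "kind": kind,
                    "condition": tr["condition"],
                    "block": int(tr["block"]),
                    "trial_id": int(tr["trial_id"]),
                }
            )
    return pd.DataFrame(rows).sort_values("time_s", ignore_index=True)


# ---------------------------------------------------------------------------
# plant dynamics
# ---------------------------------------------------------------------------


def simulate_plant(
    plant: PlantConfig,
    input_current: np.ndarray | None,
    duration: float,
    fs: float,
    seed: int,
) -> np.ndarray:
    """Open-loop plant response: resonator + 1/f background (microvolt).

    ``input_current`` (ampere, same sampling) enters as additive drive
    scaled by ``plant.coupling``; with no input the plant free-runs and its
    spectrum peaks within +/-1 Hz of ``natural_freq``.  Identical seeds and
    inputs give identical traces.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    n = int(round(duration * fs))
    rng = np.random.default_rng(seed)
    drive = rng.standard_normal(n) * plant.noise_sd
    if input_current is not None:
        input_current = np.asarray(input_current, dtype=float)
        if len(input_current) != n:
            raise ValueError(
                f"input length {len(input_current)} does not match "
                f"duration*fs = {n} samples"
            )
        drive = drive + plant.coupling * input_current
    a1, a2 = plant.ar_coefficients(fs)
    x = sp_signal.lfilter([1.0], [1.0, -a1, -a2], drive)
    bg = pink_noise(
        n, fs, rng, exponent=plant.background_exponent, rms=plant.background_rms
    )
    return x + bg


def _closed_loop_core(
    plant: PlantConfig,
    spec: FilterSpec,
    loop: LoopConfig,
    fs: float,
    stim_mask: np.ndarray,
    seed: int,
    invert: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample-by-sample closed-loop simulation.

    Returns (lfp trace in microvolt, command voltage series).  The loop is
    strictly causal: the command at sample t is the filter output from
    ``delay_samples`` samples earlier, so feedback is well defined for any
    positive delay.
    """
    n = len(stim_mask)
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(n) * plant.noise_sd
    bg = pink_noise(
        n, fs, rng, exponent=plant.background_exponent, rms=plant.background_rms
    )
    a1, a2 = plant.ar_coefficients(fs)
    b, a = discretize(spec, fs)
    b0, b1, b2 = b[0], b[1], (b[2] if len(b) > 2 else 0.0)
    _, a1f, a2f = a
    d = max(1, loop.delay_samples)
    ring = np.zeros(d)
    sign = -1.0 if invert else 1.0
    limit = loop.command_limit
    gain_in = loop.input_gain
    gain_stim = loop.stim_gain * plant.coupling
    x1 = x2 = 0.0  # plant state
    z1 = z2 = 0.0  # biquad state (direct form II transposed)
    x = np.empty(n)
    command = np.zeros(n)
    for t in range(n):
        cmd = ring[t % d] * sign
        if cmd > limit:
            cmd = limit
        elif cmd < -limit:
            cmd = -limit
        if stim_mask[t]:
            command[t] = cmd
            drive = noise[t] + gain_stim * cmd
        else:
            drive = noise[t]
        xt = a1 * x1 + a2 * x2 + drive
        x2, x1 = x1, xt
        x[t] = xt
        u = gain_in * (xt + bg[t])  # measured LFP -> filter input (volt)
        y = b0 * u + z1
        z1 = b1 * u - a1f * y + z2
        z2 = b2 * u - a2f * y
        ring[t % d] = y
    return x + bg, command


def make_stim_command(
    condition: str,
    plant_output: np.ndarray,
    spec: FilterSpec,
    loop: LoopConfig,
    fs: float,
    replay: np.ndarray | None = None,
    open_freq: float = 11.5,
    open_amplitude: float = 0.3,
) -> np.ndarray:
    """Command voltage series for one trial of the given condition.

    ``closed``: the concurrent plant output (microvolt) through the filter
    chain (causal, delayed, clipped).  ``open``: a fixed sinusoid at
    ``open_freq`` (11.5 Hz).  ``brain``: a previously recorded trace,
    band-pass filtered through the same chain.  All outputs are clipped to
    the command limit.
    """
    from .circuit import apply_filter

    n = len(plant_output)
    if condition == "closed":
        return apply_filter(loop.input_gain * np.asarray(plant_output), fs, spec, loop)
    if condition == "open":
        t = np.arange(n) / fs
        return np.clip(
            open_amplitude * np.sin(2 * np.pi * open_freq * t),
            -loop.command_limit,
            loop.command_limit,
        )
    if condition == "brain":
        if replay is None or len(replay) < n:
            raise ValueError("brain condition requires a replay series >= trial length")
        return apply_filter(loop.input_gain * np.asarray(replay[:n]), fs, spec, loop)
    raise ValueError(f"unknown condition {condition!r}")


def run_session(
    plant: PlantConfig,
    spec: FilterSpec,
    loop: LoopConfig,
    schedule: TrialSchedule,
    n_arrays: int = 3,
    seed: int = 0,
    channels_per_array: int | None = 4,
    channel_noise_rms: float = 20.0,
) -> Session:
    """Simulate a full experimental session under the trial schedule.

    The controller channel carries the feedback-target plant; the remaining
    channels on each array are correlated copies of a per-array source with
    independent pink channel noise.  Closed-loop feedback runs sample by
    sample against the controller source; open/brain commands are generated
    per trial.  ``channels_per_array=None`` yields full 96-channel arrays.
    """
    fs = loop.sample_rate
    rng = np.random.default_rng(seed)
    trials = schedule.realize(rng)
    n = int(round(schedule.total_duration(trials) * fs))

    stim_mask = np.zeros(n, dtype=bool)
    cond_of_sample = np.full(n, "", dtype=object)
    for _, tr in trials.iterrows():
        i0, i1 = int(tr["t_on"] * fs), int(tr["t_off"] * fs)
        stim_mask[i0:i1] = True
        cond_of_sample[i0:i1] = tr["condition"]

    closed_mask = stim_mask & (cond_of_sample == "closed")
    lfp, command = _closed_loop_core(
        plant, spec, loop, fs, closed_mask, seed=int(rng.integers(2**31))
    )

    # open / brain commands injected as additional drive on top of the trace:
    # re-run the plant with the extra open/brain current as external input.
    extra_current = np.zeros(n)
    replay_src = simulate_plant(
        plant, None, 60.0, fs, seed=int(rng.integers(2**31))
    )
    for _, tr in trials.iterrows():
        if tr["condition"] == "closed":
            continue
        i0, i1 = int(tr["t_on"] * fs), int(tr["t_off"] * fs)
        seg = lfp[i0:i1]
        cmd = make_stim_command(
            tr["condition"], seg, spec, loop, fs,
            replay=np.tile(replay_src, int(np.ceil((i1 - i0) / len(replay_src)) + 1)),
        )
        command[i0:i1] = cmd
        extra_current[i0:i1] = loop.stim_gain * cmd
    if np.any(extra_current):
        a1, a2 = plant.ar_coefficients(fs)
        lfp = lfp + sp_signal.lfilter(
            [1.0], [1.0, -a1, -a2], plant.coupling * extra_current
        )

    cmap = ChannelMap.grid(arrays=tuple(range(1, n_arrays + 1)))
    if channels_per_array is not None:
        cmap = cmap.subsample(channels_per_array, seed=seed)
    ctrl, ref = cmap.controller_pair
    n_ch = len(cmap)
    data = np.empty((n_ch, n), dtype=np.float32)
    array_src = {1: lfp}
    for arr in cmap.arrays:
        if arr not in array_src:
            array_src[arr] = simulate_plant(
                plant, None, n / fs, fs, seed=int(rng.integers(2**31))
            )
    for i in range(n_ch):
        arr = int(cmap.table["array"].iloc[i])
        if i in (ctrl, ref):
            data[i] = array_src[arr]
        else:
            ch_noise = pink_noise(n, fs, rng, rms=channel_noise_rms)
            data[i] = array_src[arr] + ch_noise

    return Session(
        data=data,
        fs=fs,
        channels=cmap,
        events=trials_to_events(trials),
        kind="in_vivo",
        meta={"seed": seed, "generator": "loop_sim"},
    )


# ---------------------------------------------------------------------------
# interference experiment
# ---------------------------------------------------------------------------


def post_offset_alpha_change(
    seed: int,
    invert: bool = False,
    plant: PlantConfig | None = None,
    spec: FilterSpec | None = None,
    loop: LoopConfig | None = None,
    n_trials: int = 16,
    stim_duration: float = 10.0,
    rest: float = 15.0,
    window: tuple[float, float] = (0.0, 1.0),
) -> float:
    """Mean post-offset alpha change (dB) over closed-loop trials vs a matched no-stim run.

    Simulates a short session of ``n_trials`` feedback trials and, with the
    identical noise realization (same seed), a free-running session, then
    compares mean 8-15 Hz band power in ``window`` seconds after each
    stimulation offset.  With the canonical alpha design the loop phase is
    ~360 deg across the band, so the un-inverted loop pumps the oscillator
    (positive change) and ``invert=True`` (an extra half-cycle in the loop)
    damps it.
    """
    from .circuit import design_mfb

    plant = plant or PlantConfig()
    spec = spec or design_mfb(12.0, 1.5)
    loop = loop or LoopConfig()
    fs = loop.sample_rate
    trial_len = stim_duration + rest
    n = int(round((rest + n_trials * trial_len) * fs))
    mask_on = np.zeros(n, dtype=bool)
    offsets = []
    for k in range(n_trials):
        i0 = int((rest + k * trial_len) * fs)
        i1 = i0 + int(stim_duration * fs)
        mask_on[i0:i1] = True
        offsets.append(i1)
    mask_off = np.zeros(n, dtype=bool)
    stim, _ = _closed_loop_core(plant, spec, loop, fs, mask_on, seed, invert=invert)
    free, _ = _closed_loop_core(plant, spec, loop, fs, mask_off, seed, invert=invert)

    sos = sp_signal.butter(2, [8.0, 15.0], btype="bandpass", fs=fs, output="sos")
    stim_b = sp_signal.sosfiltfilt(sos, stim)
    free_b = sp_signal.sosfiltfilt(sos, free)
    w0, w1 = int(window[0] * fs), int(window[1] * fs)
    p_stim = np.mean([np.mean(stim_b[i + w0 : i + w1] ** 2) for i in offsets])
    p_free = np.mean([np.mean(free_b[i + w0 : i + w1] ** 2) for i in offsets])
    return float(10.0 * np.log10(p_stim / p_free))
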