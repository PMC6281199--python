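"""Canonical validation studies run on the synthetic generators.

These are the package's own control experiments, sized to run on a desk
machine (channel subsets instead of full 96-electrode arrays, rest
intervals trimmed to the minimum that still fits the -5..+5 s epochs, and
the wavelet grid restricted to the bands under test).  Each function is
deterministic given its seed.
"""

from __future__ import annotations

import numpy as np

from .channels import ChannelMap
from .pipeline import AnalysisConfig, condition_band_power
from .plant import TrialSchedule
from .stats import bootstrap_vs_zero, fdr_bh, perm_condition
from .synth import EffectSpec, generate_saline_session, generate_session

__all__ = [
    "recovery_estimate",
    "recovery_study",
    "saline_band_pvalues",
    "saline_study",
]

#: rest long enough for the -5..+5 s epoch windows plus margin
_SHORT_REST = 12.0


def _recovery_map(arrays=(1, 2), channels_per_array=6) -> ChannelMap:
    return ChannelMap.grid(arrays=arrays).subsample(channels_per_array, seed=0)


def recovery_estimate(
    effect_db: float,
    seed: int,
    n_trials: int = 100,
    arrays: tuple[int, ...] = (1,),
    channels_per_array: int = 6,
    band: str = "alpha",
    effect_duration: float = 1.5,
) -> dict[int, float]:
    """Pipeline band-power estimate per array for one injected-effect session.

    Generates a single-condition session of ``n_trials`` stimulation trials
    with a ground-truth ``effect_db`` alpha perturbation on Array 1 (none if
    ``effect_db == 0``), runs the full pipeline, and returns the post-offset
    window summary per array.  The effect spans 1.5 s after each offset so
    the 0.5-1 s summary window plus the wavelet support lies inside the
    perturbed interval.
    """
    cmap = _recovery_map(arrays=tuple(sorted(set(arrays) | {1})),
                         channels_per_array=channels_per_array)
    n_blocks = int(np.ceil(n_trials / 10))
    sched = TrialSchedule(
        rest_duration=_SHORT_REST,
        trials_per_block=10,
        inter_block_rest=_SHORT_REST,
        block_conditions=("closed",) * n_blocks,
    )
    effects = (
        [EffectSpec("closed", 1, band, effect_db, duration=effect_duration)]
        if effect_db != 0.0
        else []
    )
    ses = generate_session(effects, sched, cmap, seed=seed)
    config = AnalysisConfig(bands=(band,), decim=10)
    out = {}
    for arr in arrays:
        bundles = condition_band_power([ses], config, array=arr, bands=(band,))
        out[arr] = bundles[("closed", band)].summary()
    return out


def recovery_study(
    effect_levels: tuple[float, ...] = (-0.5, 0.0, 0.5),
    n_seeds: int = 20,
    n_trials: int = 100,
    seed: int = 0,
    check_locality_on: float = 0.5,
) -> dict:
    """Parameter-recovery study over seeds and effect levels.

    Returns per-level estimates plus pooled bias and RMSE against the
    injected truth, and the Array-2 estimates for the ``check_locality_on``
    level (effects are injected on Array 1 only, so Array 2 should read
    ~0 dB).
    """
    rng = np.random.default_rng(seed)
    estimates: dict[float, list[float]] = {lv: [] for lv in effect_levels}
    array2: list[float] = []
    for lv in effect_levels:
        arrays = (1, 2) if lv == check_locality_on else (1,)
        for _ in range(n_seeds):
            s = int(rng.integers(2**31))
            res = recovery_estimate(lv, s, n_trials=n_trials, arrays=arrays)
            estimates[lv].append(res[1])
            if 2 in res:
                array2.append(res[2])
    errors = np.concatenate(
        [np.asarray(estimates[lv]) - lv for lv in effect_levels]
    )
    return {
        "estimates": {lv: np.asarray(v) for lv, v in estimates.items()},
        "bias": float(errors.mean()),
        "rmse": float(np.sqrt(np.mean(errors**2))),
        "array2_estimates": np.asarray(array2),
        "array2_mean": float(np.mean(array2)) if array2 else np.nan,
    }


def saline_band_pvalues(
    seed: int,
    n_trials_per_condition: int = 10,
    channels_per_array: int = 5,
    bands: tuple[str, ...] = ("alpha", "beta", "hgp"),
    n_resamples: int = 500,
) -> dict:
    """FDR-corrected band tests for one saline (in vitro) session.

    Runs the pipeline on a no-oscillator bath session and returns the
    BH-FDR-corrected p-values of every condition-vs-baseline bootstrap and
    pairwise condition permutation, within-band families — all of which
    should be null.
    """
    cmap = ChannelMap.grid(arrays=(1,)).subsample(channels_per_array, seed=0)
    n_blocks = max(1, n_trials_per_condition // 10)
    conds = ("open", "closed", "brain")
    sched = TrialSchedule(
        rest_duration=_SHORT_REST,
        trials_per_block=n_trials_per_condition // n_blocks,
        inter_block_rest=_SHORT_REST,
        block_conditions=conds * n_blocks,
    )
    ses = generate_saline_session(sched, cmap, seed=seed)
    config = AnalysisConfig(bands=bands, decim=10, baseline_stride=4,
                            n_boot=n_resamples, n_perm=n_resamples, seed=seed)
    bundles = condition_band_power([ses], config, array=1, bands=bands)
    from itertools import combinations

    p_boot, p_perm, fam_boot, fam_perm = [], [], [], []
    for b_i, band in enumerate(bands):
        for c_i, cond in enumerate(conds):
            tbp = bundles[(cond, band)]
            res = bootstrap_vs_zero(
                np.arange(tbp.n_trials),
                config.stats_config(salt=100 * b_i + c_i),
                batch_statistic=tbp.summaries,
            )
            p_boot.append(res.p)
            fam_boot.append(band)
        for p_i, (ca, cb) in enumerate(combinations(conds, 2)):
            ta, tb = bundles[(ca, band)], bundles[(cb, band)]
            pooled = type(ta)(
                step1=np.concatenate([ta.step1, tb.step1], axis=0),
                times=ta.times, valid=ta.valid,
                baseline=ta.baseline, window=ta.window,
                baseline_stride=ta.baseline_stride,
            )
            res = perm_condition(
                np.arange(ta.n_trials),
                np.arange(ta.n_trials, ta.n_trials + tb.n_trials),
                config.stats_config(salt=5000 + 100 * b_i + p_i),
                batch_statistic=pooled.summaries,
            )
            p_perm.append(res.p)
            fam_perm.append(band)
    return {
        "p_boot": np.asarray(p_boot),
        "p_boot_fdr": fdr_bh(p_boot, fam_boot),
        "p_perm": np.asarray(p_perm),
        "p_perm_fdr": fdr_bh(p_perm, fam_perm),
    }


def saline_study(n_seeds: int = 20, seed: int = 0, alpha: float = 0.05) -> dict:
    """Fraction of saline sessions with any FDR-significant band effect.

    The bath has no field generators, so no condition should differ from
    its baseline or from another condition in any band.
    """
    rng = np.random.default_rng(seed)
    any_sig = []
    for _ in range(n_seeds):
        res = saline_band_pvalues(int(rng.integers(2**31)))
        sig = (res["p_boot_fdr"] < alpha).any() or (res["p_perm_fdr"] < alpha).any()
        any_sig.append(bool(sig))
    any_sig = np.asarray(any_sig)
    return {
        "n_seeds": n_seeds,
        "n_with_false_positive": int(any_sig.sum()),
        "fraction_clean": float(1.0 - any_sig.mean()),
    }
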