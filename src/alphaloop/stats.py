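"""Resampling inference: bootstrap vs zero, two permutation schemes, BH-FDR.

Three schemes mirror the study design:

* ``bootstrap_vs_zero`` — trials are resampled with replacement and the
  band summary recomputed per draw, giving a confidence distribution for
  the mean post-stimulation effect; the masses above and below zero are
  both reported.
* ``perm_condition`` — condition labels are permuted across the pooled
  trials of two conditions; two-sided p by the |null| >= |observed| rule.
  For comparisons against a smaller condition the larger groups are first
  randomly subsampled to its size within every permutation.
* ``perm_array`` — electrode array labels are shuffled; the unit of
  exchange is the electrode, not the trial.

Permutation p-values are the plain fraction of null values at least as
extreme as the observation (no +1 correction); when the permutation space
is small the schemes switch to exhaustive enumeration automatically.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

__all__ = [
    "StatsConfig",
    "StatResult",
    "bootstrap_vs_zero",
    "perm_condition",
    "perm_array",
    "fdr_bh",
]


@dataclass(frozen=True)
class StatsConfig:
    """Resampling sizes and seeding.

    ``subsample_to`` equalizes group sizes inside permutation draws (80 for
    comparisons against the smaller condition of the reference design).
    The headline p of the bootstrap is two-sided (twice the smaller tail
    mass, capped at 1); set ``sidedness="greater"``/``"less"`` for the
    one-sided masses themselves.
    """

    n_boot: int = 5000
    n_perm: int = 5000
    subsample_to: int | None = None
    seed: int = 0
    sidedness: str = "two-sided"

    def __post_init__(self) -> None:
        if self.n_boot < 1 or self.n_perm < 1:
            raise ValueError("resample counts must be >= 1")
        if self.sidedness not in ("two-sided", "greater", "less"):
            raise ValueError("sidedness must be two-sided, greater or less")


@dataclass
class StatResult:
    """Effect estimate with bootstrap/permutation summaries."""

    scheme: str
    observed: float
    p: float
    ci_low: float | None = None
    ci_high: float | None = None
    boot_mean: float | None = None
    mass_above: float | None = None
    mass_below: float | None = None
    null_mean: float | None = None
    null_sd: float | None = None
    n_resamples: int = 0
    exhaustive: bool = False
    seed: int | None = None
    p_fdr: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must lie in [0, 1]")


def _as_statistic(
    data: np.ndarray, statistic: Callable[[np.ndarray], float] | None
) -> Callable[[np.ndarray], float]:
    if statistic is not None:
        return statistic
    if np.ndim(data) != 1:
        raise ValueError("default statistic (mean) requires 1-D trial values")
    return lambda x: float(np.mean(x))


def bootstrap_vs_zero(
    trials: np.ndarray,
    cfg: StatsConfig | None = None,
    statistic: Callable[[np.ndarray], float] | None = None,
    batch_statistic: Callable[[np.ndarray], np.ndarray] | None = None,
) -> StatResult:
    """Bootstrap confidence distribution of a trial-level summary vs zero.

    ``trials`` has trials on the first axis; ``statistic`` maps a resampled
    trial array to the scalar summary (default: mean of 1-D values; pass a
    closure that recomputes the normalization collapse for band summaries).
    ``batch_statistic`` — a vectorized form mapping a (draws, n) matrix of
    trial *indices* to draw summaries — short-circuits the per-draw loop;
    ``trials`` must then be the index vector ``arange(n)``.
    The CI is the 2.5-97.5 percentile range of the bootstrap distribution.
    """
    cfg = cfg or StatsConfig()
    trials = np.asarray(trials)
    n = trials.shape[0]
    if n < 2:
        raise ValueError("need at least two trials")
    rng = np.random.default_rng(cfg.seed)
    if batch_statistic is not None:
        observed = float(batch_statistic(np.arange(n)[None, :])[0])
        boot = np.asarray(batch_statistic(rng.integers(0, n, size=(cfg.n_boot, n))))
    else:
        stat = _as_statistic(trials, statistic)
        observed = stat(trials)
        boot = np.empty(cfg.n_boot)
        for b in range(cfg.n_boot):
            idx = rng.integers(0, n, size=n)
            boot[b] = stat(trials[idx])
    if np.ptp(boot) == 0:
        warnings.warn("degenerate bootstrap: all resamples identical", stacklevel=2)
    mass_above = float(np.mean(boot > 0))
    mass_below = float(np.mean(boot < 0))
    if cfg.sidedness == "greater":
        p = mass_below + float(np.mean(boot == 0))
    elif cfg.sidedness == "less":
        p = mass_above + float(np.mean(boot == 0))
    else:
        p = min(1.0, 2.0 * min(mass_above, mass_below))
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return StatResult(
        scheme="bootstrap_vs_zero",
        observed=observed,
        p=p,
        ci_low=float(lo),
        ci_high=float(hi),
        boot_mean=float(boot.mean()),
        mass_above=mass_above,
        mass_below=mass_below,
        n_resamples=cfg.n_boot,
        seed=cfg.seed,
    )


def _two_sided_p(null: np.ndarray, observed: float) -> float:
    return float(np.mean(np.abs(null) >= abs(observed)))


def perm_condition(
    group_a: np.ndarray,
    group_b: np.ndarray,
    cfg: StatsConfig | None = None,
    statistic: Callable[[np.ndarray], float] | None = None,
    batch_statistic: Callable[[np.ndarray], np.ndarray] | None = None,
) -> StatResult:
    """Label-permutation test for a difference between two conditions.

    The statistic is applied to each group and differenced (A - B).  With
    ``cfg.subsample_to`` set, any group larger than that size is randomly
    subsampled to it before computing the statistic — both for the observed
    value and inside every permutation.  Exhaustive enumeration replaces
    Monte-Carlo when the number of distinct splits is at most ``n_perm``
    (and no subsampling is requested).

    With ``batch_statistic`` the groups must be disjoint *index* vectors
    into the pooled trial tensor, and the statistic evaluates whole
    (draws, size) index matrices at once.
    """
    cfg = cfg or StatsConfig()
    a, b = np.asarray(group_a), np.asarray(group_b)
    n_a, n_b = a.shape[0], b.shape[0]
    if n_a < 2 or n_b < 2:
        raise ValueError("both groups need at least two trials")
    pooled = np.concatenate([a, b])
    n = n_a + n_b
    rng = np.random.default_rng(cfg.seed)
    sub = cfg.subsample_to

    if batch_statistic is not None:
        def stats_of(idx_matrix: np.ndarray) -> np.ndarray:
            return np.asarray(batch_statistic(idx_matrix))

        def subsampled(idx_matrix: np.ndarray) -> np.ndarray:
            if sub is None or idx_matrix.shape[1] <= sub:
                return idx_matrix
            out = np.empty((idx_matrix.shape[0], sub), dtype=int)
            for i, row in enumerate(idx_matrix):
                out[i] = rng.choice(row, size=sub, replace=False)
            return out

        observed = float(
            stats_of(subsampled(a[None, :]))[0] - stats_of(subsampled(b[None, :]))[0]
        )
        n_exhaustive = math.comb(n, n_a)
        exhaustive = sub is None and n_exhaustive <= cfg.n_perm
        if exhaustive:
            picks = np.array(list(combinations(range(n), n_a)))
            rests = np.array(
                [sorted(set(range(n)) - set(p)) for p in picks]
            )
            null = stats_of(pooled[picks]) - stats_of(pooled[rests])
        else:
            perms = np.array([rng.permutation(n) for _ in range(cfg.n_perm)])
            null = stats_of(subsampled(pooled[perms[:, :n_a]])) - stats_of(
                subsampled(pooled[perms[:, n_a:]])
            )
    else:
        stat = _as_statistic(pooled, statistic)

        def group_stat(values: np.ndarray) -> float:
            if sub is not None and values.shape[0] > sub:
                idx = rng.choice(values.shape[0], size=sub, replace=False)
                values = values[idx]
            return stat(values)

        observed = group_stat(a) - group_stat(b)
        n_exhaustive = math.comb(n, n_a)
        exhaustive = sub is None and n_exhaustive <= cfg.n_perm
        if exhaustive:
            null = np.empty(n_exhaustive)
            all_idx = set(range(n))
            for k, pick in enumerate(combinations(range(n), n_a)):
                rest = sorted(all_idx - set(pick))
                null[k] = stat(pooled[list(pick)]) - stat(pooled[rest])
        else:
            null = np.empty(cfg.n_perm)
            for k in range(cfg.n_perm):
                perm = rng.permutation(n)
                null[k] = group_stat(pooled[perm[:n_a]]) - group_stat(
                    pooled[perm[n_a:]]
                )
    return StatResult(
        scheme="perm_condition",
        observed=float(observed),
        p=_two_sided_p(null, observed),
        null_mean=float(null.mean()),
        null_sd=float(null.std()),
        n_resamples=len(null),
        exhaustive=exhaustive,
        seed=cfg.seed,
    )


def perm_array(
    values: np.ndarray,
    array_labels: Sequence,
    cfg: StatsConfig | None = None,
) -> StatResult:
    """Array-shuffle permutation test on per-electrode summaries.

    ``values`` holds one summary per electrode; ``array_labels`` its array
    membership (exactly two arrays).  The statistic is the difference of
    array means (first label minus second, in sorted label order), and the
    null shuffles electrode-to-array assignment.
    """
    cfg = cfg or StatsConfig()
    values = np.asarray(values, dtype=float)
    labels = np.asarray(array_labels)
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise ValueError(f"need exactly two arrays, got {list(uniq)}")
    mask_a = labels == uniq[0]
    n_a, n_b = int(mask_a.sum()), int((~mask_a).sum())
    if n_a < 2 or n_b < 2:
        raise ValueError("each array needs at least two electrodes")
    observed = float(values[mask_a].mean() - values[~mask_a].mean())
    n = n_a + n_b
    n_exhaustive = math.comb(n, n_a)
    exhaustive = n_exhaustive <= cfg.n_perm
    if exhaustive:
        null = np.empty(n_exhaustive)
        idx_all = np.arange(n)
        for k, pick in enumerate(combinations(range(n), n_a)):
            sel = np.zeros(n, dtype=bool)
            sel[list(pick)] = True
            null[k] = values[sel].mean() - values[~sel].mean()
    else:
        rng = np.random.default_rng(cfg.seed)
        null = np.empty(cfg.n_perm)
        for k in range(cfg.n_perm):
            perm = rng.permutation(n)
            null[k] = values[perm[:n_a]].mean() - values[perm[n_a:]].mean()
    return StatResult(
        scheme="perm_array",
        observed=observed,
        p=_two_sided_p(null, observed),
        null_mean=float(null.mean()),
        null_sd=float(null.std()),
        n_resamples=len(null),
        exhaustive=exhaustive,
        seed=cfg.seed,
    )


def fdr_bh(
    pvals: Sequence[float], families: Sequence | None = None
) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, within declared families.

    ``families`` assigns each p-value to a correction family (e.g. its
    frequency band, giving families of three condition comparisons);
    adjustment is applied independently within each family.  With no
    families, all p-values form one family.  A single p-value is returned
    unchanged.
    """
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if families is None:
        families = np.zeros(len(p))
    families = np.asarray(families)
    out = np.empty_like(p)
    for fam in np.unique(families):
        m = families == fam
        if m.sum() == 1:
            out[m] = p[m]
        else:
            out[m] = multipletests(p[m], method="fdr_bh")[1]
    return out
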