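"""Bootstrap vs zero, permutation schemes, and BH-FDR against independent oracles."""

from itertools import combinations, product

import numpy as np
import pytest

from alphaloop.stats import (
    StatsConfig,
    bootstrap_vs_zero,
    fdr_bh,
    perm_array,
    perm_condition,
)


class TestBootstrap:
    def test_constant_positive_values(self):
        with pytest.warns(UserWarning, match="degenerate"):
            res = bootstrap_vs_zero(np.full(6, 2.5), StatsConfig(n_boot=200))
        assert res.ci_low == res.ci_high == pytest.approx(2.5)
        assert res.mass_below == 0.0 and res.mass_above == 1.0

    def test_symmetric_data_masses_near_half(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(400)  # mean ~0
        res = bootstrap_vs_zero(x - x.mean(), StatsConfig(n_boot=2000, seed=1))
        assert res.mass_above == pytest.approx(0.5, abs=0.05)
        assert res.mass_below == pytest.approx(0.5, abs=0.05)

    def test_exhaustive_enumeration_oracle_n5(self):
        """Monte-Carlo tail masses match full 5^5 enumeration within 0.01."""
        values = np.array([-1.0, -0.4, 0.2, 0.9, 1.4])
        total, above = 0, 0
        for draw in product(range(5), repeat=5):
            total += 1
            if np.mean(values[list(draw)]) > 0:
                above += 1
        exact_above = above / total
        res = bootstrap_vs_zero(values, StatsConfig(n_boot=5000, seed=2))
        assert res.mass_above == pytest.approx(exact_above, abs=0.01)

    def test_seed_reproducibility(self):
        x = np.random.default_rng(3).standard_normal(30)
        a = bootstrap_vs_zero(x, StatsConfig(n_boot=500, seed=9))
        b = bootstrap_vs_zero(x, StatsConfig(n_boot=500, seed=9))
        assert (a.p, a.ci_low, a.ci_high) == (b.p, b.ci_low, b.ci_high)

    def test_degenerate_input_warns(self):
        with pytest.warns(UserWarning, match="degenerate"):
            res = bootstrap_vs_zero(np.zeros(5), StatsConfig(n_boot=50))
        assert res.p in (0.0, 1.0)

    def test_batch_statistic_equivalent_to_plain_mean(self):
        x = np.random.default_rng(4).standard_normal(20)
        plain = bootstrap_vs_zero(x, StatsConfig(n_boot=300, seed=5))
        batched = bootstrap_vs_zero(
            np.arange(20),
            StatsConfig(n_boot=300, seed=5),
            batch_statistic=lambda idx: x[idx].mean(axis=1),
        )
        assert plain.p == batched.p
        assert plain.observed == pytest.approx(batched.observed)


class TestPermCondition:
    def test_identical_groups_p_near_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = perm_condition(x, x.copy(), StatsConfig(n_perm=5000, seed=0))
        assert res.p > 0.9

    def test_separated_groups_exhaustive_p_is_one_tenth(self):
        """{1,2,3} vs {10,11,12}: 2 of the 20 splits reach |diff| >= 9."""
        res = perm_condition(
            np.array([1.0, 2.0, 3.0]), np.array([10.0, 11.0, 12.0]), StatsConfig()
        )
        assert res.exhaustive
        assert res.n_resamples == 20
        assert res.p == pytest.approx(0.1)

    def test_exhaustive_matches_brute_force_null(self):
        a = np.array([0.3, -0.2, 1.1])
        b = np.array([0.9, 0.1, -0.5])
        res = perm_condition(a, b, StatsConfig())
        pooled = np.concatenate([a, b])
        null = []
        for pick in combinations(range(6), 3):
            rest = [i for i in range(6) if i not in pick]
            null.append(pooled[list(pick)].mean() - pooled[rest].mean())
        obs = a.mean() - b.mean()
        assert res.p == pytest.approx(np.mean(np.abs(null) >= abs(obs)))

    def test_monotone_in_group_shift(self):
        rng = np.random.default_rng(6)
        base = rng.standard_normal(15)
        other = rng.standard_normal(15)
        ps = [
            perm_condition(base + shift, other, StatsConfig(n_perm=2000, seed=7)).p
            for shift in (0.0, 0.5, 1.0, 2.0)
        ]
        assert all(p1 >= p2 for p1, p2 in zip(ps, ps[1:]))

    def test_subsampling_equalizes_group_sizes(self):
        rng = np.random.default_rng(8)
        big = rng.standard_normal(50)
        small = rng.standard_normal(10)
        calls = []
        res = perm_condition(
            np.arange(50),
            np.arange(50, 60),
            StatsConfig(n_perm=50, seed=9, subsample_to=10),
            batch_statistic=lambda idx: (
                calls.append(idx.shape), np.concatenate([big, small])[idx].mean(axis=1)
            )[1],
        )
        assert all(shape[1] == 10 for shape in calls)
        assert 0.0 <= res.p <= 1.0

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            perm_condition(np.array([1.0]), np.array([2.0, 3.0]))


class TestPermArray:
    def test_identical_arrays_p_near_one(self):
        v = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        labels = [1, 1, 1, 2, 2, 2]
        res = perm_array(v, labels, StatsConfig())
        assert res.exhaustive
        assert res.p > 0.9

    def test_exhaustive_matches_brute_force(self):
        v = np.array([0.9, 1.4, 0.2, -0.3, 0.1, -0.8])
        labels = np.array([1, 1, 1, 2, 2, 2])
        res = perm_array(v, labels, StatsConfig())
        null = []
        for pick in combinations(range(6), 3):
            rest = [i for i in range(6) if i not in pick]
            null.append(v[list(pick)].mean() - v[rest].mean())
        obs = v[:3].mean() - v[3:].mean()
        assert res.observed == pytest.approx(obs)
        assert res.p == pytest.approx(np.mean(np.abs(null) >= abs(obs)))

    def test_detects_array_level_shift_at_full_size(self):
        """96 + 96 electrodes with a one-array offset: p < 0.05."""
        rng = np.random.default_rng(10)
        v1 = rng.normal(0.15, 0.1, size=96)
        v2 = rng.normal(0.0, 0.1, size=96)
        labels = np.array([1] * 96 + [2] * 96)
        res = perm_array(np.concatenate([v1, v2]), labels, StatsConfig(n_perm=2000, seed=11))
        assert not res.exhaustive
        assert res.p < 0.05

    def test_requires_two_arrays(self):
        with pytest.raises(ValueError, match="two arrays"):
            perm_array(np.ones(4), [1, 1, 1, 1])


class TestFdr:
    def test_textbook_example(self):
        out = fdr_bh([0.01, 0.02, 0.03])
        assert np.allclose(out, [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert fdr_bh([0.2]) == pytest.approx([0.2])

    def test_family_of_three_scales_smallest_p_threefold(self):
        """p = 0.006 in a family of three corrects to 0.018 when it is smallest."""
        out = fdr_bh([0.006, 0.3, 0.5])
        assert out[0] == pytest.approx(0.018)

    def test_matches_direct_step_up_formula(self):
        rng = np.random.default_rng(12)
        p = rng.uniform(size=9)
        # independent direct implementation of the step-up adjustment
        order = np.argsort(p)
        m = len(p)
        adj = np.empty(m)
        prev = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            prev = min(prev, p[i] * m / rank)
            adj[i] = prev
        assert np.allclose(fdr_bh(p), adj)

    def test_families_are_independent(self):
        p = [0.01, 0.02, 0.03, 0.01, 0.02, 0.03]
        fams = ["a", "a", "a", "b", "b", "b"]
        assert np.allclose(fdr_bh(p, fams), [0.03] * 6)

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(13)
        p = rng.uniform(size=12)
        assert np.all(fdr_bh(p) >= p)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            fdr_bh([0.5, 1.2])
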