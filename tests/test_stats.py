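"""Bootstrap contrasts, ANOVA/Tukey, slope test, leaf-area derivation."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

import pinedrought as pdr


class TestBootstrapContrast:
    def test_degenerate_identical_groups(self):
        res = pdr.bootstrap_contrast([2.0] * 4, [2.0] * 4, seed=0)
        assert (res.differences == 0).all()
        assert not res.significant

    def test_separated_groups_significant(self):
        res = pdr.bootstrap_contrast([10.0, 10.1, 9.9, 10.0], [1.0, 1.1, 0.9, 1.0], seed=0)
        assert res.significant
        assert res.ci95[0] > 0

    def test_reproducible_under_seed(self, rng):
        t, c = rng.normal(5, 1, 6), rng.normal(4, 1, 6)
        a = pdr.bootstrap_contrast(t, c, seed=77)
        b = pdr.bootstrap_contrast(t, c, seed=77)
        np.testing.assert_array_equal(a.differences, b.differences)
        assert a.significant == b.significant

    def test_relative_and_absolute_agree_in_sign(self, rng):
        for seed in range(10):
            t = rng.normal(5, 2, 5)
            c = rng.normal(4, 2, 5)
            a = pdr.bootstrap_contrast(t, c, mode="absolute", seed=seed)
            r = pdr.bootstrap_contrast(t, c, mode="relative", seed=seed)
            assert np.sign(a.median) == np.sign(r.median)

    def test_invariant_to_group_ordering(self, rng):
        t, c = rng.normal(5, 1, 6), rng.normal(4, 1, 6)
        a = pdr.bootstrap_contrast(t, c, seed=3)
        b = pdr.bootstrap_contrast(t[::-1].copy(), c[::-1].copy(), seed=3)
        assert a.ci95 == pytest.approx(b.ci95, abs=0.2)
        assert a.significant == b.significant

    def test_zero_control_mean_relative_rejected(self):
        with pytest.raises(ValueError):
            pdr.bootstrap_contrast([1.0, 2.0], [-1.0, 1.0], mode="relative")

    def test_null_calibration_matches_direct_monte_carlo_oracle(self):
        """False-positive rate of the 95%-exclude-zero rule on two n=4 null
        groups matches an independently coded nested Monte-Carlo estimate."""
        n_rep = 500
        gen = np.random.default_rng(2024)
        datasets = [(gen.normal(0, 1, 4), gen.normal(0, 1, 4)) for _ in range(n_rep)]

        hits_pkg = sum(
            pdr.bootstrap_contrast(t, c, n_iter=1000, seed=k).significant
            for k, (t, c) in enumerate(datasets)
        )

        # independent oracle: plain-loop percentile bootstrap on the same data
        hits_oracle = 0
        for k, (t, c) in enumerate(datasets):
            orng = np.random.default_rng(10_000 + k)
            diffs = np.empty(1000)
            for i in range(1000):
                diffs[i] = np.mean(orng.choice(t, 4)) - np.mean(orng.choice(c, 4))
            lo, hi = np.percentile(diffs, [2.5, 97.5])
            hits_oracle += lo > 0 or hi < 0
        rate_pkg = hits_pkg / n_rep
        rate_oracle = hits_oracle / n_rep
        assert abs(rate_pkg - rate_oracle) <= 0.03


class TestAnova:
    def test_null_groups_large_p(self, rng):
        vals = rng.normal(0, 1, 40)
        groups = np.repeat(list("abcd"), 10)
        res = pdr.one_way_anova(vals, groups)
        assert res.p > 0.001
        assert res.f >= 0

    def test_two_group_f_equals_t_squared(self, rng):
        a, b = rng.normal(0, 1, 8), rng.normal(1, 1, 8)
        vals = np.concatenate([a, b])
        groups = np.repeat(["a", "b"], 8)
        res = pdr.one_way_anova(vals, groups)
        t = sps.ttest_ind(a, b)
        assert res.f == pytest.approx(t.statistic**2)
        assert res.p == pytest.approx(t.pvalue)

    def test_matches_scipy_f_oneway(self, rng):
        arrays = [rng.normal(m, 1, 6) for m in (0, 0.5, 1, 2)]
        vals = np.concatenate(arrays)
        groups = np.repeat(list("abcd"), 6)
        res = pdr.one_way_anova(vals, groups)
        ref = sps.f_oneway(*arrays)
        assert res.f == pytest.approx(ref.statistic)
        assert res.p == pytest.approx(ref.pvalue)

    @given(st.integers(0, 1000))
    def test_sum_of_squares_decomposition(self, seed):
        rng = np.random.default_rng(seed)
        sizes = rng.integers(2, 8, size=rng.integers(2, 5))
        vals = rng.normal(0, 1, sizes.sum())
        groups = np.repeat(np.arange(sizes.size), sizes)
        res = pdr.one_way_anova(vals, groups)
        assert res.ss_total == pytest.approx(res.ss_between + res.ss_within, rel=1e-9)

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            pdr.one_way_anova([1.0, 1.0, 1.0, 1.0], ["a", "a", "b", "b"])


class TestTukey:
    def test_two_separated_groups_get_distinct_letters(self, rng):
        vals = np.concatenate([rng.normal(0, 0.1, 6), rng.normal(5, 0.1, 6)])
        groups = np.repeat(["lo", "hi"], 6)
        res = pdr.tukey_hsd(vals, groups)
        assert res.letters["hi"] != res.letters["lo"]
        assert set(res.letters.values()) == {"a", "b"}

    def test_three_identical_groups_share_a_letter(self, rng):
        base = rng.normal(0, 1, 7)
        vals = np.concatenate([base, base, base])
        groups = np.repeat(list("abc"), 7)
        res = pdr.tukey_hsd(vals, groups)
        assert len(set(res.letters.values())) == 1

    def test_two_cluster_pattern(self, rng):
        vals = np.concatenate(
            [rng.normal(0, 0.2, 6), rng.normal(0.1, 0.2, 6), rng.normal(8, 0.2, 6), rng.normal(8.1, 0.2, 6)]
        )
        groups = np.repeat(list("wxyz"), 6)
        res = pdr.tukey_hsd(vals, groups)
        assert res.letters["w"] == res.letters["x"]
        assert res.letters["y"] == res.letters["z"]
        assert res.letters["w"] != res.letters["y"]

    def test_pvalues_match_scipy_tukey(self, rng):
        arrays = [rng.normal(m, 1, 6) for m in (0, 1, 3)]
        vals = np.concatenate(arrays)
        groups = np.repeat(list("abc"), 6)
        res = pdr.tukey_hsd(vals, groups)
        ref = sps.tukey_hsd(*arrays)
        got = {frozenset((g1, g2)): p for g1, g2, p in zip(res.pairs["group_a"], res.pairs["group_b"], res.pairs["p"])}
        for i, gi in enumerate("abc"):
            for j, gj in enumerate("abc"):
                if i < j:
                    assert got[frozenset((gi, gj))] == pytest.approx(ref.pvalue[i, j], abs=1e-6)

    @given(st.integers(0, 300))
    def test_letters_consistent_with_decisions(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 5))
        means = rng.uniform(0, 4, k)
        vals = np.concatenate([rng.normal(m, 0.5, 5) for m in means])
        groups = np.repeat([f"g{i}" for i in range(k)], 5)
        res = pdr.tukey_hsd(vals, groups)
        for _, row in res.pairs.iterrows():
            shared = set(res.letters[row["group_a"]]) & set(res.letters[row["group_b"]])
            if row["significant"]:
                assert not shared
            else:
                assert shared


class TestSlopeTest:
    def test_exact_line(self):
        x = np.arange(10.0)
        res = pdr.slope_test(x, 2 * x)
        assert res.slope == pytest.approx(2.0)
        assert res.p < 1e-10

    def test_null_slope_near_zero(self, rng):
        x = rng.uniform(0, 10, 200)
        res = pdr.slope_test(x, rng.normal(0, 1, 200))
        assert abs(res.slope) < 0.2
        assert res.p > 1e-4

    def test_f_matches_rss_oracle(self, rng):
        x = rng.uniform(0, 10, 30)
        y = x + rng.normal(0, 1, 30)
        res = pdr.slope_test(x, y)
        # from-scratch residual-sum-of-squares F statistic
        b = np.cov(x, y, bias=True)[0, 1] / x.var()
        a = y.mean() - b * x.mean()
        rss1 = np.sum((y - a - b * x) ** 2)
        rss0 = np.sum((y - y.mean()) ** 2)
        f_oracle = (rss0 - rss1) / (rss1 / (x.size - 2))
        assert res.f == pytest.approx(f_oracle, rel=1e-6)
        assert res.p == pytest.approx(float(sps.f.sf(f_oracle, 1, x.size - 2)), rel=1e-6)

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError):
            pdr.slope_test([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestLeafArea:
    def test_definition(self):
        out = pdr.leaf_area_from_biomass({"current": 10.0}, {"current": 50.0})
        assert out["areas_cm2"]["current"] == 500.0

    def test_zero_current_biomass_gives_old_proportion_one(self):
        out = pdr.leaf_area_from_biomass(
            {"current": 0.0, "old": 5.0}, {"current": 55.0, "old": 45.0}
        )
        assert out["proportion_old"] == pytest.approx(1.0)

    def test_negative_biomass_rejected(self):
        with pytest.raises(ValueError):
            pdr.leaf_area_from_biomass({"current": -1.0}, {"current": 55.0})
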