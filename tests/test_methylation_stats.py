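"""Relative methylation index, critical-CpG flagging, group contrasts."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import rankdata

from cpgprofiler import methylation_stats as ms
from cpgprofiler import synthetic_data
from cpgprofiler.data_io import ValidationError
from conftest import make_matrix


class TestPromoterMean:
    def test_simple_mean(self):
        m = make_matrix([[80, 100, 120 - 20]])
        assert ms.promoter_mean_methylation(m, "s1") == pytest.approx((80 + 100 + 100) / 3)

    def test_missing_excluded_pairwise(self):
        m = make_matrix([[80, np.nan, 90.0]])
        assert ms.promoter_mean_methylation(m, "s1") == pytest.approx(85.0)

    def test_all_missing_is_error(self):
        m = make_matrix([[np.nan, np.nan]])
        with pytest.raises(ValidationError):
            ms.promoter_mean_methylation(m, "s1")


class TestRelativeIndex:
    def test_examples(self):
        m = make_matrix([[40, 50, 60]])
        t = ms.relative_methylation_index(m)
        np.testing.assert_allclose(t.indices.iloc[0], [0.8, 1.0, 1.2])

    def test_all_equal_gives_all_ones(self):
        m = make_matrix([[55, 55, 55], [20, 20, 20]])
        t = ms.relative_methylation_index(m)
        np.testing.assert_allclose(t.indices.to_numpy(), 1.0)

    def test_per_sample_mean_of_indices_is_one(self):
        rng = np.random.default_rng(0)
        m = make_matrix(rng.uniform(5, 95, size=(8, 12)))
        t = ms.relative_methylation_index(m)
        np.testing.assert_allclose(t.indices.mean(axis=1), 1.0, atol=1e-12)

    @settings(max_examples=50, derandomize=True)
    @given(st.floats(min_value=0.05, max_value=1.0))
    def test_scale_invariance(self, c):
        base = np.array([[30.0, 60.0, 90.0]])
        t1 = ms.relative_methylation_index(make_matrix(base))
        t2 = ms.relative_methylation_index(make_matrix(base * c))
        np.testing.assert_allclose(t1.indices.to_numpy(), t2.indices.to_numpy(), rtol=1e-12)

    def test_zero_denominator_yields_missing_with_warning(self):
        m = make_matrix([[0.0, 0.0], [50.0, 70.0]])
        with pytest.warns(UserWarning, match="promoter mean is 0"):
            t = ms.relative_methylation_index(m)
        assert t.indices.loc["s1"].isna().all()
        assert np.isfinite(t.indices.loc["s2"]).all()

    def test_planted_effect_recovered_at_high_depth(self):
        # effect 1.5 at CpG 3 (index 2), rest neutral: analytic median index
        # is 1.5 / mean(effects)
        effects = np.ones(10)
        effects[2] = 1.5
        m, _, _ = synthetic_data.generate_panel(
            8, 10, 1, cpg_effects=effects, read_depth=10**6,
            overdispersion=np.inf, seed=5, line_mean_range=(20, 60),
        )
        t = ms.relative_methylation_index(m)
        expected = 1.5 / effects.mean()
        assert abs(t.median_index().iloc[2] - expected) < 0.05


def _signflip_oracle(d):
    """Independent exhaustive sign-flip reference for the one-sample test."""
    d = np.asarray(d, float)
    d = d[d != 0]
    r = rankdata(np.abs(d))
    mu = r.sum() / 2
    t_obs = r[d > 0].sum()
    hits = total = 0
    n = len(d)
    for mask in range(2 ** n):
        t = sum(r[i] for i in range(n) if mask >> i & 1)
        total += 1
        if abs(t - mu) >= abs(t_obs - mu) - 1e-9:
            hits += 1
    return hits / total


class TestCriticalFlags:
    def test_all_ones_is_neutral(self):
        m = make_matrix(np.full((5, 4), 42.0))
        flags = ms.flag_critical_cpgs(ms.relative_methylation_index(m))
        assert (flags["direction"] == "neutral").all()

    def test_uniform_high_index_matches_enumeration(self):
        # 12 samples, index exactly 1.5 at one CpG: p is the exact sign-flip
        # tail 2/2^12
        idx = ms.RelativeIndexTable(
            indices=make_matrix(np.tile([75.0, 25.0], (12, 1))).aggregate() / 50.0,
            promoter_means=None,
        )
        flags = ms.flag_critical_cpgs(idx)
        assert flags.iloc[0]["direction"] == "high"
        assert flags.iloc[0]["p"] == pytest.approx(2 / 4096)
        assert flags.iloc[0]["p"] == pytest.approx(_signflip_oracle(np.full(12, 0.5)))

    def test_two_samples_untestable(self):
        m = make_matrix([[80, 100.0], [60, 80]])
        flags = ms.flag_critical_cpgs(ms.relative_methylation_index(m))
        assert (~flags["testable"]).all()
        assert (flags["direction"] == "neutral").all()

    @pytest.mark.parametrize("seed", range(5))
    def test_signflip_p_matches_oracle_on_random_differences(self, seed):
        rng = np.random.default_rng(seed)
        d = np.round(rng.normal(0, 1, size=rng.integers(4, 10)), 1)
        assert ms.wilcoxon_signed_rank(d) == pytest.approx(_signflip_oracle(d))


def _mw_oracle(a, b):
    """Independent enumeration of the two-sided Mann-Whitney p."""
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    n_a = len(a)
    m = n_a * len(b)
    const = n_a * (n_a + 1) / 2
    u_obs = ranks[:n_a].sum() - const
    hits = total = 0
    for idx in combinations(range(len(pooled)), n_a):
        u = sum(ranks[i] for i in idx) - const
        total += 1
        if abs(u - m / 2) >= abs(u_obs - m / 2) - 1e-9:
            hits += 1
    return hits / total


class TestGroupCompare:
    def test_separated_groups_exact_p(self):
        u, p = ms.group_compare([1, 2, 3], [4, 5, 6])
        assert u == 0 and p == pytest.approx(2 / 20)

    def test_identical_sets_give_p_one(self):
        _, p = ms.group_compare([1, 2, 3], [3, 1, 2])
        assert p == pytest.approx(1.0)

    @settings(max_examples=100, derandomize=True)
    @given(
        st.lists(st.integers(0, 5), min_size=1, max_size=4),
        st.lists(st.integers(0, 5), min_size=1, max_size=4),
    )
    def test_exact_p_matches_enumeration_with_ties(self, a, b):
        a, b = np.array(a, float), np.array(b, float)
        _, p = ms.group_compare(a, b)
        assert p == pytest.approx(_mw_oracle(a, b))

    def test_kruskal_all_ties_h_zero(self):
        h, p = ms.group_compare([5, 5], [5, 5], [5, 5], test="kruskal_wallis")
        assert h == 0.0

    def test_kruskal_needs_three_groups(self):
        with pytest.raises(ValueError, match="mann_whitney"):
            ms.group_compare([1], [2], test="kruskal_wallis")

    def test_large_groups_use_asymptotic(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 20), rng.normal(1, 1, 20)
        _, p = ms.group_compare(a, b)
        assert 0 < p < 1


class TestDemethylationContrast:
    def test_identical_conditions_all_zero(self):
        m = make_matrix(np.full((2, 3), 80.0), n_replicates=3)
        res = ms.demethylation_contrast(m, m)
        assert (res["per_cpg"]["delta_methylation"] == 0).all()

    def test_noise_free_reduction_with_exact_p(self):
        vehicle = make_matrix([[90.0] * 4], n_replicates=3)
        treated = make_matrix([[40.0] * 4], n_replicates=3)
        res = ms.demethylation_contrast(treated, vehicle)
        assert (res["per_cpg"]["delta_methylation"] == -50).all()
        # 3 vs 3, all ties within groups: enumeration oracle
        expected = _mw_oracle(np.full(3, 40.0), np.full(3, 90.0))
        assert res["per_cpg"]["p"].iloc[0] == pytest.approx(expected)

    def test_expression_re_expression_sign(self):
        m = make_matrix([[50.0, 60.0]], n_replicates=3)
        from cpgprofiler.synthetic_data import generate_panel

        _, e_v, _ = generate_panel(3, 2, 1, line_means=[50, 50, 50],
                                   coupling_noise_sd=0.0, intercept=15 - 0.15 * 50, seed=0)
        _, e_t, _ = generate_panel(3, 2, 1, line_means=[50, 50, 50],
                                   coupling_noise_sd=0.0, intercept=10 - 0.15 * 50, seed=0)
        res = ms.demethylation_contrast(m, m, e_t, e_v)
        assert res["ddct"] == pytest.approx(-5.0)
        assert res["re_expressed"]

    def test_mismatched_labels_rejected(self):
        a = make_matrix([[50, 60]], labels=["CpG_1", "CpG_2"])
        b = make_matrix([[50, 60]], labels=["CpG_1", "CpG_3"])
        with pytest.raises(ValidationError):
            ms.demethylation_contrast(a, b)
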