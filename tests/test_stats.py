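"""Paired comparison battery vs closed forms, enumeration and scipy oracles."""

from itertools import product

import numpy as np
import pytest
from scipy import stats as sp_stats

from semgbench.stats import (
    PairedSample,
    bonferroni_adjust,
    compare_models,
    effect_sizes,
    friedman,
    nemenyi_posthoc,
    paired_t,
    wilcoxon_signed_rank,
)


def sample_from_diffs(diffs, base=0.9):
    d = np.asarray(diffs, dtype=float)
    b = np.linspace(base, base + 0.01, len(d))
    return PairedSample(
        subjects=tuple(f"S{i}" for i in range(len(d))), a=b + d, b=b
    )


def enumeration_wilcoxon_p(diffs):
    """Independent oracle: full 2^n enumeration on average ranks."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    ranks = sp_stats.rankdata(np.abs(d))
    total = ranks.sum()
    w_obs = min(ranks[d > 0].sum(), ranks[d < 0].sum())
    count = sum(
        1
        for signs in product([0, 1], repeat=len(ranks))
        if min(np.dot(signs, ranks), total - np.dot(signs, ranks)) <= w_obs + 1e-12
    )
    return count / 2.0 ** len(ranks)


class TestPairedT:
    def test_null_case(self):
        s = sample_from_diffs([0, 0, 0, 0])
        t0, p0 = paired_t(s)
        assert (t0, p0) == (0.0, 1.0)

    def test_closed_form_differences_1_to_5(self):
        d = [1, 2, 3, 4, 5]
        t, p = paired_t(sample_from_diffs(d))
        sd = np.std(d, ddof=1)
        assert sd == pytest.approx(1.5811, abs=1e-4)
        assert t == pytest.approx(3 / (sd / np.sqrt(5)))
        assert t == pytest.approx(4.2426, abs=1e-3)
        # cross-check with scipy's paired t-test
        s = sample_from_diffs(d)
        ref = sp_stats.ttest_rel(s.a, s.b)
        assert t == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_antisymmetry(self):
        s = sample_from_diffs([0.5, 1.0, -0.2, 0.8])
        swapped = PairedSample(subjects=s.subjects, a=s.b, b=s.a)
        t1, p1 = paired_t(s)
        t2, p2 = paired_t(swapped)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)


class TestWilcoxon:
    def test_all_positive_three_differences(self):
        W, p, _ = wilcoxon_signed_rank(sample_from_diffs([1, 2, 3]), mode="exact")
        assert W == 0.0
        assert p == pytest.approx(0.25)

    def test_tied_symmetric_differences(self):
        W, p, _ = wilcoxon_signed_rank(sample_from_diffs([-1, 1]), mode="exact")
        assert p == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_exact_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        d = np.round(rng.standard_normal(10), 2)
        d[d == 0] = 0.5
        W, p, _ = wilcoxon_signed_rank(sample_from_diffs(d), mode="exact")
        assert p == pytest.approx(enumeration_wilcoxon_p(d))

    @pytest.mark.parametrize("seed", [5, 6])
    def test_exact_matches_scipy_on_tie_free_data(self, seed):
        rng = np.random.default_rng(seed)
        d = rng.standard_normal(11)  # continuous -> tie-free
        W, p, _ = wilcoxon_signed_rank(sample_from_diffs(d), mode="exact")
        ref = sp_stats.wilcoxon(d, mode="exact")
        assert W == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_zero_differences_dropped_and_counted(self):
        W, p, zeros = wilcoxon_signed_rank(sample_from_diffs([0, 0, 1, 2, -3]))
        assert zeros == 2

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            wilcoxon_signed_rank(sample_from_diffs([0, 0, 0]))

    def test_approx_mode_reasonable_on_large_n(self):
        rng = np.random.default_rng(9)
        d = rng.standard_normal(40) + 0.6
        _, p_approx, _ = wilcoxon_signed_rank(sample_from_diffs(d), mode="approx")
        ref = sp_stats.wilcoxon(d, correction=False, mode="approx")
        assert p_approx == pytest.approx(ref.pvalue, rel=1e-6)


class TestFriedman:
    def test_identical_models(self):
        m = np.tile(np.array([[0.9, 0.9, 0.9]]), (4, 1))
        chi2, p = friedman(m)
        assert chi2 == 0.0 and p == 1.0

    def test_closed_form_full_separation(self):
        # one model always best, one always worst, n=4, k=3
        m = np.array([[0.7, 0.8, 0.9]] * 4)
        chi2, p = friedman(m)
        assert chi2 == pytest.approx(8.0)
        assert p == pytest.approx(0.0183, abs=1e-4)

    def test_column_permutation_invariance(self):
        rng = np.random.default_rng(2)
        m = rng.random((6, 4))
        chi2_a, _ = friedman(m)
        chi2_b, _ = friedman(m[:, [2, 0, 3, 1]])
        assert chi2_a == pytest.approx(chi2_b)

    def test_matches_scipy_on_tie_free_data(self):
        rng = np.random.default_rng(8)
        m = rng.random((10, 4))
        chi2, p = friedman(m)
        ref = sp_stats.friedmanchisquare(*m.T)
        assert chi2 == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_incomplete_matrix_rejected(self):
        m = np.array([[0.9, 0.8], [np.nan, 0.7]])
        with pytest.raises(ValueError, match="incomplete"):
            friedman(m)


class TestNemenyi:
    def test_identical_columns_p_one(self):
        rng = np.random.default_rng(1)
        col = rng.random(8)
        m = np.column_stack([col, col, rng.random(8)])
        res = nemenyi_posthoc(m)
        assert res["p_values"][0, 1] == pytest.approx(1.0)

    def test_critical_difference_closed_form(self):
        rng = np.random.default_rng(4)
        m = rng.random((10, 3))
        res = nemenyi_posthoc(m, alpha=0.05)
        q = sp_stats.studentized_range.ppf(0.95, 3, np.inf) / np.sqrt(2)
        assert res["critical_difference"] == pytest.approx(q * np.sqrt(12 / 60))

    def test_significance_flag_matches_cd_rule(self):
        # strongly separated columns: rank diff 2 between extremes
        m = np.array([[0.1, 0.5, 0.9]] * 10, dtype=float)
        m += np.random.default_rng(0).normal(0, 1e-3, m.shape)
        res = nemenyi_posthoc(m)
        diffs = np.abs(res["mean_ranks"][:, None] - res["mean_ranks"][None, :])
        np.testing.assert_array_equal(
            res["significant"], diffs > res["critical_difference"]
        )

    def test_two_models_rejected(self):
        with pytest.raises(ValueError, match="Wilcoxon"):
            nemenyi_posthoc(np.random.default_rng(0).random((5, 2)))


class TestEffectSizes:
    def test_constant_differences_rejected(self):
        s = PairedSample(subjects=("a", "b", "c"),
                         a=[1.5, 2.5, 3.5], b=[1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="degenerate"):
            effect_sizes(s)

    def test_closed_form_d(self):
        d, r = effect_sizes(sample_from_diffs([1, 2, 3, 4, 5]))
        assert d == pytest.approx(3 / 1.5811, abs=1e-3)
        assert d == pytest.approx(1.897, abs=1e-3)

    def test_antisymmetry(self):
        s = sample_from_diffs([0.4, 0.9, -0.1, 0.7, 0.2])
        neg = sample_from_diffs([-0.4, -0.9, 0.1, -0.7, -0.2])
        d1, r1 = effect_sizes(s)
        d2, r2 = effect_sizes(neg)
        assert d1 == pytest.approx(-d2)
        assert r1 == pytest.approx(-r2)


class TestBonferroni:
    def test_reference_family_of_four(self):
        adj, alpha_adj = bonferroni_adjust([0.049, 0.043, 0.320, 0.213], m=4)
        np.testing.assert_allclose(adj, [0.196, 0.172, 1.000, 0.852])
        assert alpha_adj == pytest.approx(0.0125)

    def test_single_test_family_is_identity(self):
        adj, _ = bonferroni_adjust([0.3], m=1)
        assert adj[0] == pytest.approx(0.3)

    def test_family_must_cover_pvalues(self):
        with pytest.raises(ValueError, match="family"):
            bonferroni_adjust([0.1, 0.2, 0.3], m=2)

    def test_adjusted_never_below_raw_and_capped(self):
        rng = np.random.default_rng(3)
        p = rng.random(6)
        adj, _ = bonferroni_adjust(p, m=8)
        assert np.all(adj >= p)
        assert np.all(adj <= 1.0)


def test_compare_models_full_battery():
    rng = np.random.default_rng(11)
    base = 0.9 + 0.02 * rng.standard_normal(10)
    s = PairedSample(
        subjects=tuple(f"P{i}" for i in range(10)),
        a=base + 0.015 + 0.01 * rng.standard_normal(10),
        b=base,
    )
    rep = compare_models(s, label="CViT vs CNN", family_size=4)
    d = rep.to_dict()
    assert d["alpha_adjusted"] == pytest.approx(0.0125)
    assert d["t_p_adjusted"] >= d["t_p"]
    assert d["wilcoxon_p_adjusted"] >= d["wilcoxon_p"]
    assert 0 <= d["wilcoxon_p"] <= 1
    # consistency of flags with thresholds
    assert d["significant"]["t"] == (d["t_p"] < 0.05)
    assert d["significant_adjusted"]["t"] == (d["t_p_adjusted"] < 0.05)
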