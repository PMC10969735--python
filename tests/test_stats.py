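"""Friedman, Conover post hoc, Spearman and descriptives.

Reference checks use independent implementations: scipy.stats for the
Friedman statistic and Spearman's rho, and a two-way (block + treatment)
ANOVA on within-block ranks via statsmodels for the Conover pairwise
comparisons, which are algebraically Fisher's LSD on those ranks.
"""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from ctsib_sway import (
    BlockMatrix,
    conover_posthoc,
    friedman_test,
    rank_within_blocks,
    spearman_correlation,
    summarize_median_iqr,
)
from ctsib_sway.errors import DegenerateProfileError, InputError
from ctsib_sway.stats import holm_adjust


def lsd_on_ranks(m: np.ndarray):
    """Independent oracle: Fisher's LSD from a two-way ANOVA of the ranks."""
    ranks = np.apply_along_axis(sps.rankdata, 1, m)
    n, k = m.shape
    long = pd.DataFrame(
        {
            "r": ranks.ravel(),
            "block": np.repeat(np.arange(n), k).astype(str),
            "trt": np.tile(np.arange(k), n).astype(str),
        }
    )
    fit = sm.OLS.from_formula("r ~ C(block) + C(trt)", long).fit()
    means = ranks.mean(axis=0)
    out = {}
    for a in range(k):
        for b in range(a + 1, k):
            t = (means[a] - means[b]) / np.sqrt(2 * fit.mse_resid / n)
            out[(a, b)] = (t, 2 * sps.t.sf(abs(t), fit.df_resid))
    return out


class TestRankWithinBlocks:
    def test_plain_and_tied_blocks(self):
        r = rank_within_blocks(BlockMatrix(np.array([[3.0, 1.0, 2.0], [1.0, 1.0, 2.0]])))
        np.testing.assert_array_equal(r[0], [3, 1, 2])
        np.testing.assert_array_equal(r[1], [1.5, 1.5, 3])

    @settings(deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_row_sums_equal_k_times_k_plus_1_over_2(self, seed):
        rng = np.random.default_rng(seed)
        n, k = rng.integers(2, 10), rng.integers(2, 7)
        m = np.round(rng.normal(size=(n, k)), 1)  # ties likely
        r = rank_within_blocks(BlockMatrix(m))
        np.testing.assert_allclose(r.sum(axis=1), k * (k + 1) / 2)


class TestFriedman:
    def test_perfect_concordance_closed_form(self):
        m = np.tile(np.arange(1.0, 5.0), (5, 1))
        res = friedman_test(BlockMatrix(m))
        assert res.statistic == pytest.approx(15.0)  # n(k-1)
        assert res.df == 3

    @settings(deadline=None, derandomize=True)
    @given(n=st.integers(min_value=2, max_value=12), k=st.integers(min_value=2, max_value=6))
    def test_concordance_closed_form_holds_generally(self, n, k):
        m = np.tile(np.arange(1.0, k + 1), (n, 1))
        assert friedman_test(BlockMatrix(m)).statistic == pytest.approx(n * (k - 1))

    def test_fully_tied_matrix(self):
        res = friedman_test(BlockMatrix(np.ones((4, 3))))
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_matches_scipy_on_random_matrices(self):
        rng = np.random.default_rng(123)
        for i in range(50):
            m = rng.normal(size=(8, 4))
            if i % 3 == 0:
                m = np.round(m, 1)  # induce ties
            res = friedman_test(BlockMatrix(m))
            ref = sps.friedmanchisquare(*m.T)
            assert res.statistic == pytest.approx(ref.statistic, abs=1e-10)
            assert res.p_value == pytest.approx(ref.pvalue, abs=1e-10)

    @settings(deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.normal(size=(6, 4))
        q1 = friedman_test(BlockMatrix(m)).statistic
        q2 = friedman_test(BlockMatrix(np.exp(m))).statistic
        assert q1 == pytest.approx(q2, abs=1e-12)

    def test_too_small_matrix_rejected(self):
        with pytest.raises(InputError):
            BlockMatrix(np.ones((1, 4)))


class TestConoverPosthoc:
    def test_all_tied_is_degenerate(self):
        with pytest.raises(DegenerateProfileError):
            conover_posthoc(BlockMatrix(np.ones((5, 3))))

    def test_extreme_treatment_dominates_statistics(self, rng):
        m = rng.normal(size=(10, 4)) + 5.0
        m[:, 0] = rng.uniform(0, 0.1, size=10)  # strictly smallest everywhere
        pairs = {(p.treatment_a, p.treatment_b): abs(p.statistic) for p in conover_posthoc(BlockMatrix(m))}
        with_a = [v for k, v in pairs.items() if "t1" in k]
        without_a = [v for k, v in pairs.items() if "t1" not in k]
        assert min(with_a) > max(without_a)

    def test_matches_anova_lsd_oracle(self):
        rng = np.random.default_rng(321)
        for i in range(50):
            m = rng.normal(size=(8, 4))
            if i % 3 == 0:
                m = np.round(m, 1)
            ref = lsd_on_ranks(m)
            for p in conover_posthoc(BlockMatrix(m)):
                a, b = int(p.treatment_a[1:]) - 1, int(p.treatment_b[1:]) - 1
                t_ref, p_ref = ref[(a, b)]
                assert p.statistic == pytest.approx(t_ref, abs=1e-8)
                assert p.p_unadjusted == pytest.approx(p_ref, abs=1e-8)

    def test_p_monotone_in_rank_sum_difference(self, rng):
        m = rng.normal(size=(12, 5))
        bm = BlockMatrix(m)
        R = rank_within_blocks(bm).sum(axis=0)
        labels = {f"t{j + 1}": j for j in range(5)}
        pairs = conover_posthoc(bm)
        diffs = [abs(R[labels[p.treatment_a]] - R[labels[p.treatment_b]]) for p in pairs]
        order = np.argsort(diffs)
        ps = np.array([p.p_unadjusted for p in pairs])[order]
        assert all(ps[i] >= ps[i + 1] - 1e-12 for i in range(len(ps) - 1))

    def test_holm_adjustment_never_smaller(self, rng):
        m = rng.normal(size=(9, 4))
        for p in conover_posthoc(BlockMatrix(m), adjust="holm"):
            assert p.p_adjusted >= p.p_unadjusted - 1e-15

    def test_holm_adjust_known_values(self):
        np.testing.assert_allclose(
            holm_adjust(np.array([0.01, 0.04, 0.03])), [0.03, 0.06, 0.06]
        )


class TestSpearman:
    def test_monotone_and_reversed(self):
        up = spearman_correlation(np.array([1, 2, 3, 4.0]), np.array([10, 20, 30, 40.0]))
        down = spearman_correlation(np.array([1, 2, 3, 4.0]), np.array([8, 6, 4, 2.0]))
        assert up.rho == pytest.approx(1.0)
        assert down.rho == pytest.approx(-1.0)

    def test_matches_scipy_on_random_vectors(self):
        rng = np.random.default_rng(456)
        for i in range(50):
            x, y = rng.normal(size=27), rng.normal(size=27)
            if i % 4 == 0:
                x = np.round(x, 1)  # ties
            res = spearman_correlation(x, y)
            ref = sps.spearmanr(x, y)
            assert res.rho == pytest.approx(ref.statistic, abs=1e-10)
            assert res.p_value == pytest.approx(ref.pvalue, abs=1e-10)

    @settings(deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_symmetry_and_monotone_transform_invariance(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=15), rng.normal(size=15)
        a = spearman_correlation(x, y)
        assert spearman_correlation(y, x).rho == pytest.approx(a.rho, abs=1e-12)
        assert spearman_correlation(np.exp(x), y).rho == pytest.approx(a.rho, abs=1e-12)

    def test_constant_vector_warns_and_returns_zero(self, caplog):
        with caplog.at_level("WARNING"):
            res = spearman_correlation(np.ones(5), np.arange(5.0))
        assert res.rho == 0.0 and res.p_value == 1.0
        assert caplog.records

    def test_length_mismatch_rejected(self):
        with pytest.raises(InputError):
            spearman_correlation(np.arange(4.0), np.arange(5.0))


class TestMedianIqr:
    @pytest.mark.parametrize(
        "values, expected",
        [
            ([1, 2, 3, 4, 5], (3.0, 2.0)),
            ([7.5], (7.5, 0.0)),
            ([1, 1, 1, 9], (1.0, 2.0)),  # type-7: Q3 = 1 + 0.25*(9-1) = 3
        ],
    )
    def test_known_values(self, values, expected):
        med, iqr = summarize_median_iqr(np.array(values, dtype=float))
        assert (med, iqr) == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(InputError):
            summarize_median_iqr(np.array([]))
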