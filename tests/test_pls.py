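"""Unit and property tests for the PLS-correlation engine."""

import itertools

import numpy as np
import pytest
from scipy import stats

from boldvar.pls import (BehaviorBlock, GroupedDataBlock, PLSError,
                         behavioral_pls, bootstrap_saliences, brain_scores,
                         group_mean_center, mean_centered_pls,
                         permutation_test, stack_correlations, svd_lv)


def make_block(X, groups):
    return GroupedDataBlock(np.asarray(X, float), np.asarray(groups))


class TestGroupMeanCenter:
    def test_two_point_centering(self):
        X = np.array([[1.0], [1.0], [3.0], [3.0]])
        M = group_mean_center(make_block(X, ["a", "a", "b", "b"]))
        assert np.allclose(M, [[-1.0], [1.0]])

    def test_identical_group_means_give_null_contrast(self):
        X = np.array([[1.0, 2.0], [3.0, 0.0], [0.0, 1.0], [4.0, 1.0]])
        M = group_mean_center(make_block(X, ["a", "a", "b", "b"]))
        assert np.allclose(M, 0.0)
        assert np.allclose(svd_lv(M).S, 0.0)

    def test_hand_computed_deviations(self):
        # group a rows: (1,2,3),(3,4,5) -> mean (2,3,4); group b: (5,0,1),(7,2,3)
        # -> mean (6,1,2); grand mean (4,2,3)
        X = np.array([[1, 2, 3], [3, 4, 5], [5, 0, 1], [7, 2, 3]], float)
        M = group_mean_center(make_block(X, list("aabb")))
        assert np.allclose(M, [[-2, 1, 1], [2, -1, -1]])

    def test_single_group_is_an_error(self):
        with pytest.raises(PLSError):
            make_block(np.eye(3), ["a", "a", "a"])


class TestStackCorrelations:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(0)
        y = rng.standard_normal(12)
        X = y[:, None]
        R = stack_correlations(make_block(X, ["a"] * 6 + ["b"] * 6),
                               BehaviorBlock(y))
        assert np.allclose(R, 1.0)

    def test_hand_computed_pearson(self):
        X = np.array([[1.0, 2.0], [2.0, 1.0], [4.0, 3.0], [3.0, 5.0]])
        y = np.array([0.0, 1.0, 1.0, 3.0])
        g = np.array(["a", "a", "b", "b"])
        R = stack_correlations(make_block(X, g), BehaviorBlock(y))
        expect = np.array([
            [stats.pearsonr(X[:2, 0], y[:2])[0], stats.pearsonr(X[:2, 1], y[:2])[0]],
            [stats.pearsonr(X[2:, 0], y[2:])[0], stats.pearsonr(X[2:, 1], y[2:])[0]],
        ])
        assert np.allclose(R, expect)

    def test_row_order_is_group_major(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((8, 3))
        Y = rng.standard_normal((8, 2))
        g = np.array(["a"] * 4 + ["b"] * 4)
        R = stack_correlations(make_block(X, g), BehaviorBlock(Y))
        assert R.shape == (4, 3)
        first_group = stack_correlations(
            make_block(X[:4], ["a", "a", "b", "b"]), BehaviorBlock(Y[:4]))
        # rows 0..1 of R are group a's two behaviors
        Xa, Ya = X[:4], Y[:4]
        za = (Xa - Xa.mean(0)) / Xa.std(0)
        ya = (Ya - Ya.mean(0)) / Ya.std(0)
        assert np.allclose(R[:2], ya.T @ za / 4)

    def test_zero_variance_element_gets_zero_with_warning(self):
        X = np.array([[1.0, 5.0], [2.0, 5.0], [3.0, 1.0], [4.0, 2.0]])
        y = np.array([1.0, 2.0, 3.0, 4.0])
        with pytest.warns(UserWarning, match="zero-variance"):
            R = stack_correlations(make_block(X, list("aabb")), BehaviorBlock(y))
        assert R[0, 1] == 0.0


class TestSvdLV:
    def test_identity_singular_values(self):
        d = svd_lv(np.eye(2))
        assert np.allclose(d.S, [1.0, 1.0])

    def test_rank_one_closed_form(self):
        a = np.array([2.0, 0.0])  # norm 2
        b = np.array([0.0, 3.0, 0.0])  # norm 3
        d = svd_lv(np.outer(a, b))
        assert np.isclose(d.S[0], 6.0)
        assert np.allclose(d.S[1:], 0.0)

    def test_reconstruction_and_orthonormality(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            M = rng.standard_normal((6, 8))
            d = svd_lv(M)
            assert np.linalg.norm(d.reconstruct() - M) < 1e-8
            assert np.allclose(d.U.T @ d.U, np.eye(6), atol=1e-10)
            assert np.allclose(d.V.T @ d.V, np.eye(6), atol=1e-10)
            assert np.isclose(d.covariance_fraction.sum(), 1.0)
            assert np.all(np.diff(d.S) <= 1e-12)

    def test_matches_eigendecomposition_oracle(self):
        """U, S, V agree (up to sign) with brute-force eigendecomposition
        of M'M and MM'."""
        rng = np.random.default_rng(3)
        for _ in range(20):
            M = rng.standard_normal((6, 8))
            d = svd_lv(M)
            wU, Z = np.linalg.eigh(M.T @ M)  # right vectors
            wV, W = np.linalg.eigh(M @ M.T)  # left vectors
            order = np.argsort(wU)[::-1][:6]
            assert np.allclose(np.sqrt(np.maximum(wU[order], 0)), d.S, atol=1e-8)
            for k in range(6):
                if d.S[k] < 1e-10:
                    continue
                assert abs(abs(Z[:, order[k]] @ d.U[:, k]) - 1) < 1e-8
            orderV = np.argsort(wV)[::-1]
            for k in range(6):
                if d.S[k] < 1e-10:
                    continue
                assert abs(abs(W[:, orderV[k]] @ d.V[:, k]) - 1) < 1e-8

    def test_sign_convention_largest_v_entry_positive(self):
        rng = np.random.default_rng(4)
        M = rng.standard_normal((5, 7))
        d = svd_lv(M)
        for k in range(d.n_lv):
            assert d.V[np.argmax(np.abs(d.V[:, k])), k] > 0


class TestPermutation:
    def test_add_one_counting_convention(self):
        # strong planted contrast: observed S1 should beat every permutation
        rng = np.random.default_rng(5)
        X = np.vstack([rng.normal(0, 0.05, (10, 4)) + 5,
                       rng.normal(0, 0.05, (10, 4)) - 5])
        block = make_block(X, ["a"] * 10 + ["b"] * 10)
        d = svd_lv(group_mean_center(block))
        p = permutation_test(block, None, d.S, n_perm=1000, seed=0)
        assert np.isclose(p[0], 1.0 / 1001.0)

    def test_matches_exhaustive_enumeration(self):
        """Monte-Carlo permutation p agrees with exhaustive enumeration of
        all 720 row orders at n=6."""
        rng = np.random.default_rng(6)
        X = rng.standard_normal((6, 3)) + np.array([1, 1, 1, -1, -1, -1])[:, None]
        g = np.array(["a"] * 3 + ["b"] * 3)
        block = make_block(X, g)
        S_obs = svd_lv(group_mean_center(block)).S
        count = 0
        total = 0
        for perm in itertools.permutations(range(6)):
            b = make_block(X[list(perm)], g)
            Sp = np.linalg.svd(group_mean_center(b), compute_uv=False)
            count += Sp[0] >= S_obs[0]
            total += 1
        p_exact = (1 + count) / (1 + total)
        p_mc = permutation_test(block, None, S_obs, n_perm=4000, seed=1)[0]
        assert abs(p_mc - p_exact) < 0.02


def _structured_behavioral_data(rng, n_per=15, p=30, effect=0.9):
    g = rng.standard_normal(2 * n_per)
    sal = np.zeros(p)
    sal[:10] = 1.0
    X = g[:, None] * sal * effect + rng.standard_normal((2 * n_per, p))
    y = g * effect + rng.standard_normal(2 * n_per) * 0.3
    groups = np.array(["a"] * n_per + ["b"] * n_per)
    return make_block(X, groups), BehaviorBlock(y[:, None])


class TestBootstrap:
    def test_procrustes_alignment_beats_none(self):
        """Without alignment axis reflections corrupt the accumulated
        saliences; with it the bootstrap mean stays close to the original."""
        rng = np.random.default_rng(7)
        block, behav = _structured_behavioral_data(rng)
        M = stack_correlations(block, behav)
        d = svd_lv(M)
        se_u, *_ = bootstrap_saliences(block, behav, d, n_boot=100, seed=2,
                                       procrustes=True)
        se_u_raw, *_ = bootstrap_saliences(block, behav, d, n_boot=100, seed=2,
                                           procrustes=False)
        # aligned SEs cannot exceed reflection-inflated ones on average
        assert se_u[:, 0].mean() <= se_u_raw[:, 0].mean() + 1e-12

    def test_degenerate_two_boot_run_completes_and_flags(self):
        rng = np.random.default_rng(8)
        block, behav = _structured_behavioral_data(rng, n_per=4, p=5)
        M = stack_correlations(block, behav)
        d = svd_lv(M)
        out = bootstrap_saliences(block, behav, d, n_boot=2, seed=3)
        se_u, se_v, bsr, bsr_v, unstable, lo, hi = out
        assert np.all(np.isfinite(se_u) | unstable)
        assert lo.shape == d.V.shape

    def test_bootstrap_ratio_grows_with_sample_size(self):
        """|BSR| of truly salient elements increases from n=20 to n=80."""
        def mean_bsr(n_per, seed):
            rng = np.random.default_rng(seed)
            block, behav = _structured_behavioral_data(rng, n_per=n_per)
            res = behavioral_pls(block, behav, n_perm=10, n_boot=150, seed=seed)
            return np.abs(res.resampling.bootstrap_ratio[:10, 0]).mean()

        small = np.mean([mean_bsr(10, s) for s in range(3)])
        large = np.mean([mean_bsr(40, s) for s in range(3)])
        assert large > small

    def test_bsr_threshold_tracks_ci_zero_exclusion(self):
        """|BSR| >= 2.5 on behavior saliences corresponds to ~95% CIs
        excluding zero, like a z-score."""
        rng = np.random.default_rng(9)
        agree = 0
        total = 0
        for s in range(6):
            block, behav = _structured_behavioral_data(
                np.random.default_rng(100 + s), n_per=15, p=8, effect=0.6)
            res = behavioral_pls(block, behav, n_perm=10, n_boot=300, seed=s)
            r = res.resampling
            for i in range(res.decomposition.V.shape[0]):
                sig_bsr = abs(r.bootstrap_ratio_v[i, 0]) >= 2.5
                sig_ci = (r.ci_low[i, 0] > 0) or (r.ci_high[i, 0] < 0)
                agree += sig_bsr == sig_ci
                total += 1
        assert agree / total > 0.80


class TestBrainScores:
    def test_orthonormal_projection_is_one(self):
        rng = np.random.default_rng(10)
        M = rng.standard_normal((4, 6))
        d = svd_lv(M)
        X = np.vstack([d.U[:, 0], rng.standard_normal((3, 6))])
        bs = brain_scores(make_block(X, list("aabb")), d)
        assert np.isclose(bs.scores[0, 0], 1.0)

    def test_duplicated_subjects_get_duplicated_scores(self):
        rng = np.random.default_rng(11)
        M = rng.standard_normal((4, 5))
        d = svd_lv(M)
        X = rng.standard_normal((2, 5))
        X4 = np.vstack([X, X])
        bs = brain_scores(make_block(X4, list("abab")), d)
        assert np.allclose(bs.scores[:2], bs.scores[2:])

    def test_hand_matrix_product(self):
        X = np.array([[1.0, 2.0], [0.0, 1.0], [3.0, -1.0], [1.0, 1.0]])
        U = np.array([[0.6, -0.8], [0.8, 0.6]])
        d = svd_lv(np.eye(2))
        d.U = U
        bs = brain_scores(make_block(X, list("aabb")), d)
        assert np.allclose(bs.scores, X @ U)

    def test_dimension_mismatch_errors(self):
        d = svd_lv(np.eye(3))
        with pytest.raises(PLSError):
            brain_scores(make_block(np.ones((4, 2)), list("aabb")), d)


class TestModelWrappers:
    def test_single_element_reduces_to_standardized_mean_difference(self):
        """With one element and equal groups, S1 = sqrt(2) * |group-mean
        deviation from the grand mean|."""
        rng = np.random.default_rng(12)
        x = np.concatenate([rng.normal(1.0, 1, 10), rng.normal(-0.5, 1, 10)])
        block = make_block(x[:, None], ["a"] * 10 + ["b"] * 10)
        d = svd_lv(group_mean_center(block))
        dev = abs(x[:10].mean() - x.mean())
        assert np.isclose(d.S[0], np.sqrt(2) * dev)

    def test_reproducible_under_fixed_seed(self):
        rng = np.random.default_rng(13)
        block, behav = _structured_behavioral_data(rng, n_per=8, p=6)
        r1 = behavioral_pls(block, behav, n_perm=50, n_boot=50, seed=42)
        r2 = behavioral_pls(block, behav, n_perm=50, n_boot=50, seed=42)
        assert np.array_equal(r1.resampling.permutation_p,
                              r2.resampling.permutation_p)
        assert np.array_equal(r1.resampling.ci_low, r2.resampling.ci_low)

    def test_planted_effect_detected(self):
        rng = np.random.default_rng(14)
        block, behav = _structured_behavioral_data(rng, n_per=20, p=50)
        res = behavioral_pls(block, behav, n_perm=200, n_boot=50, seed=0)
        assert res.resampling.permutation_p[0] < 0.05
        assert res.decomposition.covariance_fraction[0] > 0.3
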