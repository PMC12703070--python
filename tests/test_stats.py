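"""Association statistics: Spearman, partial Spearman, AD, BH-FDR, CCA."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import linalg, stats as sps
from statsmodels.stats.multitest import multipletests

from neurotyp import (
    CollinearityError,
    DegenerateSignalError,
    RankDeficiencyError,
    anderson_darling_normal,
    associate_family,
    bh_fdr,
    cca,
    partial_spearman,
    spearman,
)


class TestSpearman:
    def test_monotone_increasing_gives_rho_one_exact_p(self):
        rho, p = spearman([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
        assert rho == pytest.approx(1.0)
        assert p == pytest.approx(2 / math.factorial(5))

    def test_reversed_gives_minus_one(self):
        rho, _ = spearman([1, 2, 3, 4, 5], [5, 4, 3, 2, 1])
        assert rho == pytest.approx(-1.0)

    def test_ties_match_rank_then_pearson_oracle(self):
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([1.0, 1, 2, 2, 3])
        rho, _ = spearman(x, y)
        oracle = np.corrcoef(sps.rankdata(x), sps.rankdata(y))[0, 1]
        assert rho == pytest.approx(oracle, abs=1e-12)

    def test_matches_scipy_on_random_instances(self, rng):
        for _ in range(50):
            n = rng.integers(10, 40)
            x = rng.standard_normal(n)
            y = rng.standard_normal(n) + 0.5 * x
            if rng.random() < 0.5:  # inject ties
                x = np.round(x, 1)
            rho, p = spearman(x, y)
            ref = sps.spearmanr(x, y)
            assert rho == pytest.approx(ref.statistic, abs=1e-8)
            assert p == pytest.approx(ref.pvalue, rel=1e-6, abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(DegenerateSignalError):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])

    @settings(deadline=None, max_examples=25)
    @given(st.lists(st.floats(-100, 100), min_size=10, max_size=20, unique=True))
    def test_invariant_under_strictly_monotone_transform(self, xs):
        rng = np.random.default_rng(0)
        x = np.asarray(xs)
        y = rng.standard_normal(len(x))
        rho1, _ = spearman(x, y)
        rho2, _ = spearman(x**3 + 5.0 * x, y)  # strictly increasing map
        assert rho1 == pytest.approx(rho2, abs=1e-12)


class TestPartialSpearman:
    def test_self_correlation_survives_residualization(self, rng):
        x = rng.standard_normal(50)
        z = rng.standard_normal((50, 2))
        rho, _ = partial_spearman(x, x, z)
        assert rho == pytest.approx(1.0, abs=1e-12)

    def test_zero_influence_covariate_changes_little(self, rng):
        n = 2000
        x = rng.standard_normal(n)
        y = 0.5 * x + rng.standard_normal(n)
        z = rng.standard_normal(n)  # independent of both
        plain, _ = spearman(x, y)
        partial, _ = partial_spearman(x, y, z)
        assert abs(plain - partial) < 0.02

    def test_confound_is_removed(self, rng):
        n = 2000
        z = rng.standard_normal(n)
        y = np.exp(z)  # exact monotone function of the covariate
        x = rng.standard_normal(n)
        rho, _ = partial_spearman(x, y, z)
        assert abs(rho) < 2 / math.sqrt(n)

    def test_rank_deficient_covariates_rejected(self, rng):
        x = rng.standard_normal(20)
        y = rng.standard_normal(20)
        z = np.column_stack([np.arange(20.0), 2 * np.arange(20.0)])
        with pytest.raises(CollinearityError):
            partial_spearman(x, y, z)


class TestAndersonDarling:
    def test_statistic_matches_scipy(self, rng):
        for _ in range(20):
            x = rng.standard_normal(rng.integers(20, 200))
            report = anderson_darling_normal(x)
            ref = sps.anderson(x, dist="norm", method="interpolate").statistic
            assert report.A2 == pytest.approx(ref, abs=1e-10)

    def test_null_rejection_rate_near_nominal(self):
        rng = np.random.default_rng(77)
        rejections = sum(
            anderson_darling_normal(rng.standard_normal(100)).reject_at_05
            for _ in range(1000)
        )
        assert 0.035 <= rejections / 1000 <= 0.065

    def test_binary_vector_rejects_normality(self):
        x = np.array([0.0] * 40 + [1.0] * 40)
        report = anderson_darling_normal(x, "sex")
        assert report.reject_at_05
        assert report.variable_name == "sex"

    def test_deterministic(self, rng):
        x = rng.standard_normal(60)
        assert anderson_darling_normal(x) == anderson_darling_normal(x)

    def test_modification_formula(self, rng):
        x = rng.standard_normal(50)
        r = anderson_darling_normal(x)
        assert r.A2_modified == pytest.approx(
            r.A2 * (1 + 0.75 / 50 + 2.25 / 2500), abs=1e-12
        )


def _brute_force_bh(p):
    """Step-up definition enumerated directly."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    for rank_pos, idx in enumerate(order, start=1):
        candidates = [
            m * p[order[j - 1]] / j for j in range(rank_pos, m + 1)
        ]
        q[idx] = min(1.0, min(candidates))
    return q


class TestBHFDR:
    def test_hand_enumerated_example(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04], atol=1e-12)

    def test_single_p_unchanged(self):
        assert bh_fdr([0.2])[0] == pytest.approx(0.2)

    def test_all_ones_capped(self):
        np.testing.assert_allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_matches_brute_force_and_statsmodels(self, rng):
        for _ in range(50):
            p = rng.uniform(0, 1, size=rng.integers(2, 30))
            q = bh_fdr(p)
            np.testing.assert_allclose(q, _brute_force_bh(p), atol=1e-12)
            ref = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(q, ref, atol=1e-10)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    @settings(deadline=None, max_examples=25)
    @given(st.lists(st.floats(0, 1), min_size=2, max_size=20))
    def test_sorted_q_monotone_and_q_ge_p_scaled(self, ps):
        p = np.asarray(ps)
        q = bh_fdr(p)
        order = np.argsort(p, kind="mergesort")
        assert np.all(np.diff(q[order]) >= -1e-12)
        assert np.all(q >= p - 1e-12)


def _cca_eig_oracle(X, Y):
    """Canonical correlations via the generalized eigenproblem
    inv(Sxx) Sxy inv(Syy) Syx — an independent route from the QR/SVD one."""
    Xc = X - X.mean(0)
    Yc = Y - Y.mean(0)
    Sxx = Xc.T @ Xc
    Syy = Yc.T @ Yc
    Sxy = Xc.T @ Yc
    M = linalg.solve(Sxx, Sxy) @ linalg.solve(Syy, Sxy.T)
    ev = np.sort(np.real(linalg.eigvals(M)))[::-1]
    m = min(X.shape[1], Y.shape[1])
    return np.sqrt(np.clip(ev[:m], 0, 1))


class TestCCA:
    def test_printed_df_pair_for_study_dimensions(self, rng):
        X = rng.standard_normal((79, 12))
        Y = rng.standard_normal((79, 39))
        res = cca(X, Y)
        assert res.df1[0] == 468
        assert res.df2_display[0] == 364

    def test_self_correlation_single_column(self, rng):
        x = rng.standard_normal((30, 1))
        res = cca(x, x)
        assert res.canonical_correlations[0] == pytest.approx(1.0, abs=1e-10)

    def test_matches_eig_oracle_on_random_instances(self, rng):
        for _ in range(50):
            n = int(rng.integers(25, 60))
            p = int(rng.integers(2, 5))
            q = int(rng.integers(2, 6))
            X = rng.standard_normal((n, p))
            Y = rng.standard_normal((n, q))
            res = cca(X, Y)
            np.testing.assert_allclose(
                res.canonical_correlations, _cca_eig_oracle(X, Y), atol=1e-8
            )

    def test_invariant_to_affine_transforms(self, rng):
        X = rng.standard_normal((40, 3))
        Y = rng.standard_normal((40, 4))
        A = rng.standard_normal((3, 3)) + 3 * np.eye(3)
        B = rng.standard_normal((4, 4)) + 3 * np.eye(4)
        base = cca(X, Y).canonical_correlations
        trans = cca(X @ A + 1.0, Y @ B - 2.0).canonical_correlations
        np.testing.assert_allclose(base, trans, atol=1e-8)

    def test_identical_blocks_give_all_ones(self, rng):
        X = rng.standard_normal((30, 4))
        res = cca(X, X.copy())
        np.testing.assert_allclose(res.canonical_correlations, 1.0, atol=1e-8)

    def test_more_features_than_observations_raises(self, rng):
        X = rng.standard_normal((81, 12))
        Y = rng.standard_normal((81, 90))
        with pytest.raises(RankDeficiencyError, match="rank deficient"):
            cca(X, Y)

    def test_last_dimension_uses_s_equal_one(self, rng):
        # p'=q'=1 at the last dimension: s formula degenerates to 1
        X = rng.standard_normal((30, 2))
        Y = rng.standard_normal((30, 2))
        res = cca(X, Y)
        # d=2: p'=q'=1, df1=1, df2 = (n-1-1.5)*1 - 0.5 + 1 = 28
        assert res.df1[-1] == 1
        assert res.df2[-1] == pytest.approx(28.0)

    def test_wilks_lambda_definition(self, rng):
        X = rng.standard_normal((40, 3))
        Y = rng.standard_normal((40, 5))
        res = cca(X, Y)
        r2 = res.canonical_correlations**2
        for d in range(3):
            assert res.wilks_lambda[d] == pytest.approx(
                np.prod(1 - r2[d:]), abs=1e-12
            )


class TestAssociateFamily:
    def test_cardinality_12_traits_by_4_windows(self, rng):
        x = pd.DataFrame(rng.standard_normal((30, 4)),
                         columns=["all", "w", "r", "e"])
        y = pd.DataFrame(rng.standard_normal((30, 12)),
                         columns=[f"t{i}" for i in range(12)])
        out = associate_family(x, y, family_id="traits")
        assert len(out) == 48
        assert set(out.family_id) == {"traits"}

    def test_single_pair_q_equals_p(self, rng):
        x = pd.DataFrame({"a": rng.standard_normal(20)})
        y = pd.DataFrame({"b": rng.standard_normal(20)})
        out = associate_family(x, y)
        assert out.q.iloc[0] == pytest.approx(out.p.iloc[0])

    def test_partial_requires_covariates(self, rng):
        x = pd.DataFrame({"a": rng.standard_normal(20)})
        with pytest.raises(ValueError, match="covariates"):
            associate_family(x, x, method="partial")
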