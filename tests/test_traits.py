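"""Trait intercorrelations and PCA of the 12-score table."""

import numpy as np
import pandas as pd
import pytest
from sklearn.decomposition import PCA as SkPCA

from neurotyp import (
    DegenerateSignalError,
    biplot_export,
    pca_traits,
    select_components,
    trait_intercorrelations,
)
from neurotyp.data import TRAIT_NAMES, PersonalityTable
from neurotyp.simulate import DEFAULT_TRAIT_LOADINGS, generate_personality
from neurotyp.traits import TraitPCA


def _table(values: np.ndarray) -> PersonalityTable:
    ids = [f"s{i}" for i in range(values.shape[0])]
    return PersonalityTable(
        ids, pd.DataFrame(values, index=ids, columns=list(TRAIT_NAMES))
    )


class TestIntercorrelations:
    def test_duplicated_column_has_r_one(self, rng):
        X = rng.standard_normal((30, 12))
        X[:, 1] = X[:, 0]
        m = trait_intercorrelations(_table(X))
        assert m.r.iloc[0, 1] == pytest.approx(1.0)

    def test_independent_columns_have_small_r(self, rng):
        X = rng.standard_normal((5000, 12))
        m = trait_intercorrelations(_table(X))
        off = m.r.to_numpy()[np.triu_indices(12, 1)]
        assert np.max(np.abs(off)) < 0.05

    def test_hand_computed_sums_oracle(self):
        # embed a hand-checkable pair in columns 0 and 1 of a 4-subject table
        X = np.zeros((4, 12))
        X[:, 0] = [1, 2, 3, 4]
        X[:, 1] = [2, 4, 5, 9]
        rng = np.random.default_rng(0)
        X[:, 2:] = rng.standard_normal((4, 10))
        m = trait_intercorrelations(_table(X))
        # Pearson via the sum formula: n=4, Sx=10, Sy=20, Sxy=61, Sxx=30, Syy=126
        expected = (4 * 61 - 10 * 20) / np.sqrt((4 * 30 - 100) * (4 * 126 - 400))
        assert m.r.iloc[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_symmetry_unit_diagonal_and_q_ge_p(self, rng):
        m = trait_intercorrelations(_table(rng.standard_normal((20, 12))))
        np.testing.assert_allclose(m.r.to_numpy(), m.r.to_numpy().T, atol=1e-12)
        np.testing.assert_allclose(np.diag(m.r.to_numpy()), 1.0)
        iu = np.triu_indices(12, 1)
        assert np.all(m.q.to_numpy()[iu] >= m.p.to_numpy()[iu] - 1e-15)

    def test_constant_trait_rejected(self, rng):
        X = rng.standard_normal((10, 12))
        X[:, 5] = 2.0
        with pytest.raises(DegenerateSignalError, match="NS"):
            trait_intercorrelations(_table(X))


class TestTraitPCA:
    def test_variance_ratio_without_standardizing(self):
        rng = np.random.default_rng(0)
        # two orthogonal directions with variances 4 and 1
        scores = np.column_stack([2.0 * rng.standard_normal(500),
                                  rng.standard_normal(500)])
        est = TraitPCA(standardize=False).fit(scores)
        assert est.explained_pct_[0] == pytest.approx(80.0, abs=2.5)
        assert est.explained_pct_[1] == pytest.approx(20.0, abs=2.5)

    def test_full_reconstruction(self, rng):
        X = rng.standard_normal((40, 12))
        est = TraitPCA().fit(X)
        np.testing.assert_allclose(
            est.inverse_transform(est.transform(X)), X, atol=1e-9
        )

    def test_explained_sums_to_100_and_is_sorted(self, rng):
        est = TraitPCA().fit(rng.standard_normal((40, 12)))
        assert est.explained_pct_.sum() == pytest.approx(100.0, abs=1e-9)
        assert np.all(np.diff(est.explained_pct_) <= 1e-12)

    def test_loadings_orthonormal(self, rng):
        est = TraitPCA().fit(rng.standard_normal((40, 12)))
        np.testing.assert_allclose(
            est.loadings_.T @ est.loadings_, np.eye(12), atol=1e-9
        )

    def test_matches_sklearn_up_to_sign(self, rng):
        X = rng.standard_normal((60, 12))
        est = TraitPCA().fit(X)
        Z = (X - X.mean(0)) / X.std(0, ddof=1)
        sk = SkPCA(n_components=12).fit(Z)
        np.testing.assert_allclose(
            est.explained_pct_, 100 * sk.explained_variance_ratio_, atol=1e-8
        )
        for j in range(12):
            dot = abs(sk.components_[j] @ est.loadings_[:, j])
            assert dot == pytest.approx(1.0, abs=1e-8)

    def test_recovers_planted_factor_subspace(self):
        table, factors = generate_personality(5000, seed=3)
        result = pca_traits(table)
        L_hat = result.loadings.to_numpy()[:, :2]
        # correlation-matrix PCA acts on standardized traits, so the planted
        # subspace must be expressed per unit trait SD before comparing
        sd = np.sqrt((DEFAULT_TRAIT_LOADINGS**2).sum(axis=1) + 0.45**2)
        Q1, _ = np.linalg.qr(DEFAULT_TRAIT_LOADINGS / sd[:, None])
        Q2, _ = np.linalg.qr(L_hat)
        s = np.linalg.svd(Q1.T @ Q2, compute_uv=False)
        angles_deg = np.degrees(np.arccos(np.clip(s, -1, 1)))
        assert np.max(angles_deg) < 5.0

    def test_invariant_to_per_trait_affine_rescaling(self, rng):
        X = rng.standard_normal((50, 12))
        scale = rng.uniform(0.5, 3.0, size=12)
        shift = rng.uniform(-10, 10, size=12)
        a = TraitPCA().fit(X)
        b = TraitPCA().fit(X * scale + shift)
        np.testing.assert_allclose(a.loadings_, b.loadings_, atol=1e-9)

    def test_scores_uncorrelated(self, rng):
        X = rng.standard_normal((100, 12))
        est = TraitPCA().fit(X)
        S = est.transform(X)
        C = np.corrcoef(S, rowvar=False)
        off = C[np.triu_indices(12, 1)]
        assert np.max(np.abs(off)) < 1e-9

    def test_pc1_loads_negatively_on_n_and_ha(self):
        table, _ = generate_personality(2000, seed=9)
        result = pca_traits(table)
        pc1 = result.loadings["PC1"]
        assert pc1["N"] < 0 and pc1["HA"] < 0
        assert pc1["Co"] > 0 and pc1["A"] > 0


class TestSelectionAndBiplot:
    def test_fixed_k_passthrough(self, rng):
        res = pca_traits(_table(rng.standard_normal((30, 12))))
        assert select_components(res, "fixed_k", k=2) == 2

    @pytest.mark.parametrize("threshold,expected", [(75, 2), (95, 3)])
    def test_cumulative_threshold(self, threshold, expected, rng):
        res = pca_traits(_table(rng.standard_normal((30, 12))))
        res.explained_pct = np.array([50.0, 30.0, 20.0] + [0.0] * 9)
        assert select_components(res, "cumulative_threshold",
                                 threshold=threshold) == expected

    def test_k_out_of_range_rejected(self, rng):
        res = pca_traits(_table(rng.standard_normal((30, 12))))
        with pytest.raises(ValueError):
            select_components(res, "fixed_k", k=13)

    def test_biplot_scaling_and_invertibility(self, rng):
        res = pca_traits(_table(rng.standard_normal((30, 12))))
        out = biplot_export(res)
        arrows = out[out.kind == "loading"]
        points = out[out.kind == "score"]
        L = res.loadings.iloc[:, :2].to_numpy()
        np.testing.assert_allclose(arrows[["PC1", "PC2"]].to_numpy(), L, atol=1e-12)
        # rescale points back by their stored scale -> original scores
        back = points[["PC1", "PC2"]].to_numpy() / points["scale"].to_numpy()[:, None]
        np.testing.assert_allclose(
            back, res.scores.iloc[:, :2].to_numpy(), atol=1e-12
        )

    def test_longest_arrow_is_dominant_trait(self, rng):
        X = rng.standard_normal((200, 12)) * 0.05
        X[:, 3] += 5.0 * rng.standard_normal(200)  # dominant trait A
        res = pca_traits(_table(X), standardize=False)
        out = biplot_export(res)
        arrows = out[out.kind == "loading"].set_index("name")
        lengths = np.sqrt(arrows["PC1"] ** 2 + arrows["PC2"] ** 2)
        assert lengths.idxmax() == "A"
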