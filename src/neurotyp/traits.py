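"""Trait intercorrelations and PCA reduction of the 12 personality scores.

The 12 scores from the two inventories overlap heavily (Neuroticism and
Harm Avoidance in particular), so the primary analysis works with the
first principal components of the trait table rather than raw scores.
PCA is performed on the correlation matrix by default (the NEO-FFI and
TCI scales have very different ranges); component signs are fixed so each
loading column sums to a positive value (falling back to making the
largest-magnitude entry positive when the sum is numerically zero). A
deterministic orientation makes reported correlation signs reproducible,
and the column-sum rule is stable under resampling even when two traits
compete for the largest loading.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .data import TRAIT_NAMES, PersonalityTable
from .errors import DegenerateSignalError, InsufficientDataError
from .stats import bh_fdr, pearson_p_twosided

__all__ = [
    "PCAResult",
    "TraitCorrelationMatrix",
    "TraitPCA",
    "trait_intercorrelations",
    "pca_traits",
    "select_components",
    "biplot_export",
]


@dataclass
class TraitCorrelationMatrix:
    """Pairwise Pearson correlations of the 12 traits with p and BH q."""

    r: pd.DataFrame
    p: pd.DataFrame
    q: pd.DataFrame


@dataclass
class PCAResult:
    """Loadings, subject scores and explained-variance percentages."""

    loadings: pd.DataFrame      # traits x components
    scores: pd.DataFrame        # subjects x components
    explained_pct: np.ndarray
    standardized: bool


def trait_intercorrelations(table: PersonalityTable) -> TraitCorrelationMatrix:
    """12 x 12 Pearson correlations with two-sided p and BH q over the
    66 unique off-diagonal pairs."""
    X = table.scores.to_numpy(dtype=float)
    n, m = X.shape
    if n < 4:
        raise InsufficientDataError("need at least 4 subjects")
    if np.any(X.std(axis=0) == 0):
        const = [TRAIT_NAMES[j] for j in np.nonzero(X.std(axis=0) == 0)[0]]
        raise DegenerateSignalError(f"constant trait column(s): {const}")
    r = np.corrcoef(X, rowvar=False)
    p = np.ones_like(r)
    iu = np.triu_indices(m, k=1)
    p[iu] = [pearson_p_twosided(r[i, j], n) for i, j in zip(*iu)]
    p[(iu[1], iu[0])] = p[iu]
    np.fill_diagonal(p, 0.0)
    q = np.ones_like(p)
    q_flat = bh_fdr(p[iu])
    q[iu] = q_flat
    q[(iu[1], iu[0])] = q_flat
    np.fill_diagonal(q, 0.0)
    names = list(table.scores.columns)
    as_df = lambda a: pd.DataFrame(a, index=names, columns=names)
    return TraitCorrelationMatrix(as_df(r), as_df(p), as_df(q))


class TraitPCA(BaseEstimator, TransformerMixin):
    """PCA of the trait table via eigendecomposition of the correlation
    (default) or covariance matrix.

    Attributes (after fit)
    ----------------------
    loadings_ : (n_traits, m) orthonormal eigenvector matrix, sign-fixed
    explained_pct_ : percentage of total variance per component
    mean_, scale_ : centering/scaling applied to the input
    """

    def __init__(self, standardize: bool = True):
        self.standardize = standardize

    def fit(self, X, y=None) -> "TraitPCA":
        X = np.asarray(X, dtype=float)
        n, m = X.shape
        if n < m + 1:
            warnings.warn(
                f"only {n} subjects for {m} traits; PCA will be rank deficient",
                stacklevel=2,
            )
        self.mean_ = X.mean(axis=0)
        if self.standardize:
            self.scale_ = X.std(axis=0, ddof=1)
            if np.any(self.scale_ == 0):
                raise DegenerateSignalError("constant column; cannot standardize")
        else:
            self.scale_ = np.ones(m)
        Z = (X - self.mean_) / self.scale_
        C = (Z.T @ Z) / (n - 1)  # correlation matrix if standardized
        eigval, eigvec = np.linalg.eigh(C)
        order = np.argsort(eigval)[::-1]
        eigval, eigvec = eigval[order], eigvec[:, order]
        eigval = np.clip(eigval, 0.0, None)
        rank = int(np.sum(eigval > max(1e-10 * eigval[0], 0)))
        if rank < m:
            warnings.warn(
                f"input is rank deficient (rank {rank} < {m} traits)", stacklevel=2
            )
        # deterministic sign: each loading column sums positive; fall back
        # to largest-|entry|-positive when the sum is numerically zero
        for j in range(m):
            s = eigvec[:, j].sum()
            if abs(s) < 1e-9:
                k = np.argmax(np.abs(eigvec[:, j]))
                s = eigvec[k, j]
            if s < 0:
                eigvec[:, j] = -eigvec[:, j]
        self.loadings_ = eigvec
        self.eigenvalues_ = eigval
        self.explained_pct_ = 100.0 * eigval / eigval.sum()
        self.n_samples_ = n
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        Z = (X - self.mean_) / self.scale_
        return Z @ self.loadings_

    def inverse_transform(self, scores) -> np.ndarray:
        Z = np.asarray(scores, dtype=float) @ self.loadings_.T
        return Z * self.scale_ + self.mean_


def pca_traits(table: PersonalityTable, standardize: bool = True) -> PCAResult:
    """Functional wrapper: PCA of a :class:`PersonalityTable`."""
    est = TraitPCA(standardize=standardize)
    with warnings.catch_warnings():
        warnings.simplefilter("always")
        est.fit(table.scores.to_numpy(dtype=float))
    comps = [f"PC{j + 1}" for j in range(est.loadings_.shape[1])]
    loadings = pd.DataFrame(
        est.loadings_, index=list(table.scores.columns), columns=comps
    )
    scores = pd.DataFrame(
        est.transform(table.scores.to_numpy(dtype=float)),
        index=list(table.subject_ids),
        columns=comps,
    )
    return PCAResult(loadings, scores, est.explained_pct_, standardize)


def select_components(
    result: PCAResult,
    rule: str = "fixed_k",
    k: int = 2,
    threshold: float = 55.0,
) -> int:
    """Number of components to carry into the primary analysis.

    ``fixed_k`` returns ``k`` (the scree bend was chosen by inspection,
    so k=2 is the default); ``cumulative_threshold`` returns the smallest
    m whose cumulative explained percentage reaches ``threshold``.
    """
    m = len(result.explained_pct)
    if rule == "fixed_k":
        if not (1 <= k <= m):
            raise ValueError(f"k={k} out of range 1..{m}")
        return int(k)
    if rule == "cumulative_threshold":
        cum = np.cumsum(result.explained_pct)
        return int(np.searchsorted(cum, threshold - 1e-12) + 1)
    raise ValueError(f"unknown rule {rule!r}")


def biplot_export(result: PCAResult, k: int = 2) -> pd.DataFrame:
    """Tidy table of loading arrows and scaled subject scores for a biplot.

    Scores are divided by max |score| and multiplied by the maximum
    loading-vector length, so points and arrows share one scale.
    """
    if result.loadings.shape[1] < 2 or k < 2:
        raise ValueError("biplot needs at least 2 components")
    L = result.loadings.iloc[:, :k]
    S = result.scores.iloc[:, :k]
    max_score = np.abs(S.to_numpy()).max()
    max_len = np.sqrt((L.to_numpy() ** 2).sum(axis=1)).max()
    scale = max_len / max_score if max_score > 0 else 1.0
    rows = []
    for trait, row in L.iterrows():
        rows.append({"kind": "loading", "name": trait, "scale": 1.0,
                     **{c: row[c] for c in L.columns}})
    for sid, row in S.iterrows():
        rows.append({"kind": "score", "name": sid, "scale": scale,
                     **{c: row[c] * scale for c in S.columns}})
    return pd.DataFrame(rows)
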