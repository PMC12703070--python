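"""Functional-connectivity typicality.

Instead of comparing time courses directly, each subject is summarised by
their K x K functional-connectivity matrix (pairwise Pearson correlations
between signals). Typicality is then the Pearson correlation between the
vectorised upper triangle of a subject's FC matrix and the element-wise
mean FC of the cohort, with the same IQR outlier handling as the
time-series statistic. Because FC typicality correlates with age, its
association with traits is measured with partial Spearman correlations
controlling for age.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .data import Cohort, PersonalityTable
from .errors import (
    DegenerateSignalError,
    InsufficientDataError,
    MissingCovariateError,
)
from .stats import associate_family
from .typicality import TypicalityResult, TypicalityScorer

__all__ = ["fc_matrix", "FCTypicalityScorer", "fc_typicality", "fc_trait_association"]


def fc_matrix(subject_series: np.ndarray, fisher_z: bool = False) -> np.ndarray:
    """K x K Pearson correlation matrix between a subject's signals.

    ``fisher_z=True`` returns arctanh-transformed off-diagonal values
    (the diagonal stays at 1).
    """
    series = np.asarray(subject_series, dtype=float)
    if series.ndim != 2 or series.shape[0] < 2:
        raise ValueError("subject series must be K x T with K >= 2")
    if np.any(series.std(axis=1) == 0):
        which = np.nonzero(series.std(axis=1) == 0)[0]
        raise DegenerateSignalError(
            f"constant signal(s) at row index {which.tolist()}"
        )
    fc = np.clip(np.corrcoef(series), -1.0, 1.0)
    if fisher_z:
        off = ~np.eye(fc.shape[0], dtype=bool)
        fc = fc.copy()
        fc[off] = np.arctanh(np.clip(fc[off], -1 + 1e-15, 1 - 1e-15))
    return fc


def _upper_triangle(fc: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(fc.shape[0], k=1)
    return fc[iu]


class FCTypicalityScorer(BaseEstimator):
    """Typicality of FC matrices, sharing the IQR machinery of
    :class:`~neurotyp.typicality.TypicalityScorer`.

    Requires K >= 3 signals (with K = 2 the upper triangle has a single
    entry and a correlation across it is undefined).
    """

    def __init__(
        self,
        leave_one_out: bool = False,
        outlier_multiplier: float = 1.5,
        outlier_passes: int = 1,
        fisher_z: bool = False,
    ):
        self.leave_one_out = leave_one_out
        self.outlier_multiplier = outlier_multiplier
        self.outlier_passes = outlier_passes
        self.fisher_z = fisher_z

    def fit(self, X: Cohort | np.ndarray, y=None) -> "FCTypicalityScorer":
        if isinstance(X, Cohort):
            series = X.series
            ids = list(X.subject_ids)
        else:
            series = np.asarray(X, dtype=float)
            ids = [f"sub-{i:03d}" for i in range(series.shape[0])]
        if series.ndim != 3:
            raise ValueError("X must be a Cohort or (n_subjects, K, T) array")
        if series.shape[1] < 3:
            raise InsufficientDataError(
                f"FC typicality needs at least 3 signals, got {series.shape[1]}: "
                "with K=2 the FC upper triangle has a single entry and its "
                "correlation with the mean is undefined"
            )
        triangles = np.stack(
            [_upper_triangle(fc_matrix(s, fisher_z=self.fisher_z)) for s in series]
        )
        # reuse the time-series machinery on 'series' of shape (n, 1, n_pairs):
        # the typical FC triangle is the subject mean and the similarity step
        # is a plain Pearson correlation, exactly as for time courses.
        scorer = TypicalityScorer(
            leave_one_out=self.leave_one_out,
            outlier_multiplier=self.outlier_multiplier,
            outlier_passes=self.outlier_passes,
        )
        scorer.fit(triangles[:, None, :])
        res = scorer.result_
        id_map = {f"sub-{i:03d}": ids[i] for i in range(len(ids))}
        self.result_ = TypicalityResult(
            subject_ids=[id_map[s] for s in res.subject_ids],
            indices=res.indices,
            profiles=res.profiles,
            removed_subjects=[id_map[s] for s in res.removed_subjects],
            passes=res.passes,
            leave_one_out=self.leave_one_out,
        )
        self.indices_ = res.indices
        self.removed_subjects_ = self.result_.removed_subjects
        self.mean_fc_triangle_ = scorer.typical_series_[0]
        return self

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X).indices_


def fc_typicality(
    cohort: Cohort | np.ndarray,
    leave_one_out: bool = False,
    outlier_multiplier: float = 1.5,
    outlier_passes: int = 1,
    fisher_z: bool = False,
) -> TypicalityResult:
    """Functional wrapper around :class:`FCTypicalityScorer`."""
    est = FCTypicalityScorer(
        leave_one_out=leave_one_out,
        outlier_multiplier=outlier_multiplier,
        outlier_passes=outlier_passes,
        fisher_z=fisher_z,
    )
    return est.fit(cohort).result_


def fc_trait_association(
    fc_result: TypicalityResult,
    personality: PersonalityTable,
    targets: pd.DataFrame | None = None,
    family_id: str = "fc_traits",
) -> pd.DataFrame:
    """Partial Spearman of FC typicality vs traits (or ``targets`` columns,
    e.g. principal-component scores), controlling for age; BH within the
    family."""
    aligned = personality.aligned_to(fc_result.subject_ids)
    if aligned.covariates is None or "age" not in aligned.covariates.columns:
        raise MissingCovariateError(
            "age covariate required for FC typicality associations"
        )
    y_table = targets.loc[fc_result.subject_ids] if targets is not None else aligned.scores
    x_table = pd.DataFrame(
        {"fc_typicality": fc_result.indices}, index=fc_result.subject_ids
    )
    return associate_family(
        x_table,
        y_table,
        method="partial",
        covariates=aligned.covariates[["age"]].to_numpy(),
        family_id=family_id,
    )
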