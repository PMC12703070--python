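"""The typicality statistic: how group-like is one subject's evoked activity.

For each of the K signals (ICA component or atlas ROI time courses) the
cohort's *typical time series* is the per-volume average across subjects.
A subject's *similarity profile* is the vector of K Pearson correlations
between their signals and the corresponding typical signals, and their
*typicality index* is the plain arithmetic mean of that profile — one
number per subject summarising how closely their activity follows the
group-average response to the stimulus.

Subjects whose index falls outside Tukey fences (1.5 interquartile ranges
beyond the quartiles) are flagged as outliers, removed, and the typical
series and all indices recomputed on the reduced cohort. A leave-one-out
variant excludes the assessed subject from the average, removing the
include-self upward bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .data import Cohort
from .errors import DegenerateSignalError, InsufficientDataError

__all__ = [
    "TypicalityResult",
    "TypicalityScorer",
    "typical_time_series",
    "similarity_profile",
    "typicality_index",
    "detect_outliers_iqr",
    "compute_typicality",
]


@dataclass
class TypicalityResult:
    """Per-subject similarity profiles and indices with outlier bookkeeping."""

    subject_ids: list[str]          # subjects surviving all removal passes
    indices: np.ndarray             # final index per surviving subject
    profiles: np.ndarray            # (n_surviving, K) similarity profiles
    removed_subjects: list[str]     # flagged and removed across passes
    passes: list[dict] = field(default_factory=list)  # audit trail
    leave_one_out: bool = False

    def index_of(self, subject_id: str) -> float:
        return float(self.indices[self.subject_ids.index(subject_id)])


def _rowwise_pearson(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson correlation of matching rows of two K x T matrices."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    ac = a - a.mean(axis=-1, keepdims=True)
    bc = b - b.mean(axis=-1, keepdims=True)
    na = np.sqrt((ac * ac).sum(axis=-1))
    nb = np.sqrt((bc * bc).sum(axis=-1))
    bad = (na == 0) | (nb == 0)
    if bad.any():
        which = np.nonzero(bad)[0]
        raise DegenerateSignalError(
            f"constant signal(s) at row index {which.tolist()}; "
            "correlation is undefined"
        )
    return np.clip((ac * bc).sum(axis=-1) / (na * nb), -1.0, 1.0)


def typical_time_series(
    cohort: Cohort | np.ndarray, exclude_subject: str | int | None = None
) -> np.ndarray:
    """Element-wise mean K x T series over (optionally all-but-one) subjects."""
    if isinstance(cohort, Cohort):
        series = cohort.series
        if isinstance(exclude_subject, str):
            exclude_subject = cohort.subject_index(exclude_subject)
    else:
        series = np.asarray(cohort, dtype=float)
    n = series.shape[0]
    if exclude_subject is None:
        if n < 2:
            raise InsufficientDataError("need at least 2 subjects to average")
        return series.mean(axis=0)
    if n - 1 < 2:
        raise InsufficientDataError(
            "excluding one subject leaves fewer than 2 for the average"
        )
    mask = np.ones(n, dtype=bool)
    mask[int(exclude_subject)] = False
    return series[mask].mean(axis=0)


def similarity_profile(subject_series: np.ndarray, typical: np.ndarray) -> np.ndarray:
    """K Pearson correlations of a subject's signals with the typical ones."""
    return _rowwise_pearson(subject_series, typical)


def typicality_index(profile: np.ndarray, fisher_z: bool = False) -> float:
    """Mean of the similarity profile (optionally averaged on the Fisher-z
    scale and transformed back; plain mean is the default)."""
    profile = np.asarray(profile, dtype=float)
    if profile.size == 0:
        raise ValueError("empty similarity profile")
    if fisher_z:
        z = np.arctanh(np.clip(profile, -1 + 1e-15, 1 - 1e-15))
        return float(np.tanh(z.mean()))
    return float(profile.mean())


def detect_outliers_iqr(values: Sequence[float], multiplier: float = 1.5) -> set[int]:
    """Indices of values outside Tukey fences Q1 - m*IQR, Q3 + m*IQR.

    Quartiles use linear interpolation between order statistics (the
    "type 7" rule, numpy's default).
    """
    values = np.asarray(values, dtype=float)
    if values.size < 4:
        raise InsufficientDataError(
            f"need at least 4 values for IQR outlier detection, got {values.size}"
        )
    q1, q3 = np.percentile(values, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - multiplier * iqr, q3 + multiplier * iqr
    return set(np.nonzero((values < lo) | (values > hi))[0].tolist())


def _one_pass(
    series: np.ndarray, leave_one_out: bool, fisher_z: bool
) -> tuple[np.ndarray, np.ndarray]:
    """Profiles and indices for every subject in ``series``."""
    n = series.shape[0]
    profiles = np.empty((n, series.shape[1]))
    if leave_one_out:
        total = series.sum(axis=0)
        for i in range(n):
            typical = (total - series[i]) / (n - 1)
            profiles[i] = _rowwise_pearson(series[i], typical)
    else:
        typical = series.mean(axis=0)
        for i in range(n):
            profiles[i] = _rowwise_pearson(series[i], typical)
    indices = np.array([typicality_index(p, fisher_z=fisher_z) for p in profiles])
    return profiles, indices


class TypicalityScorer(BaseEstimator):
    """Estimator computing typicality indices with IQR outlier handling.

    Parameters
    ----------
    leave_one_out : bool, default False
        Exclude the assessed subject from the typical series. The default
        includes the subject (the group-template convention); inclusion
        biases indices upward but barely moves downstream associations.
    outlier_multiplier : float, default 1.5
        Tukey fence multiplier on the interquartile range.
    outlier_passes : int, default 1
        Number of remove-and-recompute passes. 1 means: compute on all
        subjects, drop flagged outliers once, recompute.
    fisher_z : bool, default False
        Average similarity values on the Fisher-z scale instead of the
        plain mean.

    Attributes
    ----------
    result_ : TypicalityResult
    indices_ : ndarray of final typicality indices (surviving subjects)
    removed_subjects_ : list of subject ids flagged across passes
    typical_series_ : K x T typical series of the final (reduced) cohort
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

    def fit(self, X: Cohort | np.ndarray, y=None) -> "TypicalityScorer":
        if isinstance(X, Cohort):
            series = X.series
            subject_ids = list(X.subject_ids)
        else:
            series = np.asarray(X, dtype=float)
            if series.ndim != 3:
                raise ValueError("X must be a Cohort or (n_subjects, K, T) array")
            subject_ids = [f"sub-{i:03d}" for i in range(series.shape[0])]
        if series.shape[0] < 4:
            raise InsufficientDataError(
                f"need at least 4 subjects, got {series.shape[0]}"
            )

        ids = list(subject_ids)
        removed: list[str] = []
        audit: list[dict] = []
        profiles, indices = _one_pass(series, self.leave_one_out, self.fisher_z)
        for pass_no in range(int(self.outlier_passes)):
            flagged = detect_outliers_iqr(indices, self.outlier_multiplier)
            audit.append(
                {
                    "pass": pass_no + 1,
                    "n_subjects": len(ids),
                    "indices": {s: float(v) for s, v in zip(ids, indices)},
                    "flagged": sorted(ids[i] for i in flagged),
                }
            )
            if not flagged:
                break
            keep = [i for i in range(len(ids)) if i not in flagged]
            removed.extend(ids[i] for i in sorted(flagged))
            ids = [ids[i] for i in keep]
            series = series[keep]
            if series.shape[0] < 4:
                raise InsufficientDataError(
                    "outlier removal left fewer than 4 subjects"
                )
            profiles, indices = _one_pass(series, self.leave_one_out, self.fisher_z)
        audit.append(
            {
                "pass": "final",
                "n_subjects": len(ids),
                "indices": {s: float(v) for s, v in zip(ids, indices)},
                "flagged": [],
            }
        )

        self.result_ = TypicalityResult(
            subject_ids=ids,
            indices=indices,
            profiles=profiles,
            removed_subjects=removed,
            passes=audit,
            leave_one_out=self.leave_one_out,
        )
        self.indices_ = indices
        self.profiles_ = profiles
        self.removed_subjects_ = removed
        self.typical_series_ = series.mean(axis=0)
        return self

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X).indices_


def compute_typicality(
    cohort: Cohort | np.ndarray,
    leave_one_out: bool = False,
    outlier_multiplier: float = 1.5,
    outlier_passes: int = 1,
    fisher_z: bool = False,
) -> TypicalityResult:
    """Functional wrapper around :class:`TypicalityScorer`."""
    scorer = TypicalityScorer(
        leave_one_out=leave_one_out,
        outlier_multiplier=outlier_multiplier,
        outlier_passes=outlier_passes,
        fisher_z=fisher_z,
    )
    return scorer.fit(cohort).result_
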