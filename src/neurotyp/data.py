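"""In-memory containers for cohorts, stimulus segments and trait tables.

A :class:`Cohort` holds one multivariate time-series matrix per subject
(K signals x T volumes, sampled every ``tr_seconds``), together with the
stimulus :class:`SegmentTable` that partitions the time axis into the
concatenated video segments. A :class:`PersonalityTable` holds the 12
inventory scores per subject (five NEO-FFI traits and seven TCI traits)
plus optional age/sex covariates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError

#: Canonical order of the 12 trait scores: NEO-FFI (Neuroticism,
#: Extraversion, Openness, Agreeableness, Conscientiousness) followed by
#: TCI (Novelty Seeking, Harm Avoidance, Reward Dependence, Persistence,
#: Self-Directedness, Cooperativeness, Self-Transcendence).
TRAIT_NAMES: tuple[str, ...] = (
    "N", "E", "O", "A", "C", "NS", "HA", "RD", "Pe", "SD", "Co", "ST",
)

#: The three stimulus segments in presentation order with their durations
#: in seconds (10 min western, 8 min 5 s reality show, 11 min 40 s
#: emotional clips).
DEFAULT_SEGMENTS: tuple[tuple[str, float], ...] = (
    ("western", 600.0),
    ("reality_show", 485.0),
    ("emotional_clips", 700.0),
)

DEFAULT_TR_SECONDS = 2.5


@dataclass(frozen=True)
class SegmentTable:
    """Contiguous, ordered partition of the volume axis into named segments.

    Intervals are 0-based and half-open: segment i covers
    ``[start_volume[i], end_volume[i])``.
    """

    names: tuple[str, ...]
    start_volume: tuple[int, ...]
    end_volume: tuple[int, ...]

    def __post_init__(self) -> None:
        if not (len(self.names) == len(self.start_volume) == len(self.end_volume)):
            raise SchemaError("segment name/start/end lengths differ")
        if len(set(self.names)) != len(self.names):
            raise SchemaError("duplicate segment names")
        prev_end = 0
        for name, s, e in zip(self.names, self.start_volume, self.end_volume):
            if s != prev_end:
                raise SchemaError(
                    f"segment {name!r} starts at {s}, expected {prev_end} "
                    "(segments must be contiguous from volume 0)"
                )
            if e <= s:
                raise SchemaError(f"segment {name!r} is empty or reversed")
            prev_end = e

    @property
    def n_volumes(self) -> int:
        return self.end_volume[-1]

    @classmethod
    def from_durations(
        cls,
        named_durations: Sequence[tuple[str, float]],
        tr_seconds: float,
    ) -> "SegmentTable":
        """Convert (name, duration in seconds) pairs into volume intervals.

        Durations divisible by TR convert exactly; otherwise the volume
        count is floored. Boundaries are cumulative from volume 0.
        """
        names, starts, ends = [], [], []
        cursor = 0
        for name, dur in named_durations:
            n = dur / tr_seconds
            n_vol = int(round(n)) if math.isclose(n, round(n)) else int(math.floor(n))
            names.append(name)
            starts.append(cursor)
            cursor += n_vol
            ends.append(cursor)
        return cls(tuple(names), tuple(starts), tuple(ends))

    @classmethod
    def default(cls, tr_seconds: float = DEFAULT_TR_SECONDS) -> "SegmentTable":
        return cls.from_durations(DEFAULT_SEGMENTS, tr_seconds)

    def bounds(self, name: str) -> tuple[int, int]:
        try:
            i = self.names.index(name)
        except ValueError:
            raise KeyError(
                f"unknown segment {name!r}; valid names: {list(self.names)} or 'all'"
            ) from None
        return self.start_volume[i], self.end_volume[i]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "name": self.names,
                "start_volume": self.start_volume,
                "end_volume": self.end_volume,
            }
        )


@dataclass
class Cohort:
    """Subject-indexed collection of K x T time-series matrices."""

    subject_ids: list[str]
    series: np.ndarray  # shape (n_subjects, K, T)
    tr_seconds: float
    signal_labels: list[str]
    segments: SegmentTable | None = None

    def __post_init__(self) -> None:
        self.series = np.asarray(self.series, dtype=float)
        if self.series.ndim != 3:
            raise SchemaError(
                f"series must be (n_subjects, K, T), got shape {self.series.shape}"
            )
        n, k, t = self.series.shape
        if len(self.subject_ids) != n:
            raise SchemaError("subject_ids length does not match series")
        if len(self.signal_labels) != k:
            raise SchemaError("signal_labels length does not match series")
        if self.tr_seconds <= 0:
            raise SchemaError("tr_seconds must be positive")
        if not np.isfinite(self.series).all():
            raise SchemaError("series contain NaN or Inf values")
        if self.segments is not None and self.segments.n_volumes != t:
            raise SchemaError(
                f"segment table covers {self.segments.n_volumes} volumes, "
                f"series have {t}"
            )

    @property
    def n_subjects(self) -> int:
        return self.series.shape[0]

    @property
    def n_signals(self) -> int:
        return self.series.shape[1]

    @property
    def n_volumes(self) -> int:
        return self.series.shape[2]

    def subject_index(self, subject_id: str) -> int:
        return self.subject_ids.index(subject_id)

    def subset_subjects(self, keep_ids: Sequence[str]) -> "Cohort":
        idx = [self.subject_ids.index(s) for s in keep_ids]
        return replace(
            self, subject_ids=list(keep_ids), series=self.series[idx].copy()
        )

    def drop_subjects(self, drop_ids: Sequence[str]) -> "Cohort":
        keep = [s for s in self.subject_ids if s not in set(drop_ids)]
        return self.subset_subjects(keep)


@dataclass
class PersonalityTable:
    """Subject x 12 trait scores, with optional age/sex covariates."""

    subject_ids: list[str]
    scores: pd.DataFrame  # index: subject_ids, columns: TRAIT_NAMES
    covariates: pd.DataFrame | None = None  # optional columns: age, sex

    def __post_init__(self) -> None:
        missing = [t for t in TRAIT_NAMES if t not in self.scores.columns]
        if missing:
            raise SchemaError(f"personality table lacks trait columns {missing}")
        self.scores = self.scores.loc[:, list(TRAIT_NAMES)].astype(float)
        if list(self.scores.index) != list(self.subject_ids):
            self.scores.index = pd.Index(self.subject_ids)
        if self.scores.isna().any().any():
            raise SchemaError("personality table has missing trait values")
        if self.covariates is not None:
            self.covariates = self.covariates.astype(float)
            self.covariates.index = pd.Index(self.subject_ids)

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def aligned_to(self, subject_ids: Sequence[str]) -> "PersonalityTable":
        """Return a copy restricted to ``subject_ids`` (in that order)."""
        missing = [s for s in subject_ids if s not in set(self.subject_ids)]
        if missing:
            raise SchemaError(f"no personality scores for subjects {missing}")
        scores = self.scores.loc[list(subject_ids)]
        cov = (
            self.covariates.loc[list(subject_ids)]
            if self.covariates is not None
            else None
        )
        return PersonalityTable(list(subject_ids), scores, cov)
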