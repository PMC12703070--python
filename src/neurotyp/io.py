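"""Readers and writers for the plain-text cohort layout.

A cohort on disk is a manifest CSV (``subject_id,series_path``) next to one
TSV per subject. Each series TSV has a header row (``signal`` followed by
volume labels ``t0..t{T-1}``) and one row per signal: the label in the
first column, then T numeric values. Personality scores travel in a single
CSV with the canonical trait columns and optional ``age``/``sex`` columns;
segments in a CSV giving either durations or explicit volume bounds.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .data import TRAIT_NAMES, Cohort, PersonalityTable, SegmentTable
from .errors import SchemaError

logger = logging.getLogger(__name__)


def write_series(path: Path, matrix: np.ndarray, signal_labels: list[str]) -> None:
    matrix = np.asarray(matrix, dtype=float)
    df = pd.DataFrame(
        matrix, index=pd.Index(signal_labels, name="signal"),
        columns=[f"t{j}" for j in range(matrix.shape[1])],
    )
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_series(path: Path) -> tuple[list[str], np.ndarray]:
    if not path.exists():
        raise FileNotFoundError(f"series file not found: {path}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        # locate the offending cell for the error message
        for i, row in enumerate(df.itertuples(index=False)):
            for j, v in enumerate(row):
                try:
                    float(v)
                except (TypeError, ValueError):
                    raise SchemaError(
                        f"non-numeric cell at row {i}, column {j} of {path}: {v!r}"
                    ) from exc
        raise SchemaError(f"non-numeric data in {path}") from exc
    return [str(s) for s in df.index], values


def write_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    """Write manifest + per-subject TSVs (+ segments CSV); returns manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for sid, mat in zip(cohort.subject_ids, cohort.series):
        fname = f"{sid}.tsv"
        write_series(out_dir / fname, mat, cohort.signal_labels)
        rows.append({"subject_id": sid, "series_path": fname})
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    meta = {"tr_seconds": cohort.tr_seconds}
    pd.DataFrame([meta]).to_csv(out_dir / "meta.csv", index=False)
    if cohort.segments is not None:
        cohort.segments.to_frame().to_csv(out_dir / "segments.csv", index=False)
    return manifest


def read_cohort(
    manifest_path: str | Path,
    tr_seconds: float | None = None,
    segments: SegmentTable | None = None,
) -> Cohort:
    """Load a cohort from its manifest CSV.

    ``tr_seconds`` and ``segments`` default to the ``meta.csv`` /
    ``segments.csv`` files next to the manifest when present.
    """
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    manifest = pd.read_csv(manifest_path)
    for col in ("subject_id", "series_path"):
        if col not in manifest.columns:
            raise SchemaError(f"manifest lacks required column {col!r}")

    subject_ids: list[str] = []
    matrices: list[np.ndarray] = []
    labels_ref: list[str] | None = None
    shape_errors: list[str] = []
    for _, row in manifest.iterrows():
        sid = str(row["subject_id"])
        path = base / str(row["series_path"])
        if not path.exists():
            raise FileNotFoundError(f"series file for subject {sid!r} not found: {path}")
        labels, mat = read_series(path)
        if labels_ref is None:
            labels_ref = labels
            shape_ref = mat.shape
        elif mat.shape != shape_ref:
            shape_errors.append(f"{sid} has shape {mat.shape}, expected {shape_ref}")
        subject_ids.append(sid)
        matrices.append(mat)
        logger.debug("loaded subject %s: %s signals x %s volumes", sid, *mat.shape)
    if shape_errors:
        raise SchemaError("ragged cohort: " + "; ".join(shape_errors))
    if not matrices:
        raise SchemaError("empty manifest")

    if tr_seconds is None:
        meta_path = base / "meta.csv"
        if meta_path.exists():
            tr_seconds = float(pd.read_csv(meta_path)["tr_seconds"].iloc[0])
        else:
            raise SchemaError("tr_seconds not given and no meta.csv next to manifest")
    if segments is None:
        seg_path = base / "segments.csv"
        if seg_path.exists():
            segments = read_segments(seg_path, tr_seconds)

    cohort = Cohort(
        subject_ids=subject_ids,
        series=np.stack(matrices),
        tr_seconds=tr_seconds,
        signal_labels=list(labels_ref or []),
        segments=segments,
    )
    logger.info(
        "cohort loaded: n=%d subjects, K=%d signals, T=%d volumes",
        cohort.n_subjects, cohort.n_signals, cohort.n_volumes,
    )
    return cohort


def read_segments(path: str | Path, tr_seconds: float) -> SegmentTable:
    df = pd.read_csv(path)
    if {"name", "start_volume", "end_volume"}.issubset(df.columns):
        return SegmentTable(
            tuple(df["name"].astype(str)),
            tuple(int(v) for v in df["start_volume"]),
            tuple(int(v) for v in df["end_volume"]),
        )
    if {"name", "duration_seconds"}.issubset(df.columns):
        pairs = [(str(n), float(d)) for n, d in zip(df["name"], df["duration_seconds"])]
        return SegmentTable.from_durations(pairs, tr_seconds)
    raise SchemaError(
        "segment file needs columns name,duration_seconds or "
        "name,start_volume,end_volume"
    )


def write_personality(table: PersonalityTable, path: str | Path) -> None:
    df = table.scores.copy()
    if table.covariates is not None:
        for col in table.covariates.columns:
            df[col] = table.covariates[col]
    df.insert(0, "subject_id", table.subject_ids)
    df.to_csv(path, index=False, float_format="%.10g")


def read_personality(path: str | Path) -> PersonalityTable:
    df = pd.read_csv(path)
    if "subject_id" not in df.columns:
        raise SchemaError("personality file lacks subject_id column")
    subject_ids = [str(s) for s in df["subject_id"]]
    scores = df[[c for c in TRAIT_NAMES if c in df.columns]]
    cov_cols = [c for c in ("age", "sex") if c in df.columns]
    covariates = df[cov_cols] if cov_cols else None
    scores = scores.set_axis(pd.Index(subject_ids), axis=0)
    if covariates is not None:
        covariates = covariates.set_axis(pd.Index(subject_ids), axis=0)
    return PersonalityTable(subject_ids, scores, covariates)
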