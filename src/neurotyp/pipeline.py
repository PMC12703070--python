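"""End-to-end orchestration of the typicality analysis.

The flow mirrors the study design: band-pass filter the concatenated
series, compute typicality with one IQR outlier removal pass on the
all-stimuli window, check age/sex confounds with uncorrected Spearman
correlations, reduce the 12 traits by PCA, and correlate typicality with
principal components (primary analysis), with individual traits, and
per-signal (exploratory), each block forming one BH-FDR family. A CCA of
the 12 traits against the K similarity indices and the FC-typicality
variant (age-partialled) complete the picture.

Outlier subjects flagged on the all-stimuli window are excluded from all
per-segment analyses by default, keeping n constant across the stimulus
columns of the reported tables; per-segment redetection is available.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as ntio
from .data import TRAIT_NAMES, Cohort, PersonalityTable
from .errors import RankDeficiencyError
from .fc import fc_trait_association, fc_typicality
from .preprocess import (
    DEFAULT_HIGH_HZ,
    DEFAULT_LOW_HZ,
    DEFAULT_ORDER,
    filter_cohort,
    slice_segment,
)
from .stats import associate_family, cca, spearman
from .traits import PCAResult, pca_traits, select_components, trait_intercorrelations
from .typicality import TypicalityResult, _one_pass, compute_typicality

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "covariate_check",
    "window_typicality",
    "primary_association",
    "trait_association",
    "signalwise_association",
    "run_primary",
    "run_trait_analysis",
    "run_signalwise_analysis",
    "run_cca",
    "run_fc",
    "run_all",
]


@dataclass
class RunConfig:
    """Fully serialisable description of one analysis run."""

    cohort_manifest: str
    personality_path: str
    out_dir: str = "neurotyp_out"
    tr_seconds: float | None = None
    segments_path: str | None = None
    filter_low_hz: float = DEFAULT_LOW_HZ
    filter_high_hz: float = DEFAULT_HIGH_HZ
    filter_order: int = DEFAULT_ORDER
    outlier_multiplier: float = 1.5
    outlier_passes: int = 1
    redetect_outliers_per_segment: bool = False
    leave_one_out: bool = False
    fisher_z: bool = False
    pca_k: int = 2
    pca_standardize: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _load(config: RunConfig) -> tuple[Cohort, PersonalityTable]:
    segments = None
    if config.segments_path:
        tr = config.tr_seconds
        if tr is None:
            raise ValueError("tr_seconds required when segments_path is given")
        segments = ntio.read_segments(config.segments_path, tr)
    cohort = ntio.read_cohort(
        config.cohort_manifest, tr_seconds=config.tr_seconds, segments=segments
    )
    personality = ntio.read_personality(config.personality_path)
    return cohort, personality


def covariate_check(
    typicality: TypicalityResult, covariates: pd.DataFrame
) -> pd.DataFrame:
    """Uncorrected Spearman of the typicality index against each covariate
    (typically age and sex), on the surviving subjects."""
    cov = covariates.loc[typicality.subject_ids]
    rows = []
    for name in cov.columns:
        rho, p = spearman(typicality.indices, cov[name].to_numpy(dtype=float))
        rows.append(
            {"x": "typicality", "y": name, "n": len(typicality.subject_ids),
             "rho": rho, "p": p, "q": p, "family_id": "covariate_check_uncorrected"}
        )
    return pd.DataFrame(rows)


def window_typicality(
    cohort: Cohort,
    leave_one_out: bool = False,
    fisher_z: bool = False,
    outlier_multiplier: float = 1.5,
    outlier_passes: int = 1,
    redetect_per_segment: bool = False,
) -> tuple[pd.DataFrame, TypicalityResult]:
    """Typicality indices per analysis window ("all" + each segment).

    The all-stimuli window determines the outlier set; per-segment
    indices are recomputed on the reduced cohort over the segment's
    volumes. With ``redetect_per_segment`` each window reruns the IQR
    procedure and the returned table is restricted to subjects surviving
    every window.
    """
    result = compute_typicality(
        cohort,
        leave_one_out=leave_one_out,
        outlier_multiplier=outlier_multiplier,
        outlier_passes=outlier_passes,
        fisher_z=fisher_z,
    )
    seg_names = list(cohort.segments.names) if cohort.segments is not None else []
    if redetect_per_segment:
        per_window = {"all": result}
        for name in seg_names:
            per_window[name] = compute_typicality(
                slice_segment(cohort, name),
                leave_one_out=leave_one_out,
                outlier_multiplier=outlier_multiplier,
                outlier_passes=outlier_passes,
                fisher_z=fisher_z,
            )
        survivors = [
            s for s in cohort.subject_ids
            if all(s in res.subject_ids for res in per_window.values())
        ]
        table = pd.DataFrame(
            {
                w: [res.index_of(s) for s in survivors]
                for w, res in per_window.items()
            },
            index=pd.Index(survivors),
        )
        return table, result

    reduced = cohort.drop_subjects(result.removed_subjects)
    columns = {"all": result.indices}
    for name in seg_names:
        sliced = slice_segment(reduced, name)
        _, idx = _one_pass(sliced.series, leave_one_out, fisher_z)
        columns[name] = idx
    table = pd.DataFrame(columns, index=pd.Index(result.subject_ids))
    return table, result


def _pc_scores(
    personality: PersonalityTable, subject_ids: list[str], k: int, standardize: bool
) -> tuple[pd.DataFrame, PCAResult]:
    aligned = personality.aligned_to(subject_ids)
    pca = pca_traits(aligned, standardize=standardize)
    k = select_components(pca, rule="fixed_k", k=k)
    return pca.scores.iloc[:, :k], pca


def primary_association(
    cohort: Cohort,
    personality: PersonalityTable,
    k: int = 2,
    **kwargs,
) -> tuple[pd.DataFrame, pd.DataFrame, TypicalityResult, PCAResult]:
    """Typicality vs first-k trait PCs across all analysis windows (one
    BH family). Returns (association table, window indices, typicality
    result, PCA result)."""
    windows, result = window_typicality(cohort, **kwargs)
    scores, pca = _pc_scores(
        personality, list(windows.index), k, standardize=True
    )
    table = associate_family(windows, scores, family_id="primary_pc")
    return table, windows, result, pca


def trait_association(
    cohort: Cohort, personality: PersonalityTable, **kwargs
) -> pd.DataFrame:
    """Typicality vs each of the 12 traits across windows (one BH family)."""
    windows, _ = window_typicality(cohort, **kwargs)
    traits = personality.aligned_to(list(windows.index)).scores
    return associate_family(windows, traits, family_id="traits_by_window")


def signalwise_association(
    cohort: Cohort, personality: PersonalityTable, **kwargs
) -> pd.DataFrame:
    """Per-signal similarity indices vs the 12 traits (one BH family);
    the all-stimuli window's final-pass profiles are used."""
    result = compute_typicality(
        cohort,
        leave_one_out=kwargs.get("leave_one_out", False),
        outlier_multiplier=kwargs.get("outlier_multiplier", 1.5),
        outlier_passes=kwargs.get("outlier_passes", 1),
        fisher_z=kwargs.get("fisher_z", False),
    )
    profiles = pd.DataFrame(
        result.profiles,
        index=pd.Index(result.subject_ids),
        columns=cohort.signal_labels,
    )
    traits = personality.aligned_to(result.subject_ids).scores
    return associate_family(profiles, traits, family_id="signalwise_traits")


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=True, float_format="%.10g")


def run_primary(config: RunConfig) -> dict:
    """Execute the primary analysis from a config; writes tables and
    returns a JSON-serialisable report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort, personality = _load(config)
    n_input = cohort.n_subjects
    filtered = filter_cohort(
        cohort, config.filter_low_hz, config.filter_high_hz, config.filter_order
    )
    kwargs = dict(
        leave_one_out=config.leave_one_out,
        fisher_z=config.fisher_z,
        outlier_multiplier=config.outlier_multiplier,
        outlier_passes=config.outlier_passes,
        redetect_per_segment=config.redetect_outliers_per_segment,
    )
    table, windows, result, pca = primary_association(
        filtered, personality, k=config.pca_k, **kwargs
    )
    logger.info(
        "primary analysis: n=%d loaded, n=%d after outlier removal (removed: %s)",
        n_input, len(result.subject_ids), result.removed_subjects,
    )
    cov_table = None
    if personality.covariates is not None:
        cov_table = covariate_check(
            result, personality.covariates
        )
        _write(cov_table, out / "covariate_check.csv")
    _write(table, out / "associations_primary.csv")
    _write(windows, out / "typicality_windows.csv")
    pd.DataFrame(
        {
            "subject_id": result.subject_ids,
            "typicality_index": result.indices,
            "removed_in_pass1": False,
        }
    ).to_csv(out / "typicality.csv", index=False, float_format="%.10g")
    profiles = pd.DataFrame(
        result.profiles, index=pd.Index(result.subject_ids),
        columns=cohort.signal_labels,
    )
    _write(profiles, out / "similarity_profiles.csv")
    _write(pca.loadings, out / "pca_loadings.csv")
    _write(pca.scores, out / "pca_scores.csv")
    pd.DataFrame(
        {"component": pca.scores.columns, "explained_pct": pca.explained_pct}
    ).to_csv(out / "pca_explained.csv", index=False)
    corr = trait_intercorrelations(personality.aligned_to(result.subject_ids))
    _write(corr.r, out / "trait_correlations_r.csv")
    _write(corr.q, out / "trait_correlations_q.csv")
    (out / "typicality_audit.json").write_text(
        json.dumps({"passes": result.passes, "config": config.to_dict()}, indent=2)
    )
    report = {
        "config": config.to_dict(),
        "n_input": n_input,
        "n_final": len(result.subject_ids),
        "removed_subjects": result.removed_subjects,
        "explained_pct": pca.explained_pct[: config.pca_k].tolist(),
        "associations": table.to_dict(orient="records"),
        "covariate_check": (
            cov_table.to_dict(orient="records") if cov_table is not None else None
        ),
    }
    (out / "summary_primary.json").write_text(json.dumps(report, indent=2))
    return report


def run_trait_analysis(config: RunConfig) -> dict:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort, personality = _load(config)
    filtered = filter_cohort(
        cohort, config.filter_low_hz, config.filter_high_hz, config.filter_order
    )
    table = trait_association(
        filtered, personality,
        leave_one_out=config.leave_one_out,
        fisher_z=config.fisher_z,
        outlier_multiplier=config.outlier_multiplier,
        outlier_passes=config.outlier_passes,
        redetect_per_segment=config.redetect_outliers_per_segment,
    )
    _write(table, out / "associations_traits.csv")
    # Table-shaped view: traits as rows, windows as columns, "rho (q)" cells
    pivot = table.assign(
        cell=[f"{r:.3f} ({q:.3f})" for r, q in zip(table["rho"], table["q"])]
    ).pivot(index="y", columns="x", values="cell")
    pivot = pivot.reindex(index=[t for t in TRAIT_NAMES if t in pivot.index])
    _write(pivot, out / "trait_table.csv")
    report = {"config": config.to_dict(), "associations": table.to_dict("records")}
    (out / "summary_traits.json").write_text(json.dumps(report, indent=2))
    return report


def run_signalwise_analysis(config: RunConfig) -> dict:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort, personality = _load(config)
    filtered = filter_cohort(
        cohort, config.filter_low_hz, config.filter_high_hz, config.filter_order
    )
    table = signalwise_association(
        filtered, personality,
        leave_one_out=config.leave_one_out,
        outlier_multiplier=config.outlier_multiplier,
        outlier_passes=config.outlier_passes,
    )
    _write(table, out / "associations_signalwise.csv")
    rho_matrix = table.pivot(index="y", columns="x", values="rho")
    star = table.assign(
        star=np.where(table["p"] < 0.01, "**", np.where(table["p"] < 0.05, "*", ""))
    ).pivot(index="y", columns="x", values="star")
    _write(rho_matrix, out / "signalwise_rho.csv")
    _write(star, out / "signalwise_stars.csv")
    report = {
        "config": config.to_dict(),
        "n_tests": len(table),
        "any_q_below_05": bool((table["q"] < 0.05).any()),
    }
    (out / "summary_signalwise.json").write_text(json.dumps(report, indent=2))
    return report


def run_cca(config: RunConfig) -> dict:
    """CCA of the 12 traits against the K similarity indices; a rank-
    deficient input (more signals than subjects) is reported as the
    documented error instead of results."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort, personality = _load(config)
    filtered = filter_cohort(
        cohort, config.filter_low_hz, config.filter_high_hz, config.filter_order
    )
    result = compute_typicality(
        filtered,
        leave_one_out=config.leave_one_out,
        outlier_multiplier=config.outlier_multiplier,
        outlier_passes=config.outlier_passes,
    )
    traits = personality.aligned_to(result.subject_ids).scores.to_numpy()
    report: dict = {"config": config.to_dict(), "n": len(result.subject_ids)}
    try:
        res = cca(traits, result.profiles)
        report["cca"] = res.to_dict()
    except RankDeficiencyError as exc:
        logger.warning("CCA not performed: %s", exc)
        report["cca"] = None
        report["error"] = str(exc)
    (out / "cca.json").write_text(json.dumps(report, indent=2))
    return report


def run_fc(config: RunConfig) -> dict:
    """FC-typicality variant with age-partialled trait associations."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort, personality = _load(config)
    filtered = filter_cohort(
        cohort, config.filter_low_hz, config.filter_high_hz, config.filter_order
    )
    result = fc_typicality(
        filtered,
        leave_one_out=config.leave_one_out,
        outlier_multiplier=config.outlier_multiplier,
        outlier_passes=config.outlier_passes,
        fisher_z=config.fisher_z,
    )
    table = fc_trait_association(result, personality)
    pd.DataFrame(
        {"subject_id": result.subject_ids, "fc_typicality": result.indices}
    ).to_csv(out / "fc_typicality.csv", index=False, float_format="%.10g")
    _write(table, out / "fc_associations.csv")
    report = {
        "config": config.to_dict(),
        "n": len(result.subject_ids),
        "removed_subjects": result.removed_subjects,
        "associations": table.to_dict("records"),
    }
    (out / "summary_fc.json").write_text(json.dumps(report, indent=2))
    return report


def run_all(config: RunConfig) -> dict:
    """Run every analysis block and write a combined summary."""
    report = {
        "primary": run_primary(config),
        "traits": run_trait_analysis(config),
        "signalwise": run_signalwise_analysis(config),
        "cca": run_cca(config),
        "fc": run_fc(config),
    }
    out = Path(config.out_dir)
    (out / "summary.json").write_text(json.dumps(report, indent=2))
    return report
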