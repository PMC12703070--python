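"""Temporal band-pass filtering and stimulus-segment slicing.

The filter is the conventional fMRI choice: a second-order Butterworth
band-pass (default 0.009–0.1 Hz) applied forward and backward (zero
phase) with reflective edge padding, on the full concatenated series
before any segment is sliced out.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from scipy import signal

from .data import Cohort, SegmentTable
from .errors import InsufficientDataError, SchemaError

DEFAULT_LOW_HZ = 0.009
DEFAULT_HIGH_HZ = 0.1
DEFAULT_ORDER = 2


def _design_sos(tr_seconds: float, low_hz: float, high_hz: float, order: int):
    nyquist = 0.5 / tr_seconds
    if not (0.0 < low_hz < high_hz):
        raise ValueError(f"need 0 < low_hz < high_hz, got {low_hz}, {high_hz}")
    if high_hz >= nyquist:
        raise ValueError(
            f"high_hz={high_hz} must be below the Nyquist frequency "
            f"{nyquist} = 1/(2*tr) for tr={tr_seconds}s"
        )
    return signal.butter(
        order, [low_hz, high_hz], btype="bandpass", fs=1.0 / tr_seconds, output="sos"
    )


def bandpass_gain(
    freq_hz: np.ndarray | float,
    tr_seconds: float,
    low_hz: float = DEFAULT_LOW_HZ,
    high_hz: float = DEFAULT_HIGH_HZ,
    order: int = DEFAULT_ORDER,
) -> np.ndarray:
    """Analytic amplitude gain of the zero-phase filter at ``freq_hz``.

    Forward-backward application squares the one-pass magnitude response.
    """
    sos = _design_sos(tr_seconds, low_hz, high_hz, order)
    w = 2.0 * np.pi * np.atleast_1d(np.asarray(freq_hz, dtype=float)) * tr_seconds
    _, h = signal.sosfreqz(sos, worN=w)
    return np.abs(h) ** 2


def butterworth_bandpass(
    series: np.ndarray,
    tr_seconds: float,
    low_hz: float = DEFAULT_LOW_HZ,
    high_hz: float = DEFAULT_HIGH_HZ,
    order: int = DEFAULT_ORDER,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the last (time) axis.

    Accepts a (K, T) matrix or any array whose last axis is time; the
    output has the same shape. DC (and any constant offset) lies in the
    stop band and is removed.
    """
    series = np.asarray(series, dtype=float)
    sos = _design_sos(tr_seconds, low_hz, high_hz, order)
    # sosfiltfilt pads with 3 * (max(len(a), len(b)) - 1) per section pair
    padlen = 3 * (2 * sos.shape[0] + 1)
    if series.shape[-1] <= 3 * padlen:
        raise InsufficientDataError(
            f"series of length {series.shape[-1]} too short for stable "
            f"zero-phase filtering (need > {3 * padlen} samples)"
        )
    return signal.sosfiltfilt(sos, series, axis=-1, padtype="even")


def filter_cohort(
    cohort: Cohort,
    low_hz: float = DEFAULT_LOW_HZ,
    high_hz: float = DEFAULT_HIGH_HZ,
    order: int = DEFAULT_ORDER,
) -> Cohort:
    """Band-pass every subject's series; segment table is unchanged."""
    filtered = butterworth_bandpass(
        cohort.series, cohort.tr_seconds, low_hz, high_hz, order
    )
    return replace(cohort, series=filtered)


def slice_segment(cohort: Cohort, segment_name: str) -> Cohort:
    """Restrict a cohort to one named stimulus segment ("all" is identity)."""
    if segment_name == "all":
        return cohort
    if cohort.segments is None:
        raise SchemaError("cohort has no segment table; cannot slice by name")
    start, end = cohort.segments.bounds(segment_name)
    sub = SegmentTable((segment_name,), (0,), (end - start,))
    return replace(cohort, series=cohort.series[:, :, start:end].copy(), segments=sub)
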