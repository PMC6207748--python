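"""Interval measurement, heart rate, rate-corrected QT, and summaries.

The interval table is a pandas ``DataFrame`` with one row per beat and
columns ``beat_index, t_s, r_peak, rr_ms, hr_bpm, pr_ms, qrs_ms, qt_ms,
qtc_ms`` (milliseconds / beats-per-minute; missing measurements are
NaN).  QT runs from the QRS onset (onset of ventricular depolarization)
to the T-wave end (end of repolarization), and QTc uses the Fridericia
correction QTc = QT / cbrt(RR) with RR in seconds — the correction
recommended for drug-safety work.  Bazett's QT / sqrt(RR) is available
as a labeled alternative but is never the default.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import BeatAnnotation, RecordingSummary, ValidationError

#: Columns summarized over beats.
SUMMARY_METRICS = ("hr_bpm", "pr_ms", "qrs_ms", "rr_ms", "qt_ms", "qtc_ms")


def qtc_fridericia(qt_ms: float, rr_ms: float):
    """Fridericia-corrected QT: ``QT / cbrt(RR in seconds)``, in ms.

    Equals QT exactly at RR = 1000 ms. Raises on non-positive input.
    """
    qt = np.asarray(qt_ms, dtype=float)
    rr = np.asarray(rr_ms, dtype=float)
    if np.any(qt[~np.isnan(qt)] <= 0) or np.any(rr[~np.isnan(rr)] <= 0):
        raise ValidationError("qt_ms and rr_ms must be positive")
    out = qt / np.cbrt(rr / 1000.0)
    return float(out) if out.ndim == 0 else out


def qtc_bazett(qt_ms: float, rr_ms: float):
    """Bazett-corrected QT: ``QT / sqrt(RR in seconds)``, in ms."""
    qt = np.asarray(qt_ms, dtype=float)
    rr = np.asarray(rr_ms, dtype=float)
    if np.any(qt[~np.isnan(qt)] <= 0) or np.any(rr[~np.isnan(rr)] <= 0):
        raise ValidationError("qt_ms and rr_ms must be positive")
    out = qt / np.sqrt(rr / 1000.0)
    return float(out) if out.ndim == 0 else out


def _dur_ms(onset, end, fs: float):
    if onset is None or end is None:
        return np.nan
    return (end - onset) * 1000.0 / fs


def intervals_from_annotations(beats: Sequence[BeatAnnotation], fs: float,
                               t0: float = 0.0) -> pd.DataFrame:
    """Build the per-beat interval table from fiducial annotations.

    RR is measured to the *previous* R peak (the first beat has none),
    and each beat's QTc uses that same preceding RR, so per-beat QTc is
    defined exactly where both QT and RR are.
    """
    rows = []
    prev_r = None
    for i, b in enumerate(beats):
        rr = (b.r_peak - prev_r) * 1000.0 / fs if prev_r is not None else np.nan
        if prev_r is not None and rr <= 0:
            raise ValidationError(f"beats out of order at index {i}")
        qt = _dur_ms(b.qrs_onset, b.t_end, fs)
        rows.append({
            "beat_index": i,
            "t_s": t0 + b.r_peak / fs,
            "r_peak": b.r_peak,
            "rr_ms": rr,
            "hr_bpm": 60000.0 / rr if rr > 0 else np.nan,
            "pr_ms": _dur_ms(b.p_onset, b.qrs_onset, fs),
            "qrs_ms": _dur_ms(b.qrs_onset, b.qrs_end, fs),
            "qt_ms": qt,
            "qtc_ms": qtc_fridericia(qt, rr) if (qt > 0 and rr > 0) else np.nan,
        })
        prev_r = b.r_peak
    cols = ["beat_index", "t_s", "r_peak", "rr_ms", "hr_bpm", "pr_ms",
            "qrs_ms", "qt_ms", "qtc_ms"]
    return pd.DataFrame(rows, columns=cols)


def summarize(table: pd.DataFrame, window: Optional[tuple] = None) -> RecordingSummary:
    """Mean +/- sample SD of each interval metric over beats in ``window``.

    ``window`` is an absolute time range ``(start_s, end_s)`` applied to
    the beat times ``t_s``; beats outside are excluded.  An empty
    selection yields ``n_beats=0`` with no statistics; dispersion fields
    are absent with fewer than two beats.
    """
    sub = table
    if window is not None:
        lo, hi = window
        sub = table[(table["t_s"] >= lo) & (table["t_s"] < hi)]
    n = int(len(sub))
    if n == 0:
        return RecordingSummary(n_beats=0)
    mean, sd = {}, {}
    for col in SUMMARY_METRICS:
        vals = sub[col].dropna().to_numpy()
        if vals.size == 0:
            continue
        mean[col] = float(np.mean(vals))
        if n >= 2 and vals.size >= 2:
            sd[col] = float(np.std(vals, ddof=1))
    return RecordingSummary(n_beats=n, mean=mean, sd=sd)
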