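"""Core domain types and plain-text I/O for single-lead ECG signals.

The whole package works on one internal representation: a uniformly
sampled single-lead voltage trace in **millivolts** with a known sampling
rate in samples per second.  Zebrafish recordings from the portable kit
this package targets are sampled at 600 SPS, which is the default rate
throughout.

Conventions
-----------
* Sample indices are 0-based.
* Intervals are half-open ``[onset, end)``;
  ``duration_ms = (end - onset) * 1000 / fs``.
* Voltage is always millivolts internally; the reader converts a
  ``voltage_uV`` column on input.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd


class ZfecgError(Exception):
    """Base class for errors raised by this package."""


class FormatError(ZfecgError, ValueError):
    """A file or data structure does not conform to the expected format."""


class ValidationError(ZfecgError, ValueError):
    """Inputs are well-formed but violate a domain constraint."""


@dataclass(frozen=True)
class ECGRecord:
    """A uniformly sampled single-lead ECG voltage trace.

    Parameters
    ----------
    samples:
        Voltage samples in millivolts. Must be finite and non-empty.
    fs:
        Sampling rate in samples per second (> 0).
    t0:
        Start time of the first sample in seconds (default 0).
    label:
        Free-text identifier carried through the pipeline.
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1 or samples.size < 1:
            raise ValidationError("samples must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(samples)):
            raise ValidationError("samples must be finite")
        if not (self.fs > 0):
            raise ValidationError(f"fs must be > 0, got {self.fs}")
        object.__setattr__(self, "samples", samples)

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        """Record duration in seconds (= n_samples / fs)."""
        return self.samples.size / self.fs

    def times(self) -> np.ndarray:
        """Absolute sample times in seconds."""
        return self.t0 + np.arange(self.samples.size) / self.fs

    def crop(self, start_s: float, end_s: float) -> "ECGRecord":
        """Return the sub-record with sample times in ``[start_s, end_s)``.

        ``t0`` of the result is the absolute time of its first sample, so
        interval tables computed from crops stay on the original clock.
        """
        i0 = int(np.ceil((start_s - self.t0) * self.fs - 1e-9))
        i1 = int(np.ceil((end_s - self.t0) * self.fs - 1e-9))
        i0 = max(i0, 0)
        i1 = min(i1, self.samples.size)
        if i1 <= i0:
            raise ValidationError(
                f"crop window [{start_s}, {end_s}) contains no samples"
            )
        return ECGRecord(
            self.samples[i0:i1], self.fs, t0=self.t0 + i0 / self.fs, label=self.label
        )


#: Canonical order of per-beat fiducials (sample indices, earliest first).
FIDUCIAL_ORDER = (
    "p_onset",
    "p_peak",
    "p_end",
    "qrs_onset",
    "r_peak",
    "qrs_end",
    "t_end",
)


@dataclass(frozen=True)
class BeatAnnotation:
    """Per-beat fiducial sample indices.

    ``r_peak`` is mandatory; every other fiducial may be absent (``None``),
    e.g. when a wave is undetectable.  Present fiducials must respect the
    physiological ordering p_onset <= p_peak <= p_end <= qrs_onset <=
    r_peak <= qrs_end <= t_end; violating input raises at construction and
    is never silently reordered.
    """

    r_peak: int
    p_onset: Optional[int] = None
    p_peak: Optional[int] = None
    p_end: Optional[int] = None
    qrs_onset: Optional[int] = None
    qrs_end: Optional[int] = None
    t_end: Optional[int] = None

    def __post_init__(self) -> None:
        for name in FIDUCIAL_ORDER:
            v = getattr(self, name)
            if v is None:
                continue
            if v != int(v) or v < 0:
                raise ValidationError(f"{name} must be a non-negative integer, got {v!r}")
            object.__setattr__(self, name, int(v))
        present = [(n, getattr(self, n)) for n in FIDUCIAL_ORDER if getattr(self, n) is not None]
        for (na, va), (nb, vb) in zip(present, present[1:]):
            if va > vb:
                raise ValidationError(
                    f"fiducial ordering violated: {na}={va} > {nb}={vb}"
                )

    def present(self) -> dict:
        """Mapping of present fiducial names to indices, in canonical order."""
        return {n: getattr(self, n) for n in FIDUCIAL_ORDER if getattr(self, n) is not None}


@dataclass(frozen=True)
class RecordingSummary:
    """Mean and sample standard deviation of interval metrics over beats.

    ``sd`` is empty when fewer than two beats contribute.  Dispersion is
    the sample standard deviation (ddof=1), matching the mean +/- SD
    convention used for cohort ECG parameters.
    """

    n_beats: int
    mean: dict = field(default_factory=dict)
    sd: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"n_beats": self.n_beats, "mean": dict(self.mean), "sd": dict(self.sd)}


# ---------------------------------------------------------------------------
# Signal file I/O
#
# UTF-8 delimited text; comment lines start with '#'; header is either
# "time_s,voltage_mV" or "voltage_mV" (optionally voltage_uV, converted);
# an optional "# fs=600" comment carries the sampling rate for
# single-column files.
# ---------------------------------------------------------------------------

_UNIFORMITY_TOL = 1e-3  # relative tolerance on the time grid


def _parse_fs_comment(lines: Sequence[str]) -> Optional[float]:
    for ln in lines:
        s = ln.strip()
        if s.startswith("#") and "fs=" in s:
            try:
                return float(s.split("fs=", 1)[1].split()[0])
            except ValueError:
                raise FormatError(f"unparseable fs comment: {ln!r}")
    return None


def read_record(path, fs_override: Optional[float] = None) -> ECGRecord:
    """Read a delimited-text ECG signal file.

    Two-column files (``time_s,voltage_mV``) carry their own time base:
    the sampling rate is inferred from the grid and validated uniform to
    1 part in 1e3.  Single-column files need ``fs_override`` or an
    ``# fs=`` comment.  When both a time column and an override are given,
    the time column wins; disagreement beyond 0.1% is an error.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    comment_lines = [ln for ln in text.splitlines() if ln.lstrip().startswith("#")]
    fs_comment = _parse_fs_comment(comment_lines)
    try:
        df = pd.read_csv(io.StringIO(text), comment="#")
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty signal file")
    if df.shape[0] == 0:
        raise FormatError(f"{path}: no data rows")

    cols = [c.strip() for c in df.columns]
    df.columns = cols
    scale = 1.0
    if "voltage_uV" in cols:
        df = df.rename(columns={"voltage_uV": "voltage_mV"})
        cols = list(df.columns)
        scale = 1e-3
    if "voltage_mV" not in cols:
        raise FormatError(
            f"{path}: expected a 'voltage_mV' (or 'voltage_uV') column, got {cols}"
        )
    volts = df["voltage_mV"].to_numpy(dtype=float) * scale

    if "time_s" in cols and df.shape[0] >= 2:
        t = df["time_s"].to_numpy(dtype=float)
        dt = np.diff(t)
        med = float(np.median(dt))
        if med <= 0:
            raise FormatError(f"{path}: non-increasing time column")
        if np.max(np.abs(dt - med)) > _UNIFORMITY_TOL * med:
            raise FormatError(
                f"{path}: non-uniform time grid (beyond {_UNIFORMITY_TOL:g} relative)"
            )
        fs = (len(t) - 1) / (t[-1] - t[0])
        if abs(fs - round(fs)) < 1e-3 * fs:
            fs = float(round(fs))
        for claimed, src in ((fs_override, "fs_override"), (fs_comment, "fs comment")):
            if claimed is not None and abs(fs - claimed) > 1e-3 * claimed:
                raise FormatError(
                    f"{path}: time column implies fs={fs:g} but {src} says "
                    f"{claimed:g} (conflict beyond 0.1%)"
                )
        return ECGRecord(volts, fs=fs, t0=float(t[0]), label=path.stem)

    fs = fs_override if fs_override is not None else fs_comment
    if fs is None:
        raise FormatError(
            f"{path}: single-column file needs fs_override or an '# fs=' comment"
        )
    return ECGRecord(volts, fs=float(fs), label=path.stem)


def write_record(record: ECGRecord, path) -> None:
    """Write a record as two-column delimited text (stable byte-for-byte).

    Voltage keeps 6 decimal digits, so write/read round-trips to 1e-6 mV.
    """
    path = Path(path)
    t = record.times()
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# zfecg signal label={record.label}\n")
        fh.write(f"# fs={record.fs:.10g}\n")
        fh.write("time_s,voltage_mV\n")
        for ti, vi in zip(t, record.samples):
            fh.write(f"{ti:.7f},{vi:.6f}\n")


# ---------------------------------------------------------------------------
# Annotation file I/O
# ---------------------------------------------------------------------------

_ANN_COLUMNS = (
    "beat_index",
    "p_onset",
    "p_peak",
    "p_end",
    "qrs_onset",
    "r_peak",
    "qrs_end",
    "t_end",
)


def write_annotations(beats: Sequence[BeatAnnotation], path) -> None:
    """Write beat annotations as delimited text, one row per beat.

    Absent fiducials are written as empty fields; the round-trip through
    :func:`read_annotations` is lossless.
    """
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(_ANN_COLUMNS)
        for i, b in enumerate(beats):
            row = [i]
            for name in _ANN_COLUMNS[1:]:
                v = getattr(b, name)
                row.append("" if v is None else v)
            w.writerow(row)


def read_annotations(path) -> list:
    """Read an annotation file written by :func:`write_annotations`."""
    path = Path(path)
    beats = []
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty annotation file")
        if [h.strip() for h in header] != list(_ANN_COLUMNS):
            raise FormatError(f"{path}: unexpected header {header}")
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != len(_ANN_COLUMNS):
                raise FormatError(f"{path}: row {lineno}: expected "
                                  f"{len(_ANN_COLUMNS)} fields, got {len(row)}")
            vals = {}
            for name, cell in zip(_ANN_COLUMNS[1:], row[1:]):
                cell = cell.strip()
                if cell == "":
                    vals[name] = None
                    continue
                try:
                    vals[name] = int(cell)
                except ValueError:
                    raise FormatError(f"{path}: row {lineno}: bad value {cell!r} "
                                      f"for {name}")
            if vals.get("r_peak") is None:
                raise FormatError(f"{path}: row {lineno}: missing r_peak")
            try:
                beats.append(BeatAnnotation(**vals))
            except ValidationError as e:
                raise FormatError(f"{path}: row {lineno}: {e}")
    return beats
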