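"""R-peak detection, beat segmentation, template averaging, delineation.

The detector is an adaptive-threshold peak picker on the smoothed
squared derivative of the band-passed signal (the classic
Pan-Tompkins / Hamilton family).  Detected beats are windowed around
the R peak, averaged into a low-noise template ("reference wave"), and
the P/QRS/T fiducials are measured once on that template with
fractional-amplitude thresholds, then projected onto every beat.

Fractional-amplitude delineation: QRS onset/offset are the points where
|template| decays to 5% of the R amplitude moving outward from R; P
onset/end sit at 10% of the P amplitude; T end at 10% of the T
amplitude.  These fractions are chosen over tangent methods for
robustness on low-amplitude zebrafish T waves; all are configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy import signal as sps

from .core import BeatAnnotation, ECGRecord, ValidationError
from .preprocess import moving_average


@dataclass(frozen=True)
class DetectorConfig:
    """Detection and delineation parameters.

    ``refractory_ms`` (150 ms) comes from zebrafish physiology: at a
    maximal plausible heart rate of ~250 bpm the RR interval is 240 ms,
    so 150 ms blocks T-wave double counting without ever masking a real
    beat.  ``threshold_frac`` is the adaptive detection threshold as a
    fraction of the running signal-peak estimate.
    ``template_halfwidth_ms`` must cover PR + QT; the pipeline widens it
    automatically from the observed median RR.
    """

    refractory_ms: float = 150.0
    threshold_frac: float = 0.4
    search_back: bool = True
    template_halfwidth_ms: float = 200.0
    template_smooth_n: int = 10
    qrs_frac: float = 0.05
    p_frac: float = 0.10
    t_frac: float = 0.10
    p_search_ms: float = 150.0
    refine_ms: float = 10.0
    min_wave_frac: float = 0.05  # min P/T amplitude relative to R to report the wave

    def __post_init__(self):
        if self.refractory_ms <= 0:
            raise ValidationError("refractory_ms must be > 0")
        if not (0.0 < self.threshold_frac < 1.0):
            raise ValidationError("threshold_frac must be in (0, 1)")
        if self.template_halfwidth_ms <= 0 or self.template_smooth_n < 1:
            raise ValidationError("bad template window parameters")


# ---------------------------------------------------------------------------
# R-peak detection
# ---------------------------------------------------------------------------


def _detection_feature(x: np.ndarray, fs: float) -> np.ndarray:
    d = np.gradient(x) * fs
    w = max(3, int(round(0.06 * fs)) | 1)
    return moving_average(d * d, w)


def detect_r_peaks(filtered: ECGRecord, cfg: Optional[DetectorConfig] = None,
                   raw: Optional[ECGRecord] = None) -> np.ndarray:
    """Detect R peaks on a band-passed record.

    Returns strictly increasing sample indices at least one refractory
    period apart.  Each detection is refined to the local maximum of the
    (polarity-corrected) raw trace within +/-20 ms when ``raw`` is
    given, otherwise of the filtered trace.  An empty array is a valid
    result (e.g. a flat signal).
    """
    cfg = cfg or DetectorConfig()
    fs = filtered.fs
    f = _detection_feature(filtered.samples, fs)
    if not np.any(f > 0):
        return np.array([], dtype=int)

    dist = max(1, int(round(cfg.refractory_ms * fs / 1000.0)))
    cand, _ = sps.find_peaks(f, distance=dist)
    if cand.size == 0:
        return np.array([], dtype=int)

    # adaptive threshold: running signal-peak estimate (EMA), seeded from
    # the strongest candidate in the first two seconds
    head = cand[cand < int(2.0 * fs)]
    spk = float(np.max(f[head])) if head.size else float(np.quantile(f[cand], 0.95))
    accepted = []
    rejected = []
    rr_hist = []
    for p in cand:
        thr = cfg.threshold_frac * spk
        if f[p] >= thr:
            if accepted:
                rr_hist.append(p - accepted[-1])
            accepted.append(int(p))
            spk = 0.875 * spk + 0.125 * float(f[p])
        else:
            rejected.append(int(p))

    if cfg.search_back and len(accepted) >= 2 and rejected:
        rej = np.asarray(rejected)
        out = [accepted[0]]
        for p in accepted[1:]:
            rr_med = float(np.median(np.diff(out))) if len(out) >= 3 else (
                float(np.median(rr_hist)) if rr_hist else dist * 2.0)
            gap = p - out[-1]
            if gap > 1.66 * rr_med:
                inside = rej[(rej > out[-1] + dist) & (rej < p - dist)]
                if inside.size:
                    best = int(inside[np.argmax(f[inside])])
                    if f[best] >= 0.2 * spk:
                        out.append(best)
            out.append(p)
        accepted = out

    # refine to the local extremum of the raw (polarity-corrected) trace
    ref = raw.samples if raw is not None else filtered.samples
    half = int(round(0.020 * fs))
    refined = []
    for p in accepted:
        i0, i1 = max(0, p - half), min(len(ref), p + half + 1)
        refined.append(i0 + int(np.argmax(ref[i0:i1])))

    # enforce strict ordering + refractory after refinement
    out = []
    for p in sorted(set(refined)):
        if out and p - out[-1] < dist:
            continue
        out.append(p)
    return np.asarray(out, dtype=int)


# ---------------------------------------------------------------------------
# Segmentation and template averaging
# ---------------------------------------------------------------------------


def halfwidth_samples(cfg: DetectorConfig, fs: float) -> int:
    return int(round(cfg.template_halfwidth_ms * fs / 1000.0))


def segment_beats(record: ECGRecord, r_peaks: Sequence[int],
                  cfg: Optional[DetectorConfig] = None) -> tuple:
    """Window each beat at ``r_peak +/- template_halfwidth_ms``.

    Returns ``(windows, kept)`` where ``windows`` is a (k, L) array of
    equal-length windows and ``kept`` holds the indices into ``r_peaks``
    of the beats retained; beats whose window would be clipped by the
    record edges are discarded.
    """
    cfg = cfg or DetectorConfig()
    h = halfwidth_samples(cfg, record.fs)
    n = len(record)
    windows, kept = [], []
    for i, r in enumerate(r_peaks):
        if r - h < 0 or r + h + 1 > n:
            continue
        windows.append(record.samples[r - h: r + h + 1])
        kept.append(i)
    windows = np.asarray(windows) if windows else np.empty((0, 2 * h + 1))
    return windows, np.asarray(kept, dtype=int)


@dataclass(frozen=True)
class Template:
    """Averaged beat waveform (the recording's reference wave).

    ``values`` is the moving-average-smoothed ensemble mean reported as
    the reference wave; ``raw`` is the unsmoothed ensemble mean, kept
    because fractional-amplitude boundaries are measured on it (the
    moving average widens narrow deflections by a known amount, which
    would bias QRS boundaries; averaging across beats already provides
    the noise suppression the boundaries need).
    """

    values: np.ndarray
    raw: np.ndarray
    r_offset: int
    n_beats: int

    def __len__(self):
        return self.values.size


def average_template(windows: np.ndarray, cfg: Optional[DetectorConfig] = None) -> Template:
    """Average per-beat windows into a template.

    Each window is smoothed with a centered moving average of
    ``template_smooth_n`` samples and the smoothed windows are averaged
    pointwise.  (The moving average is linear and identical across
    windows, so this equals smoothing the ensemble mean; the unsmoothed
    mean is retained alongside.)
    """
    cfg = cfg or DetectorConfig()
    windows = np.asarray(windows)
    if windows.size == 0 or windows.shape[0] == 0:
        raise ValidationError("no beats to average")
    raw_mean = windows.mean(axis=0)
    smoothed = moving_average(raw_mean, cfg.template_smooth_n)
    return Template(values=smoothed, raw=raw_mean,
                    r_offset=(windows.shape[1] - 1) // 2,
                    n_beats=windows.shape[0])


# ---------------------------------------------------------------------------
# Delineation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TemplateFiducials:
    """Sub-sample fiducial offsets relative to the template window start.

    Any wave that cannot be measured is reported ``None``, never
    fabricated.  ``t_start``/``t_peak`` and ``p_peak`` are retained for
    inspection even though only the canonical seven fiducials are
    projected onto beats.
    """

    r: float
    p_onset: Optional[float] = None
    p_peak: Optional[float] = None
    p_end: Optional[float] = None
    qrs_onset: Optional[float] = None
    qrs_end: Optional[float] = None
    t_start: Optional[float] = None
    t_peak: Optional[float] = None
    t_end: Optional[float] = None


def _cross_below(y: np.ndarray, start: int, stop: int, step: int, thr: float,
                 hold_n: int) -> Optional[float]:
    """First sustained |y| < thr crossing walking from ``start`` by ``step``.

    The crossing must be followed (in walk direction) by at least
    ``hold_n`` consecutive sub-threshold samples, so brief zero crossings
    inside a multiphasic complex are skipped.  Returns a sub-sample
    position via linear interpolation, or None.
    """
    a = np.abs(y)
    n = a.size
    if (step > 0 and start >= stop) or (step < 0 and start <= stop):
        return None
    run = 0
    i = start
    first_below = None
    while 0 <= i != stop and i < n:
        if a[i] < thr:
            if run == 0:
                first_below = i
            run += 1
            if run >= hold_n:
                j = first_below
                prev = j - step
                if 0 <= prev < n and a[prev] >= thr and a[prev] != a[j]:
                    frac = (a[prev] - thr) / (a[prev] - a[j])
                    return prev + step * frac
                return float(j)
        else:
            run = 0
        i += step
    # reached the boundary while inside a sub-threshold run long enough?
    if run >= max(2, hold_n // 2) and first_below is not None:
        prev = first_below - step
        if 0 <= prev < n and np.abs(y[prev]) >= thr and np.abs(y[prev]) != a[first_below]:
            frac = (np.abs(y[prev]) - thr) / (np.abs(y[prev]) - a[first_below])
            return prev + step * frac
        return float(first_below)
    return None


# Sustained-crossing hold times per wave: a boundary must stay
# sub-threshold for a duration commensurate with the wave's time scale,
# so brief zero crossings inside a complex (or noise dips on the slow T
# decay) do not terminate the search early.
_HOLD_QRS_MS = 6.0
_HOLD_P_MS = 8.0
_HOLD_T_MS = 15.0


def _delineate_once(y: np.ndarray, s: np.ndarray, r: int, fs: float,
                    cfg: DetectorConfig) -> TemplateFiducials:
    n = y.size
    r_amp = abs(float(y[r]))
    if r_amp == 0:
        raise ValidationError("template has zero amplitude at the R offset")

    def hold(ms):
        return max(2, int(round(ms * fs / 1000.0)))

    thr_qrs = cfg.qrs_frac * r_amp
    qrs_on = _cross_below(y, r - 1, -1, -1, thr_qrs, hold(_HOLD_QRS_MS))
    qrs_end = _cross_below(y, r + 1, n, +1, thr_qrs, hold(_HOLD_QRS_MS))

    out = {"r": float(r), "qrs_onset": qrs_on, "qrs_end": qrs_end}

    # ---- P wave: search the smoothed wave left of QRS onset, backed off
    # a little so the QRS upstroke cannot masquerade as a P peak
    p_lo = max(0, r - int(round(cfg.p_search_ms * fs / 1000.0)))
    p_hi = (int(math.floor(qrs_on)) - int(round(0.005 * fs))
            if qrs_on is not None else r)
    if p_hi - p_lo >= 3:
        p_peak = p_lo + int(np.argmax(s[p_lo:p_hi]))
        # refine on the ensemble mean within +/-3 ms, staying in bounds
        w = max(1, int(round(0.003 * fs)))
        i0, i1 = max(p_lo, p_peak - w), min(p_hi, p_peak + w + 1)
        p_peak = i0 + int(np.argmax(y[i0:i1]))
        p_amp = float(y[p_peak])
        if p_amp >= cfg.min_wave_frac * r_amp:
            thr_p = cfg.p_frac * p_amp
            p_on = _cross_below(y, p_peak - 1, -1, -1, thr_p, hold(_HOLD_P_MS))
            p_end = _cross_below(y, p_peak + 1, p_hi, +1, thr_p, hold(_HOLD_P_MS))
            if (p_on is not None and p_end is not None
                    and p_on < p_peak < p_end
                    and (qrs_on is None or p_end <= qrs_on)):
                out.update(p_onset=p_on, p_peak=float(p_peak), p_end=p_end)

    # ---- T wave: search right of QRS end
    if qrs_end is not None:
        t_lo = int(math.ceil(qrs_end)) + int(round(0.010 * fs))
        if n - t_lo >= 3:
            t_peak = t_lo + int(np.argmax(np.abs(s[t_lo:n])))
            w = max(1, int(round(0.003 * fs)))
            i0, i1 = max(0, t_peak - w), min(n, t_peak + w + 1)
            t_peak = i0 + int(np.argmax(np.abs(y[i0:i1])))
            t_amp = abs(float(y[t_peak]))
            if t_amp >= cfg.min_wave_frac * r_amp:
                thr_t = cfg.t_frac * t_amp
                t_end = _cross_below(y, t_peak + 1, n, +1, thr_t, hold(_HOLD_T_MS))
                t_start = _cross_below(y, t_peak - 1, t_lo - 1, -1, thr_t,
                                       hold(_HOLD_T_MS))
                if t_end is not None:
                    out.update(t_peak=float(t_peak), t_end=t_end, t_start=t_start)

    return TemplateFiducials(**out)


def _isoelectric_baseline(y: np.ndarray, r: int, fs: float, cfg: DetectorConfig,
                          rough: TemplateFiducials) -> np.ndarray:
    """Piecewise-linear baseline through the template's quiet segments.

    Low-frequency artifact (gill movement, wander) is not fully
    independent of the beat phase, so a residual survives ensemble
    averaging; it is the same order as the 10% thresholds of the small
    P and T waves.  The residual is smooth, so a piecewise-linear fit
    through isoelectric anchors — before the P search region, in the ST
    segment, and after the rough T end — removes most of it.
    """
    n = y.size

    def ms(v):
        return int(round(v * fs / 1000.0))

    anchors = []

    def add(lo, hi):
        lo, hi = max(0, lo), min(n, hi)
        if hi - lo >= 3:
            anchors.append(((lo + hi - 1) / 2.0, float(np.median(y[lo:hi]))))

    add(r - ms(cfg.p_search_ms + 20.0), r - ms(cfg.p_search_ms))
    if rough.qrs_end is not None:
        qe = int(math.ceil(rough.qrs_end))
        add(qe + ms(8.0), qe + ms(28.0))
    if rough.t_end is not None:
        te = int(math.ceil(rough.t_end))
        add(te + ms(25.0), te + ms(45.0))

    if not anchors:
        return np.zeros(n)
    xs, vs = zip(*anchors)
    return np.interp(np.arange(n), xs, vs)


def delineate(template: Template, r_offset: Optional[int] = None,
              fs: float = 600.0, cfg: Optional[DetectorConfig] = None) -> TemplateFiducials:
    """Measure P/QRS/T fiducials on an averaged template.

    Boundaries are fractional-amplitude threshold crossings on the
    unsmoothed ensemble mean (sub-sample, linearly interpolated); peak
    positions are located on the smoothed reference wave and refined on
    the ensemble mean.  Two passes are made: a rough pass locates the
    waves, an isoelectric baseline anchored in the quiet segments is
    subtracted, and the fiducials are re-measured on the corrected
    template.  Waves whose amplitude falls below ``min_wave_frac`` of
    the R amplitude are reported absent, never fabricated.
    """
    cfg = cfg or DetectorConfig()
    y = template.raw
    s = template.values
    n = y.size
    r = template.r_offset if r_offset is None else int(r_offset)
    if not (0 <= r < n):
        raise ValidationError(f"r_offset {r} outside template of length {n}")

    rough = _delineate_once(y, s, r, fs, cfg)
    base = _isoelectric_baseline(y, r, fs, cfg, rough)
    return _delineate_once(y - base, s - base, r, fs, cfg)


# ---------------------------------------------------------------------------
# Per-beat annotation
# ---------------------------------------------------------------------------


def annotate_beats(record: ECGRecord, r_peaks: Sequence[int],
                   fiducials: TemplateFiducials,
                   cfg: Optional[DetectorConfig] = None,
                   kept: Optional[Sequence[int]] = None) -> list:
    """Project template fiducials onto each retained beat.

    Boundary fiducials (onsets, offsets, T end) are carried rigidly at
    their template offsets from the R peak — per-beat threshold
    crossings on raw noisy beats are not re-measured, so a noisy beat
    cannot move a boundary across waves.  The P peak is refined to the
    local maximum of the trace within ``refine_ms`` (the R peak was
    already refined during detection).  Beats whose window was clipped
    at the record edges are absent from the output.
    """
    cfg = cfg or DetectorConfig()
    fs = record.fs
    n = len(record)
    h = halfwidth_samples(cfg, fs)
    if kept is None:
        kept = [i for i, r in enumerate(r_peaks) if r - h >= 0 and r + h + 1 <= n]

    offsets = {}
    for name in ("p_onset", "p_peak", "p_end", "qrs_onset", "qrs_end", "t_end"):
        v = getattr(fiducials, name)
        offsets[name] = None if v is None else v - fiducials.r

    w = max(1, int(round(cfg.refine_ms * fs / 1000.0)))
    beats = []
    for i in kept:
        r = int(r_peaks[i])
        vals = {"r_peak": r}
        ok = True
        for name, off in offsets.items():
            if off is None:
                vals[name] = None
                continue
            idx = int(round(r + off))
            if name == "p_peak":
                i0, i1 = max(0, idx - w), min(n, idx + w + 1)
                idx = i0 + int(np.argmax(record.samples[i0:i1]))
            if not (0 <= idx < n):
                ok = False
                break
            vals[name] = idx
        if not ok:
            continue
        # a refined P peak may not cross its neighbours; clamp into order
        if vals.get("p_peak") is not None:
            lo = vals.get("p_onset")
            hi = vals.get("p_end")
            if lo is not None:
                vals["p_peak"] = max(vals["p_peak"], lo)
            if hi is not None:
                vals["p_peak"] = min(vals["p_peak"], hi)
        beats.append(BeatAnnotation(**vals))
    return beats
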