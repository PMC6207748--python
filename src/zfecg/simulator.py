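"""Synthetic adult-zebrafish ECG generator with a ground-truth channel.

Each beat is rendered as a sum of parameterized Gaussian deflections
(P wave, triphasic Q-R-S complex, T wave) placed so that the programmed
conduction intervals hold exactly:

* ``qrs_onset = r - qrs/2`` and ``qrs_end = r + qrs/2`` — the QRS onset
  and offset are defined as the points where the R deflection decays to
  5% of its amplitude, so the R-wave standard deviation is
  ``sigma_R = (qrs/2) / sqrt(2 ln 20)``.
* ``p_onset = qrs_onset - PR``; the P wave spans ``p_width`` with its
  onset/end at the 10% points of its Gaussian
  (``sigma_P = (p_width/2) / sqrt(2 ln 10)``).
* ``t_end = qrs_onset + QT`` (QT is measured from the onset of
  ventricular depolarization to the end of repolarization); the T end is
  the 10% decay point of the T Gaussian.

Because the analytic fiducials coincide with the fractional-amplitude
definitions used by the delineator, a noise-free render is recoverable
exactly, which is what makes every pipeline stage testable without
animal data.

Acquisition is emulated with a zero-phase 80 Hz digital low-pass at
600 samples/s (the recording kit's data rate).  Noise emulates the
dominant in vivo sources: 60 Hz AC-line pickup, low-frequency
gill-movement bursts (1-3 Hz band), slow baseline wander, and white
sensor noise.  All randomness flows from a single seed through named
child streams, so the output is a pure function of the scenario.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .core import BeatAnnotation, ECGRecord, ValidationError

# Fractional-amplitude constants shared with the delineator: a Gaussian
# falls to 5% of its peak at sqrt(2 ln 20) sigma and to 10% at
# sqrt(2 ln 10) sigma.
C_QRS = math.sqrt(2.0 * math.log(20.0))   # ~2.4477
C_WAVE = math.sqrt(2.0 * math.log(10.0))  # ~2.1460


class PresetError(LookupError):
    """Unknown scenario preset name."""


# ---------------------------------------------------------------------------
# Piecewise time-courses
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Timecourse:
    """Piecewise time-course built from (time, value) knots.

    ``kinds[i]`` describes the segment between knot i and knot i+1:
    ``"hold"`` keeps the left value (a step at the next knot) and
    ``"ramp"`` interpolates linearly.  Beyond the last knot the last
    value holds; before the first knot the first value holds.
    """

    times: tuple
    values: tuple
    kinds: tuple = ()

    def __post_init__(self):
        times = tuple(float(t) for t in self.times)
        values = tuple(float(v) for v in self.values)
        if len(times) != len(values) or not times:
            raise ValidationError("times and values must be equal-length, non-empty")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValidationError("knot times must be strictly increasing")
        kinds = tuple(self.kinds) if self.kinds else ("ramp",) * (len(times) - 1)
        if len(kinds) != len(times) - 1:
            raise ValidationError("need one segment kind per knot interval")
        if any(k not in ("hold", "ramp") for k in kinds):
            raise ValidationError(f"segment kinds must be 'hold' or 'ramp', got {kinds}")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "kinds", kinds)

    @classmethod
    def constant(cls, v: float) -> "Timecourse":
        return cls((0.0,), (float(v),))

    @classmethod
    def step(cls, t_step: float, before: float, after: float) -> "Timecourse":
        """Value ``before`` up to ``t_step``, ``after`` from then on."""
        return cls((0.0, t_step), (before, after), ("hold",))

    @classmethod
    def ramp(cls, knots: Sequence) -> "Timecourse":
        """Linear interpolation through ``[(t, v), ...]`` knots."""
        ts, vs = zip(*knots)
        return cls(ts, vs)

    def value(self, t: float) -> float:
        ts, vs, kinds = self.times, self.values, self.kinds
        if t <= ts[0]:
            return vs[0]
        if t >= ts[-1]:
            return vs[-1]
        i = int(np.searchsorted(ts, t, side="right")) - 1
        if kinds[i] == "hold":
            return vs[i]
        frac = (t - ts[i]) / (ts[i + 1] - ts[i])
        return vs[i] + frac * (vs[i + 1] - vs[i])

    def max(self) -> float:
        return max(self.values)

    def min(self) -> float:
        return min(self.values)


def _as_timecourse(x) -> Timecourse:
    if isinstance(x, Timecourse):
        return x
    return Timecourse.constant(float(x))


# ---------------------------------------------------------------------------
# Scenario building blocks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BeatMorphology:
    """Amplitudes (mV) and widths (ms) of the rendered P/QRS/T deflections.

    The R wave must be the dominant deflection.  ``polarity=-1`` models a
    reversed lead (e.g. an over-inserted pectoral electrode) and negates
    the entire recorded trace.
    """

    p_amp: float = 0.15
    p_width_ms: float = 30.0
    q_amp: float = -0.15
    r_amp: float = 1.0
    s_amp: float = -0.15
    qrs_width_ms: float = 44.0
    t_amp: float = 0.25
    t_width_ms: float = 120.0
    polarity: int = 1

    def __post_init__(self):
        for name in ("p_width_ms", "qrs_width_ms", "t_width_ms"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if not (abs(self.r_amp) > abs(self.p_amp) and abs(self.r_amp) > abs(self.t_amp)):
            raise ValidationError("R must be the dominant deflection")
        if self.polarity not in (1, -1):
            raise ValidationError("polarity must be +1 or -1")


@dataclass(frozen=True)
class RhythmSpec:
    """Heart-rate and conduction-interval time-courses.

    ``hr`` is in bpm; ``pr_ms``/``qrs_ms``/``qt_ms`` are the programmed
    conduction intervals; any may be a constant or a :class:`Timecourse`.
    ``hrv_sd_ms`` is Gaussian beat-to-beat RR jitter.
    ``dropped_qrs_prob`` is the probability that an atrial (P) event is
    not followed by a ventricular complex — high-degree AV block.
    """

    hr: Timecourse = field(default_factory=lambda: Timecourse.constant(148.0))
    hrv_sd_ms: float = 5.0
    pr_ms: Timecourse = field(default_factory=lambda: Timecourse.constant(62.0))
    qrs_ms: Timecourse = field(default_factory=lambda: Timecourse.constant(44.0))
    qt_ms: Timecourse = field(default_factory=lambda: Timecourse.constant(215.0))
    dropped_qrs_prob: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "hr", _as_timecourse(self.hr))
        for name in ("pr_ms", "qrs_ms", "qt_ms"):
            object.__setattr__(self, name, _as_timecourse(getattr(self, name)))
        if not (20.0 < self.hr.min() and self.hr.max() < 400.0):
            raise ValidationError("heart rate must stay within (20, 400) bpm")
        if self.hrv_sd_ms < 0:
            raise ValidationError("hrv_sd_ms must be >= 0")
        if not (0.0 <= self.dropped_qrs_prob < 1.0):
            raise ValidationError("dropped_qrs_prob must be in [0, 1)")


@dataclass(frozen=True)
class NoiseSpec:
    """Additive noise model for the rendered trace (amplitudes in mV).

    * ``line_*`` — AC mains pickup (sinusoid, default 60 Hz).
    * ``gill_*`` — gill-movement artifact: band-limited (1-3 Hz) noise
      gated by randomly timed burst envelopes; the dominant noise source
      in anesthetized-fish recordings since opercular movement persists
      under sedation.
    * ``wander_*`` — slow baseline wander (default 0.2 Hz).
    * ``white_sd_mV`` — wideband sensor noise.
    """

    line_hz: float = 60.0
    line_amp_mV: float = 0.05
    gill_burst_rate_per_s: float = 0.5
    gill_band_hz: tuple = (1.0, 3.0)
    gill_amp_mV: float = 0.1
    wander_amp_mV: float = 0.05
    wander_hz: float = 0.2
    white_sd_mV: float = 0.02

    def __post_init__(self):
        for name in ("line_amp_mV", "gill_amp_mV", "wander_amp_mV", "white_sd_mV",
                     "gill_burst_rate_per_s"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        for name in ("line_hz", "wander_hz"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        lo, hi = self.gill_band_hz
        if not (0 < lo < hi):
            raise ValidationError("gill_band_hz must be an increasing positive pair")

    @classmethod
    def none(cls) -> "NoiseSpec":
        """A silent noise model (for oracle tests on clean renders)."""
        return cls(line_amp_mV=0.0, gill_amp_mV=0.0, wander_amp_mV=0.0,
                   white_sd_mV=0.0, gill_burst_rate_per_s=0.0)


@dataclass(frozen=True)
class ScenarioSpec:
    """Complete generative description of a recording.

    Identical specs (including ``seed``) render bit-identical output.
    """

    name: str
    duration_s: float
    morphology: BeatMorphology = field(default_factory=BeatMorphology)
    rhythm: RhythmSpec = field(default_factory=RhythmSpec)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    fs: float = 600.0
    seed: int = 0
    events: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.duration_s <= 0:
            raise ValidationError("duration_s must be > 0")
        if self.fs <= 0:
            raise ValidationError("fs must be > 0")


@dataclass(frozen=True)
class GroundTruth:
    """Truth channel recorded while rendering (indices before noise).

    ``beats`` lists fully conducted beats; ``p_events`` lists P-only
    (dropped-QRS) events as ``(p_onset, p_peak, p_end)`` index triples.
    ``intervals`` carries the programmed per-beat rr/pr/qrs/qt in ms for
    conducted beats (RR between successive conducted R peaks).
    """

    beats: list
    p_events: list
    intervals: pd.DataFrame


@dataclass(frozen=True)
class BeatSchedule:
    """Output of :func:`make_beat_schedule`: beat times + true intervals."""

    times: np.ndarray        # beat (R) times, seconds
    pr_ms: np.ndarray
    qrs_ms: np.ndarray
    qt_ms: np.ndarray
    dropped: np.ndarray      # bool; True = P not followed by QRS

    def __len__(self):
        return self.times.size


# ---------------------------------------------------------------------------
# Scheduling
# ---------------------------------------------------------------------------


def _margins(rhythm: RhythmSpec, t: float) -> tuple:
    """Lead-in / lead-out a beat at time t needs to render fully."""
    pr = rhythm.pr_ms.value(t)
    qrs = rhythm.qrs_ms.value(t)
    qt = rhythm.qt_ms.value(t)
    lead_in = (pr + qrs / 2.0) / 1000.0 + 0.1
    lead_out = (qt - qrs / 2.0) / 1000.0 + 0.15
    return lead_in, lead_out


def make_beat_schedule(rhythm: RhythmSpec, duration_s: float, seed) -> BeatSchedule:
    """Generate beat times and per-beat true intervals for a rhythm.

    Successive R times advance by ``RR = 60/hr(t)`` seconds plus Gaussian
    jitter of ``hrv_sd_ms``; per-beat conduction intervals are sampled
    from their time-courses at the beat time; dropped-QRS flags are
    Bernoulli with ``dropped_qrs_prob``.  The feasibility constraint
    ``PR + QT < RR`` is validated at every beat and raises (naming the
    first offending time) rather than clipping.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    jitter_rng, drop_rng = (np.random.Generator(np.random.Philox(s)) for s in ss.spawn(2))

    times, prs, qrss, qts, dropped = [], [], [], [], []
    lead_in, _ = _margins(rhythm, 0.0)
    t = max(0.4, lead_in)
    while True:
        _, lead_out = _margins(rhythm, t)
        if t > duration_s - lead_out:
            break
        pr = rhythm.pr_ms.value(t)
        qrs = rhythm.qrs_ms.value(t)
        qt = rhythm.qt_ms.value(t)
        rr_s = 60.0 / rhythm.hr.value(t) + jitter_rng.normal(0.0, rhythm.hrv_sd_ms) / 1000.0
        if rr_s <= 0:
            raise ValidationError(f"jittered RR became non-positive at t={t:.3f} s")
        if (pr + qt) / 1000.0 >= rr_s:
            raise ValidationError(
                f"infeasible rhythm at t={t:.3f} s: PR+QT = {pr + qt:.1f} ms "
                f">= RR = {rr_s * 1000:.1f} ms"
            )
        times.append(t)
        prs.append(pr)
        qrss.append(qrs)
        qts.append(qt)
        dropped.append(bool(drop_rng.random() < rhythm.dropped_qrs_prob))
        t += rr_s

    return BeatSchedule(
        times=np.asarray(times),
        pr_ms=np.asarray(prs),
        qrs_ms=np.asarray(qrss),
        qt_ms=np.asarray(qts),
        dropped=np.asarray(dropped, dtype=bool),
    )


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def _add_gaussian(y: np.ndarray, fs: float, center_s: float, sigma_s: float,
                  amp: float) -> None:
    if amp == 0.0:
        return
    i0 = max(0, int(math.ceil((center_s - 5 * sigma_s) * fs)))
    i1 = min(y.size, int(math.floor((center_s + 5 * sigma_s) * fs)) + 1)
    if i1 <= i0:
        return
    tt = np.arange(i0, i1) / fs
    y[i0:i1] += amp * np.exp(-0.5 * ((tt - center_s) / sigma_s) ** 2)


def _acquisition_lowpass(x: np.ndarray, fs: float, cutoff_hz: float = 80.0) -> np.ndarray:
    """Zero-phase FIR low-pass emulating the kit's 80 Hz digital filter."""
    if cutoff_hz >= fs / 2:
        return x
    numtaps = int(round(0.2 * fs)) | 1
    taps = sps.firwin(numtaps, cutoff_hz, fs=fs, window="hamming")
    return sps.oaconvolve(x, taps, mode="same")


def _gill_noise(n: int, fs: float, noise: NoiseSpec, rng: np.random.Generator) -> np.ndarray:
    """Amplitude-modulated band-limited bursts emulating gill movement."""
    if noise.gill_amp_mV == 0.0 or noise.gill_burst_rate_per_s == 0.0:
        # keep the stream advanced deterministically regardless of amplitude
        return np.zeros(n)
    duration = n / fs
    n_bursts = rng.poisson(noise.gill_burst_rate_per_s * duration)
    carrier = rng.standard_normal(n)
    lo, hi = noise.gill_band_hz
    b, a = sps.butter(2, [lo, hi], btype="band", fs=fs)
    carrier = sps.filtfilt(b, a, carrier)
    rms = float(np.sqrt(np.mean(carrier**2)))
    if rms > 0:
        carrier /= rms
    env = np.zeros(n)
    for _ in range(n_bursts):
        t_c = rng.uniform(0.0, duration)
        w = rng.uniform(0.5, 1.5)  # burst length, s
        i0 = max(0, int((t_c - w / 2) * fs))
        i1 = min(n, int((t_c + w / 2) * fs))
        if i1 > i0:
            env[i0:i1] = np.maximum(env[i0:i1], np.hanning(i1 - i0))
    return noise.gill_amp_mV * carrier * env


def render_record(spec: ScenarioSpec) -> tuple:
    """Render a scenario into an :class:`ECGRecord` plus its ground truth.

    The clean beat train is synthesized first and passed through the
    80 Hz acquisition low-pass; truth fiducials are the analytic wave
    positions on the sample grid, recorded before noise.  Noise is then
    added and the lead polarity applied to the summed trace.
    """
    fs = spec.fs
    n = int(round(spec.duration_s * fs))
    morph = spec.morphology
    rhythm = spec.rhythm

    ss = np.random.SeedSequence(spec.seed)
    sched_ss, noise_ss = ss.spawn(2)
    schedule = make_beat_schedule(rhythm, spec.duration_s, sched_ss)

    clean = np.zeros(n)
    truth_beats = []
    p_events = []
    rows = []
    prev_t_end = -np.inf
    prev_conducted_r = None

    for k in range(len(schedule)):
        r_t = schedule.times[k]
        pr = schedule.pr_ms[k] / 1000.0
        qrs = schedule.qrs_ms[k] / 1000.0
        qt = schedule.qt_ms[k] / 1000.0
        p_w = morph.p_width_ms / 1000.0
        t_w = morph.t_width_ms / 1000.0

        qrs_on_t = r_t - qrs / 2.0
        qrs_end_t = r_t + qrs / 2.0
        p_on_t = qrs_on_t - pr
        p_peak_t = p_on_t + p_w / 2.0
        p_end_t = p_on_t + p_w
        t_end_t = qrs_on_t + qt
        t_peak_t = t_end_t - t_w / 2.0

        if p_on_t < prev_t_end:
            raise ValidationError(
                f"render collision at t={r_t:.3f} s: P onset overlaps the "
                f"previous beat's T wave"
            )

        sigma_p = (p_w / 2.0) / C_WAVE
        sigma_r = (qrs / 2.0) / C_QRS
        sigma_t = (t_w / 2.0) / C_WAVE
        sigma_qs = qrs * 0.07

        _add_gaussian(clean, fs, p_peak_t, sigma_p, morph.p_amp)
        if schedule.dropped[k]:
            p_events.append((int(round(p_on_t * fs)), int(round(p_peak_t * fs)),
                             int(round(p_end_t * fs))))
            prev_t_end = p_end_t
            continue
        _add_gaussian(clean, fs, r_t - 0.3 * qrs, sigma_qs, morph.q_amp)
        _add_gaussian(clean, fs, r_t, sigma_r, morph.r_amp)
        _add_gaussian(clean, fs, r_t + 0.3 * qrs, sigma_qs, morph.s_amp)
        _add_gaussian(clean, fs, t_peak_t, sigma_t, morph.t_amp)

        idx = {name: int(round(t * fs)) for name, t in (
            ("p_onset", p_on_t), ("p_peak", p_peak_t), ("p_end", p_end_t),
            ("qrs_onset", qrs_on_t), ("r_peak", r_t), ("qrs_end", qrs_end_t),
            ("t_end", t_end_t))}
        truth_beats.append(BeatAnnotation(**idx))
        rr_ms = (r_t - prev_conducted_r) * 1000.0 if prev_conducted_r is not None else np.nan
        rows.append({
            "beat_index": len(truth_beats) - 1,
            "t_s": r_t,
            "rr_ms": rr_ms,
            "pr_ms": schedule.pr_ms[k],
            "qrs_ms": schedule.qrs_ms[k],
            "qt_ms": schedule.qt_ms[k],
        })
        prev_conducted_r = r_t
        prev_t_end = t_end_t

    clean = _acquisition_lowpass(clean, fs)

    line_rng, gill_rng, wander_rng, white_rng = (
        np.random.Generator(np.random.Philox(s)) for s in noise_ss.spawn(4))
    t_grid = np.arange(n) / fs
    noise = spec.noise
    total = clean.copy()
    total += noise.line_amp_mV * np.sin(
        2 * np.pi * noise.line_hz * t_grid + line_rng.uniform(0, 2 * np.pi))
    total += _gill_noise(n, fs, noise, gill_rng)
    total += noise.wander_amp_mV * np.sin(
        2 * np.pi * noise.wander_hz * t_grid + wander_rng.uniform(0, 2 * np.pi))
    total += noise.white_sd_mV * white_rng.standard_normal(n)
    total *= morph.polarity

    record = ECGRecord(total, fs=fs, label=spec.name)
    truth = GroundTruth(
        beats=truth_beats,
        p_events=p_events,
        intervals=pd.DataFrame(rows, columns=["beat_index", "t_s", "rr_ms",
                                              "pr_ms", "qrs_ms", "qt_ms"]),
    )
    return record, truth


# ---------------------------------------------------------------------------
# Scenario presets
#
# Preset parameter values are the study conditions this generator
# emulates: baseline adult-zebrafish electrocardiography (HR 148 bpm,
# PR 62 ms, QRS 44 ms, QT 215 ms, RR 469 ms) and the drug-response
# scenarios (MS-222 bradycardia, isoproterenol dose ladder, verapamil HR
# reduction, amiodarone/quinidine QT prolongation, veratridine
# first-degree AV block).
# ---------------------------------------------------------------------------

#: Heart-rate fold change per isoproterenol dose (uM) at the top of the
#: reported dose ladder.
ISOPROTERENOL_FOLDS = {0.5: 1.04, 1.0: 1.12, 5.0: 1.14, 7.5: 1.22, 10.0: 1.25}

#: Pre-injection heart rate for the isoproterenol scenario: the
#: MS-222-induced bradycardia condition into which the drug is injected.
ISOPROTERENOL_PRE_HR = 130.0


def _preset_baseline_ab(seed):
    return ScenarioSpec(
        name="baseline_ab", duration_s=120.0, seed=seed,
        rhythm=RhythmSpec(hr=Timecourse.constant(148.0)),
    )


def _preset_baseline_rr469(seed):
    return ScenarioSpec(
        name="baseline_rr469", duration_s=120.0, seed=seed,
        rhythm=RhythmSpec(hr=Timecourse.constant(60000.0 / 469.0)),
    )


def _preset_ms222_ramp(seed):
    # HR 108 bpm over the first sedation minute, declining to 89 bpm by
    # minute 5 and 64 bpm by minute 10.
    hr = Timecourse((0.0, 60.0, 300.0, 600.0), (108.0, 108.0, 89.0, 64.0),
                    ("hold", "ramp", "ramp"))
    return ScenarioSpec(name="ms222_ramp", duration_s=600.0, seed=seed,
                        rhythm=RhythmSpec(hr=hr))


def _preset_isoproterenol_step(seed, dose_um: float = 10.0):
    if dose_um not in ISOPROTERENOL_FOLDS:
        raise PresetError(
            f"unknown isoproterenol dose {dose_um}; known doses: "
            f"{sorted(ISOPROTERENOL_FOLDS)}")
    fold = ISOPROTERENOL_FOLDS[dose_um]
    hr = Timecourse.step(60.0, ISOPROTERENOL_PRE_HR, ISOPROTERENOL_PRE_HR * fold)
    return ScenarioSpec(
        name="isoproterenol_step", duration_s=120.0, seed=seed,
        rhythm=RhythmSpec(hr=hr),
        events={"injection_s": 60.0, "dose_um": dose_um, "fold": fold},
    )


def _preset_verapamil_step(seed):
    # Baseline 155 bpm; drop to 116 bpm within 60 s of injection (25%
    # reduction), then decline to 88 bpm by the 5-minute mark (43%).
    hr = Timecourse((0.0, 60.0, 120.0, 330.0), (155.0, 116.0, 116.0, 88.0),
                    ("hold", "hold", "ramp"))
    return ScenarioSpec(
        name="verapamil_step", duration_s=420.0, seed=seed,
        rhythm=RhythmSpec(hr=hr),
        events={"injection_s": 60.0, "t_5min_s": 360.0},
    )


def _preset_amiodarone_qt(seed):
    # Post-immersion steady state: HR 60 bpm with QT 481 ms, QRS 79 ms,
    # PR 103 ms.
    return ScenarioSpec(
        name="amiodarone_qt", duration_s=120.0, seed=seed,
        rhythm=RhythmSpec(hr=Timecourse.constant(60.0),
                          pr_ms=Timecourse.constant(103.0),
                          qrs_ms=Timecourse.constant(79.0),
                          qt_ms=Timecourse.constant(481.0)),
    )


def _preset_quinidine_qt(seed):
    hr = Timecourse.step(60.0, 166.0, 92.0)
    qt = Timecourse.step(60.0, 200.0, 303.0)
    return ScenarioSpec(
        name="quinidine_qt", duration_s=180.0, seed=seed,
        rhythm=RhythmSpec(hr=hr, qt_ms=qt),
        events={"injection_s": 60.0},
    )


def _preset_veratridine_avblock(seed):
    pr = Timecourse.step(60.0, 58.0, 85.0)
    return ScenarioSpec(
        name="veratridine_avblock", duration_s=180.0, seed=seed,
        rhythm=RhythmSpec(hr=Timecourse.constant(148.0), pr_ms=pr),
        events={"injection_s": 60.0},
    )


_PRESETS = {
    "baseline_ab": _preset_baseline_ab,
    "baseline_rr469": _preset_baseline_rr469,
    "ms222_ramp": _preset_ms222_ramp,
    "isoproterenol_step": _preset_isoproterenol_step,
    "verapamil_step": _preset_verapamil_step,
    "amiodarone_qt": _preset_amiodarone_qt,
    "quinidine_qt": _preset_quinidine_qt,
    "veratridine_avblock": _preset_veratridine_avblock,
}


def list_presets() -> list:
    """Names of the built-in scenario presets."""
    return sorted(_PRESETS)


def preset(name: str, seed: int = 0, duration_s: Optional[float] = None,
           **kwargs) -> ScenarioSpec:
    """Return a fully populated :class:`ScenarioSpec` for a named scenario.

    ``duration_s`` overrides the preset's default duration; extra keyword
    arguments are preset-specific (e.g. ``dose_um`` for the isoproterenol
    ladder).
    """
    try:
        factory = _PRESETS[name]
    except KeyError:
        raise PresetError(
            f"unknown preset {name!r}; available: {', '.join(list_presets())}")
    spec = factory(seed, **kwargs)
    if duration_s is not None:
        spec = replace(spec, duration_s=float(duration_s))
    return spec
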