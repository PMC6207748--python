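# Methods

## Signal model

A recording is a uniformly sampled single-lead voltage trace in
millivolts. The default acquisition model matches the low-cost
recording kits used for adult zebrafish: 600 samples/s with an 80 Hz
digital low-pass; an AC-line filter may or may not be present upstream,
so mains handling is configurable throughout. Sample indices are
0-based; intervals are half-open, `duration_ms = (end − onset)·1000/fs`.

## Synthetic generator

The generator exists so that every analysis stage can be validated
against known ground truth. It is a descriptive waveform model, not a
biophysical (ionic) one.

**Beat morphology.** Each beat is a sum of Gaussians: P wave, a
triphasic Q–R–S complex, and a T wave. The fiducials are defined
analytically and consistently with the delineator's fractional
thresholds:

* QRS onset/offset are the 5% points of the R deflection:
  `σ_R = (QRS/2)/√(2 ln 20)`, onset at `r − QRS/2`, offset at
  `r + QRS/2`. Q and S are small narrow Gaussians at `r ∓ 0.3·QRS`
  (σ = 0.07·QRS); their tails at the 5% points are < 0.005 of the R
  amplitude, so they perturb the boundary definition negligibly.
* P onset/end are the 10% points of the P Gaussian
  (`σ_P = (p_width/2)/√(2 ln 10)`), with `p_onset = qrs_onset − PR`.
* T end is the 10% point of the T Gaussian, at `qrs_onset + QT` — QT is
  defined from the onset of ventricular depolarization to the end of
  repolarization.

Default amplitudes are R 1.0 mV, P 0.15 mV, T 0.25 mV, Q/S −0.15 mV
with P width 30 ms and T width 120 ms: small-amplitude P and T with a
dominant R, as in needle-electrode zebrafish traces. `polarity = −1`
negates the entire trace, modeling a reversed lead (e.g. an
over-inserted pectoral electrode).

**Rhythm.** Heart rate and the conduction intervals PR/QRS/QT are
piecewise time-courses (constant, hold/step, linear ramp). Beat times
advance by `RR = 60/hr(t)` plus Gaussian jitter (default SD 5 ms — a
modest within-recording variability; the ±15 bpm dispersions quoted for
cohorts are across fish, not within a sedated recording). Feasibility
(`PR + QT < RR`) is validated at every beat and violations raise,
naming the first offending time; nothing is clipped silently. A
`dropped_qrs_prob` parameter renders P-only beats (high-degree AV
block); those events go to a separate P-event list in the truth
channel.

**Noise.** Four additive sources, matching the dominant artifacts in
anesthetized-fish recordings: (1) gill-movement artifact — band-limited
1–3 Hz noise gated by randomly timed burst envelopes (default 0.5
bursts/s, 0.5–1.5 s long, 0.1 mV), since sedation does not abolish
opercular movement; (2) 60 Hz mains pickup (0.05 mV residual); (3)
slow baseline wander (0.2 Hz, 0.05 mV); (4) white sensor noise
(0.02 mV SD). The clean beat train is passed through the zero-phase
80 Hz acquisition low-pass, truth indices are recorded, then noise is
added and polarity applied. All randomness flows from one seed through
named child streams (Philox), so a scenario renders bit-identically and
sub-component changes cannot silently reorder draws.

**What the generator does not emulate:** perfusion-pulse artifact
beyond the generic wander term, electrode-contact drift/steps, ectopy
and morphology change within a segment, T-wave alternans, and any
pharmacokinetics (drug scenarios are programmed step/ramp time-courses,
not concentration models). Passing recovery tests therefore
demonstrates correctness of the measurement chain under realistic
stationary noise — not robustness to every artifact a live recording
can produce.

## Preprocessing

The band-pass is a Hamming windowed-sinc FIR, 3–45 Hz, order
`3·fs/f_low` rounded to even (601 taps at 600 SPS). It is applied as a
centered symmetric kernel on a reflect-padded signal — exactly zero
phase, so fiducial latencies are preserved (an isolated peak moves < 1
sample). The taps are mean-corrected to place an exact null at DC. The
single band-pass realizes the low-pass + high-pass conditioning stage
as one equivalent cascade. A zero-phase IIR notch (default 60 Hz,
Q = 30) is available and enabled by default for external raw
recordings; for simulator output the detection chain disables it (the
band-pass alone leaves a 60 Hz tone at −67 dB). The notch frequency is
configurable because mains differs by region and some kits already
filter the line frequency in hardware.

## Beat detection

A Pan-Tompkins/Hamilton-style detector: detection feature = centered
moving average (60 ms) of the squared first derivative of the
band-passed trace; candidate peaks at least one refractory period
apart; an adaptive threshold at 0.4 of a running exponential
signal-peak estimate; optional search-back at a lowered threshold for
long gaps. The refractory period is 150 ms, from physiology: at a
maximal plausible zebrafish heart rate (~250 bpm, RR 240 ms) it can
never mask a true beat but blocks T-wave double counting. Accepted
detections are refined to the local maximum of the polarity-corrected,
line-filtered raw trace within ±20 ms.

## Template averaging and delineation

Beats are windowed at `r ± halfwidth`; windows clipped by the record
edges are discarded. The pipeline widens the half-width to 60% of the
observed median RR (bounded 200–600 ms) so the window covers PR + QT
even at slow drug-induced rhythms. Each window is smoothed with a
centered 10-sample moving average and the windows are averaged into
the recording's reference wave; the unsmoothed ensemble mean is kept
alongside, because the moving average widens narrow deflections by a
known amount (~3 ms per QRS flank at these widths), which would bias
fractional-amplitude boundaries. At 600 SPS the 10-sample window spans
exactly one 60 Hz period, so the reference wave is also line-ripple
free.

Delineation runs on the template in two passes:

1. Rough pass: QRS onset/offset at the 5%-of-R crossings walking
   outward from R; P peak as the maximum left of QRS onset (within a
   150 ms search window, backed off 5 ms from the QRS so the upstroke
   cannot masquerade as P); T peak as the absolute extremum right of
   the QRS; P and T boundaries at 10% of each wave's amplitude. A
   crossing must stay sub-threshold for a hold time scaled to the wave
   (6 ms QRS, 8 ms P, 15 ms T) so brief zero crossings inside the
   complex, or noise dips on the slow T decay, cannot terminate the
   search early. Crossings are linearly interpolated to sub-sample
   positions.
2. Isoelectric correction: low-frequency artifact is not independent
   of beat phase (and R-peak refinement can phase-lock to residual
   interference), so a residual at the 0.01–0.03 mV level survives
   ensemble averaging — the same order as the 10% thresholds of the
   0.15–0.25 mV P and T waves. A piecewise-linear baseline through
   three quiet anchors (median over: the segment just before the P
   search window; the ST segment 8–28 ms after QRS offset; 25–45 ms
   after the rough T end) is subtracted and all fiducials are
   re-measured. On noise-free renders the anchors are ~0 and the
   correction is a no-op.

Waves whose amplitude is below 5% of R are reported absent, never
fabricated. Per-beat annotation projects the template offsets rigidly
from each refined R peak; only the P peak is re-refined per beat
(±10 ms, bounded). Boundary fiducials are deliberately not re-measured
on single noisy beats — a threshold crossing at 0.02 mV on one beat is
dominated by noise, and a rigid projection cannot move a fiducial
across waves. Consequently, per-beat PR/QRS/QT are template values (RR
and HR remain genuinely per-beat); recordings whose morphology changes
over time are analyzed segment-wise (`analyze_segments`), one template
per window, which is also how pre/post drug comparisons are computed.

## Intervals, QTc, summaries

The interval table is a pandas DataFrame, one row per beat, NaN for
unmeasurable entries. RR is taken to the previous R peak; each beat's
QTc uses that same preceding RR (summary QTc is the mean of per-beat
QTc, not QTc of the means — with template-projected QT and jittered RR
the two differ by well under a millisecond at the default jitter).
Fridericia's correction `QT/∛RR` (RR in seconds) is the default, as
recommended for drug-safety work; Bazett's `QT/√RR` is provided as a
labeled alternative only. Summaries report mean and sample SD (ddof=1)
per metric, matching the mean ± SD convention of cohort tables;
dispersion is omitted below two beats.

## Drug-effect analysis

`compare_pre_post` reduces each subject's window to its metric mean,
computes the per-subject fold `post/pre` (averaged across subjects) and
the signed percent change, and runs a two-sided paired Student t-test
implemented from its definition, with the p-value via the regularized
incomplete beta function `I_{ν/(ν+t²)}(ν/2, ½)` — self-contained and
cross-checked in the tests against an independent statistics library.
Zero-variance differences set a `no_variance` flag instead of a
fabricated statistic. `dose_response` tabulates per-dose fold changes
against log10 dose without fitting a curve. `classify_av_block` grades
conduction: high-degree when the dropped-QRS ratio (P events without a
QRS over all P events) exceeds 5%; first-degree when mean PR exceeds
the baseline reference mean + 3 SD with every P conducted; none
otherwise, with an `insufficient` evidence flag when PR is missing.
The 3-SD and 5% cutoffs are screening defaults — the classical grade
definitions are qualitative — and both are parameters.

## Scenario presets

Presets encode the study conditions the generator emulates; their
parameter values are the reference results for recovery testing.
Baseline: HR 148 bpm, PR 62 ms, QRS 44 ms, QT 215 ms. A separate
`baseline_rr469` preset programs mean RR 469 ms: cohort-mean HR and
cohort-mean RR are not reciprocal (averaging across fish does not
commute with 1/x), so both are exposed as distinct scenarios rather
than reconciled. Drug scenarios: `ms222_ramp` (HR 108→89 bpm over
minutes 1–5, →64 by minute 10), `isoproterenol_step` (pre 130 bpm —
the bradycardic state the drug is injected into — stepping by the
dose-ladder fold {0.5 µM: 1.04, 1: 1.12, 5: 1.14, 7.5: 1.22,
10: 1.25}), `verapamil_step` (155→116 bpm at injection, ramping to
88 bpm before the 5-minute mark and holding), `amiodarone_qt` (HR 60,
QT 481, QRS 79, PR 103 ms steady state after bath immersion),
`quinidine_qt` (HR 166→92, QT 200→303 ms), `veratridine_avblock`
(PR 58→85 ms, all else unchanged). Step presets place the injection at
t = 60 s and carry it in `ScenarioSpec.events`.

## Problem sizes and tolerances

Recovery tests render 120 s per recording (180–420 s for the step/ramp
scenarios) over ten seeds — roughly 300 beats per recording, enough
that template noise is dominated by the beat-locked residual rather
than by sampling error — and compare grand means against the
programmed values at ±2 bpm (HR), ±3–6 ms (intervals), ±1.5 points
(percent reductions) and ±0.02 (fold changes). Paired-test calibration
uses 1000 null replicates at n = 10. The full suite and the acceptance
script each run in well under a minute on one CPU.

## Known limitations

* Per-beat conduction intervals inherit the template; beat-to-beat
  PR/QT variability within a segment is not measured.
* The delineator assumes a single dominant-R morphology per segment;
  ectopic or multi-morphology recordings need segmentation or template
  clustering, which is out of scope.
* The AV-block classifier takes the P-only event list as input (from
  the truth channel or an external P detector); standalone detection of
  non-conducted P waves in noise is not implemented.
* Fractional-amplitude boundaries are threshold conventions; absolute
  interval values shift by a few ms under a different convention
  (e.g. tangent methods), though within-study contrasts do not.
* Only delimited-text formats are supported; vendor binary formats are
  not.
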