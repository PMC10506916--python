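# Methods

## Generative model of the cortical EMF

A recording is synthesised as

    x(t) = Σ_k a_k sin(2π f_k t + φ_k)  +  b(t)  +  w(t)

with narrowband circuit oscillations (`CircuitComponent`s), a
structured broadband background `b`, and white instrument noise `w`.
The analysis downstream consumes only amplitude-spectrum structure, so
this is the simplest model that can carry every feature the analysis
looks for; no biophysical dipole or volume-conduction modelling is
attempted.

**Background.** `b` is synthesised in the frequency domain with
*deterministic per-bin magnitudes and random phases*: the magnitude
profile is a shape-preserving (PCHIP) curve through control points
pinned to a pink envelope `L·sqrt(2Δf)·f^-α` (L = `pink_noise_level` in
pT/√Hz at 1 Hz, α = 0.5).  Valley notches pull the curve to
`(1−depth)` of the envelope at the printed valley frequencies;
components cap it at a pedestal fraction (0.35); away from the
structured region the curve is anchored to the envelope itself.
Because PCHIP is monotone between control points, the background has
local extrema only at configured frequencies — which is what makes the
detected peak/valley lists reproducible from session to session while
the waveform itself varies with the seed.  A plain 1/f background with
additive Gaussian dips was tried first and rejected: its inter-notch
"rebound" humps created spurious peaks, and minima on flat noise have
no stable location.

The background is built on the 0.05 Hz grid of the 20-s analysis bin
(`REFERENCE_BIN_S`) and continued periodically, so every line completes
an integer number of cycles inside *any* 20-s window: analysis bins
taken at arbitrary offsets see no background leakage.

**Amplitude scale.** The figure axes of the recordings this emulates
are unlabelled, so the absolute scale is free.  With the sensor floor
fixed at its datasheet value (1 pT/√Hz) a 1 pT dominant line would give
a bin SNR of ~4 and none of the weaker printed features could be
resolved; the default dominant amplitude is set to 600 pT so the
synthetic spectra are as cleanly structured as the printed ones.  The
10 V digitiser span with 0.1 mV/pT transduction and 10× gain places
that signal at roughly half of full scale (no clipping; clipping, when
induced, is reported as a fraction, never an error).

**Defaults.** Baseline components (Hz : pT): 2.5 : 600, 5.5 : 420,
6.7 : 300, 7.9 : 270, 8.8 : 240, 10.0 : 210, plus two weaker conserved
lines 10.5 : 180 and 3.9 : 40 that recur pre- and post-injury.
Baseline valleys: 1.8, 3.2, 5.2, 6.1, 7.4, 8.5, 9.5 Hz (notch depth
0.75, σ 0.12 Hz).  Non-target sensors (Bx, By, Bz) carry the same
structure at 0.5× amplitude; only B319 is analysed.

## Injury transform

`apply_injury` removes the baseline oscillations (attenuation 1.0 —
the printed post-injury peak list shares none of the six baseline
peaks), adds a more dispersed set of near-uniform components (3.9, 4.5,
6.4, 7.2, 8.2, 9.1, 10.5 Hz at 204–252 pT — near-uniformity is the
observed post-injury flattening of slope changes), replaces the valley
set (1.2, 3.6, 4.2, 4.8, 6.1, 6.7, 7.6, 8.9, 10.0 Hz), and installs a
flat shelf over [1.6, 5.55] Hz at 380 pT/√Hz.  A 1.6 Hz line at
exactly the shelf's per-bin level forms its leading edge.  Components
inside the shelf own their bins (the shelf skips them): a line stronger
than the shelf pokes through as a peak, a weaker one (the 3.9 Hz
conserved line once the baseline structure returns) shows as a
deterministic dip — without this, line and shelf phasors beat randomly
and the shelf is not flat.  A reported peak at 1.8 Hz inside the
plateau region is not modelled as a discrete line: a flat shelf and a
strict-local-maximum peak cannot coexist at the same frequency, and the
shelf edge is the 1.6 Hz feature.

## Scenario and recovery

The packaged immediate-stimulation scenario holds 12 pre-operative
sessions, one injured pre-stimulation session on postoperative day
(POD) 0, and daily post-stimulation sessions on POD 0–21.  Component
amplitudes and notch depths interpolate linearly between the injured
(weight 0) and baseline (weight 1) structures.  The weight ramps as
`0.75·d/C` and snaps to 1 at the convergence day `C` (default 10):
recovery is gradual but completes abruptly when the stimulated circuit
re-locks.  The ceiling of 0.75 keeps the residual injured peaks
resolvable on day C−1, so the detector cannot fire a day early.  The
shelf is not interpolated: it persists at full level until the valley
recovery day (default 17) and then vanishes.  This two-time-scale
recovery — oscillation pattern first, broadband shelf a week later —
is what makes peak patterns converge on POD 10 while valley patterns
converge only on POD 17: the shelf sits on top of the low-frequency
valleys (1.8, 3.2, 5.2 Hz) and erases them until it clears.

Stimulation entrainment is phenomenological: each session adds
`gain × reference` (default 0.25× the day's dominant amplitude) to the
component at the stimulation frequency.  The protocol schedule is two
sessions on POD 0 and one per day from POD 1, switching from 2.5 Hz to
5.5 Hz at session 12 (POD 10); "1 V" is taken as zero-to-peak, so the
phase-1 waveform spans −0.5 to +1.5 V around its +0.5 V offset.  The
source descriptions of the day↔session mapping are not fully mutually
consistent; the schedule follows the 11-sessions-by-POD-9 reading that
matches the day-10 convergence claim.

## Acquisition chain

The anti-alias filter is applied forward-backward (zero phase, so peak
locations cannot shift).  The design is elliptic, chosen to meet ≤1 %
passband deviation below 0.8× cutoff together with ≥40 dB stopband
attenuation above 1.25× cutoff after the two passes — a 4th-order
Butterworth, the obvious first choice, is 8 % down at 0.8× cutoff and
cannot meet that passband spec.  Quantization is ideal mid-tread:
codes = round(clip(g·x)/LSB), so in-range reconstruction error is ≤ ½
LSB by construction.  Bin selection scores the recording in 1-s
rolling-RMS windows normalised by the session median (threshold 3.0)
and tiles each clean stretch with consecutive non-overlapping 20-s
bins; "100,000 data points per bin" is the arithmetic 20 s × 5,000
samples/s.

## Spectral features

Amplitude spectra use a single full-bin FFT scaled so a unit sinusoid
at a grid frequency reads 1.0, smoothed by a **triangular** kernel of
0.3 Hz width.  A boxcar was rejected: it turns an isolated line into a
flat top whose argmax drifts with the local background tilt, moving
detected peaks off their true frequencies by one or two bins.  Peaks
are strict local maxima (flat-topped runs count once, at the centre)
with a prominence filter of 2 % of the band maximum to reject noise
grain; at prominence 0 the bare adjacent-amplitude definition applies,
and valleys are exactly peaks of the negated spectrum.  Frequencies are
reported on a 0.1 Hz grid.  The feature band defaults to 1–12 Hz
(every feature of interest lies below 11.5 Hz); the full 1 Hz–2 kHz
band remains available.

Plateau detection estimates slope by a centred difference over 0.3 Hz
on the smoothed spectrum and takes maximal runs with |slope| ≤ 3 pT/Hz
at least 1 Hz wide.  Two corrections matter: (i) smoothing and the
slope stencil blur a sharp edge outward, so the reported onset/end are
widened back by half the combined blur — this is why a shelf starting
at 1.6 Hz is reported at 1.6 rather than ~1.9; (ii) a run must also
sit at ≥10 % of the band maximum, because the noise floor between
well-separated peaks is flat but low, and only the *elevated* flat
shelf is an injury marker.  Slope-change variability is the sample SD
of successive differences of inter-extremum segment slopes (0 when
fewer than three segments); peak-spacing dispersion is the sample SD of
consecutive inter-peak intervals (0 for a single interval).

## Pattern analysis

The three similarity criteria are: tolerance-matched frequency sets
(greedy nearest-difference matching, each element used once, tolerance
0.2 Hz — one reporting-grid step each side — scored by Jaccard index);
interval signatures (inter-peak differences of the sorted list); and
sequence similarity (1 − normalised Levenshtein distance between
signatures quantized to 0.1 Hz, with tokens within one quantum counted
equal — exact token equality made ±0.1 Hz jitter read as a full edit).
The baseline reference is the tolerance-clustered union of all preop
sessions' features, with cluster centres snapped back to the 0.1 Hz
grid.  The peaks-mode score is the mean of peak Jaccard and
peak-interval similarity; valleys-mode likewise on valleys; the
combined score is the mean of peak Jaccard, valley Jaccard and
peak-interval similarity.  Sustained convergence returns the first day
from which every subsequent session stays at or above the threshold
(default 0.7; no numeric criterion exists in the source, so the
threshold is calibrated so the packaged scenario reproduces the
day-10/day-17 behaviour).  Greedy matching is verified against
exhaustive optimal matching in the tests.

## What the generator does and does not emulate

It emulates: the printed peak/valley lists and their session-to-session
jitter, the injury plateau, conserved cross-state frequencies (10.5 and
3.9 Hz — 10.5 Hz is the most frequently occurring peak across all
sessions because it alone is visible in every state), two-time-scale
recovery, movement artifacts, and the acquisition electronics.  It does
not emulate: inter-subject variability, day-to-day drift of peak
*frequencies* (only amplitudes/phases vary), non-stationarity within a
bin, mains interference, or any physical coupling of the stimulation
field to tissue (entrainment is imposed, not derived).  Passing tests
therefore show that the *analysis chain* recovers known structure and
known recovery days from realistic spectra; they are not evidence about
real cortical recordings.

## Numerical choices and sizes

Recordings for the scenario pipeline are 40 s (two candidate bins; the
first clean one is analysed).  The packaged scenario analyses 35
sessions; a full run takes a few seconds on one core.  Determinism:
per-session seeds derive arithmetically from the scenario seed, and
fixed (config, seed, sensor) triples give bit-identical samples.  Ties
in extremum detection (flat tops) resolve to the run centre.  Degenerate
inputs: empty component lists are valid (pure noise); recordings
shorter than one bin select no bins (not an error); empty scenarios
produce an empty report; two empty feature sets count as identical
(similarity 1).  The noise-calibration test compares the measured
amplitude spectral density near 1 Hz against the white and pink levels
combined in quadrature (independent noise adds in power).

## Known limitations

The valley-recovery mechanism (shelf persistence to day 17, then
clearance) is the simplest model consistent with the delayed valley
convergence, not a mechanism identified in the source system.  The
plateau detector's edge correction assumes sharp shelf edges; gradual
plateau boundaries would be reported slightly wide.  The pattern
threshold 0.7 and matching tolerance 0.2 Hz are calibrated instrument
settings — with very different generator configurations they would
need re-calibration.  NSE tables cover three animals; only signed
contrasts are computed, as inferential statistics on n = 3 would be
meaningless.
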