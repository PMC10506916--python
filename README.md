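# cortemf

Synthetic cortical electromagnetic-field (EMF) recordings, spectral
feature extraction, and stimulation-driven pattern-convergence analysis
for a swine model of traumatic brain injury (TBI).

## The problem

Non-contact induction sensors over a swine's skull record the magnetic
field generated by cortical circuits (picotesla scale, 1 Hz–2 kHz,
digitised at 5,000 samples/s through a 2 kHz low-pass filter and a 10×
gain stage into a 16-bit card).  In the experimental paradigm this
package models, a Yucatan minipig is recorded daily before a controlled
cortical impact (CCI), is injured, and then receives daily sinusoidal
EMF stimulation through the sensor over the lesion (B319): eleven
sessions of a 2.5 Hz, +500 mV offset, 1 V sine (two on the day of
surgery), then six sessions at 5.5 Hz.  The analysis operates on
20-second artifact-free bins (100,000 samples each), whose FFT amplitude
spectra carry the physiology: baseline peaks at 2.5, 5.5, 6.7, 7.9, 8.8
and 10 Hz, valleys between them, a post-injury plateau beginning at
1.6 Hz, and — under stimulation — a gradual return of the pre-operative
pattern, read out as the first postoperative day on which the daily
peak/valley patterns durably resemble baseline.

No animal recordings are distributed.  The package instead ships a
generator that synthesises multi-sensor recordings with exactly this
spectral structure, plus the full analysis chain, so every stage can be
exercised and tested end-to-end:

- **`cortemf.synth`** — sum-of-sinusoids generator over a structured
  pink background with carved valleys, injury transform (component
  collapse + flat shelf from 1.6 Hz), multi-day recovery scenarios,
  movement artifacts.
- **`cortemf.chain`** — acquisition electronics: zero-phase 2 kHz
  low-pass, 10× gain, 16-bit quantization, clean-bin selection.
- **`cortemf.spectral`** — amplitude spectra; peaks (strict local
  maxima), valleys, plateaus (near-flat elevated regions), slope-change
  variability, peak-spacing dispersion.
- **`cortemf.patterns`** — deterministic replacement for the study's
  pattern reading: tolerance-matched peak sets (Jaccard), inter-peak
  interval signatures (edit distance), occurrence counts, and sustained
  convergence detection.
- **`cortemf.stimwave`** — stimulation waveform x(t) = offset +
  A·sin(2πft) and the 17-session protocol schedule.
- **`cortemf.biomarkers`** — packaged neuron-specific enolase (NSE)
  serum/tissue tables and site contrasts.
- **`cortemf.pipeline` / CLI `cortemf`** — the end-to-end run.

## Worked example

```python
from cortemf import (default_baseline, default_injury, apply_injury,
                     generate_signal, amplitude_spectrum, extract_features)

rec = generate_signal(default_baseline(), duration=20.0, seed=1)
feats = extract_features(amplitude_spectrum(rec))
print([f for f, _ in feats.peaks])
# [2.5, 3.9, 5.5, 6.7, 7.9, 8.8, 10.0, 10.5]
print(feats.peaks[0])          # (2.5, 157.9...)  dominant 2.5 Hz peak
print(feats.plateaus)          # ()               healthy cortex: no plateau

injured = apply_injury(default_baseline(), default_injury())
feats2 = extract_features(amplitude_spectrum(generate_signal(injured, 20.0, seed=1)))
print(feats2.plateaus[0][0])   # 1.6              plateau onset (Hz)
print(feats2.peak_spacing_dispersion > feats.peak_spacing_dispersion)  # True
```

The first peak list reproduces the baseline spectrum: the six principal
oscillations with the dominant peak at 2.5 Hz and the second at 5.5 Hz,
plus the two weaker conserved lines at 3.9 and 10.5 Hz.  After the
injury transform the oscillation set is replaced by more dispersed,
near-uniform peaks and a flat shelf whose detected onset is 1.6 Hz.

The full study (12 pre-operative sessions, injury, 22 post-stimulation
days) runs from the shell:

```sh
cortemf run --seed 0 --out out/
# convergence: peaks day 10, valleys day 17; reports in out/
```

Day 10 is the first postoperative day from which the daily peak
patterns stay above the similarity threshold (sustained convergence);
the valley patterns recover a week later, on day 17, when the injury
shelf that suppresses the low-frequency valleys has cleared.

## Not in scope

Surgical/CCI mechanics, anesthesia, behaviour, histology image
analysis, real sensor hardware, and any language-model integration for
pattern reading (the `patterns` module is its deterministic
replacement).
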