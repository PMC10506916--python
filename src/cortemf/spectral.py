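"""Amplitude spectra and the spectral features of the analysis:
peaks, valleys, plateaus, slope-change variability and peak-spacing
dispersion.

A peak is a strict local maximum of the (optionally smoothed) amplitude
spectrum: the amplitude at a frequency whose adjacent amplitudes are
lower.  A valley is the mirror image.  A plateau is a contiguous region
of near-zero spectral slope.  All detected frequencies are reported on a
0.1 Hz grid, the precision at which such features are conventionally
quoted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from scipy.signal import find_peaks

from .chain import Bin
from .synth import RawRecording

ANALYSIS_BAND = (1.0, 12.0)  # every reported feature lies below 12 Hz
FULL_BAND = (1.0, 2000.0)
DEFAULT_SMOOTHING = 0.3  # Hz
DEFAULT_PROMINENCE = 0.02  # fraction of the band maximum
REPORT_GRID = 0.1  # Hz


@dataclass(frozen=True)
class AmplitudeSpectrum:
    """One-sided amplitude spectrum of a single analysis bin.

    Scaled so a unit-amplitude sinusoid at a grid frequency yields
    amplitude 1.  For a 20-s bin the grid resolution is 0.05 Hz.
    """

    frequencies: np.ndarray
    amplitudes: np.ndarray
    smoothing_width: float = 0.0

    def __post_init__(self) -> None:
        if len(self.frequencies) != len(self.amplitudes):
            raise ValueError("frequency and amplitude arrays differ in length")
        if len(self.frequencies) > 1:
            steps = np.diff(self.frequencies)
            if np.any(steps <= 0) or not np.allclose(steps, steps[0], rtol=1e-9):
                raise ValueError("frequency grid must be strictly increasing and uniform")
        if np.any(self.amplitudes < -1e-12):
            raise ValueError("amplitudes must be non-negative")

    @property
    def df(self) -> float:
        return float(self.frequencies[1] - self.frequencies[0]) if len(self.frequencies) > 1 else 0.0

    @property
    def band(self) -> tuple[float, float]:
        return float(self.frequencies[0]), float(self.frequencies[-1])

    def restrict(self, band: tuple[float, float]) -> "AmplitudeSpectrum":
        lo, hi = band
        sel = (self.frequencies >= lo - 1e-9) & (self.frequencies <= hi + 1e-9)
        return AmplitudeSpectrum(self.frequencies[sel], self.amplitudes[sel], self.smoothing_width)


@dataclass(frozen=True)
class SpectralFeatures:
    """Extracted features of one session/sensor spectrum."""

    peaks: tuple[tuple[float, float], ...]  # (frequency Hz, amplitude pT)
    valleys: tuple[tuple[float, float], ...]
    plateaus: tuple[tuple[float, float], ...] = ()  # (onset Hz, end Hz)
    slope_change_variability: float = 0.0
    peak_spacing_dispersion: float = 0.0
    warnings: tuple[str, ...] = ()

    def peak_frequencies(self) -> list[float]:
        return [f for f, _ in self.peaks]

    def valley_frequencies(self) -> list[float]:
        return [f for f, _ in self.valleys]


def amplitude_spectrum(
    data: Union[Bin, RawRecording],
    smoothing_width: float = DEFAULT_SMOOTHING,
    band: Optional[tuple[float, float]] = FULL_BAND,
) -> AmplitudeSpectrum:
    """FFT amplitude spectrum of a bin or recording.

    ``smoothing_width`` applies a triangular smoothing kernel of that
    total width in Hz (0 disables smoothing).  ``band`` restricts the output grid; pass
    ``None`` to keep everything from DC to Nyquist (needed e.g. to verify
    energy conservation).
    """
    x = np.asarray(data.samples, dtype=float)
    n = len(x)
    fs = data.sampling_rate
    amps = np.abs(np.fft.rfft(x)) * (2.0 / n)
    amps[0] /= 2.0
    if n % 2 == 0:
        amps[-1] /= 2.0
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    if smoothing_width > 0 and len(freqs) > 1:
        df = freqs[1] - freqs[0]
        size = max(1, int(round(smoothing_width / df)))
        if size % 2 == 0:
            size += 1
        if size > 1:
            # triangular kernel: tapered weights keep the maximum of an
            # isolated spectral line at the line's own bin, which a boxcar
            # (flat-topped after smoothing) does not guarantee
            half = size // 2
            kernel = 1.0 + half - np.abs(np.arange(size) - half)
            kernel /= kernel.sum()
            amps = np.convolve(np.pad(amps, half, mode="edge"), kernel, mode="valid")
    spec = AmplitudeSpectrum(freqs, amps, smoothing_width)
    if band is not None:
        spec = spec.restrict(band)
    return spec


def _snap(freq: float, grid: float) -> float:
    return round(round(freq / grid) * grid, 6)


def _extrema(
    y: np.ndarray,
    freqs: np.ndarray,
    prominence: float,
    report_grid: float,
    amplitudes: np.ndarray,
) -> list[tuple[float, float]]:
    kwargs = {"plateau_size": (1, None)}
    if prominence > 0:
        kwargs["prominence"] = prominence
    idx, props = find_peaks(y, **kwargs)
    centres = (props["left_edges"] + props["right_edges"]) // 2
    found: dict[float, float] = {}
    for i in centres:
        f = _snap(float(freqs[i]), report_grid)
        a = float(amplitudes[i])
        if f not in found or a > found[f]:
            found[f] = a
    return sorted(found.items())


def detect_peaks(
    spectrum: AmplitudeSpectrum,
    band: Optional[tuple[float, float]] = None,
    min_prominence: float = DEFAULT_PROMINENCE,
    report_grid: float = REPORT_GRID,
) -> list[tuple[float, float]]:
    """Strict local maxima of the amplitude spectrum.

    ``min_prominence`` is a fraction of the band's maximum amplitude used
    to suppress noise-grain extrema; at 0 the bare adjacent-amplitude
    definition applies.  Flat-topped runs count as a single peak at the
    run's centre.  Frequencies are snapped to ``report_grid``.
    """
    sub = spectrum if band is None else spectrum.restrict(band)
    if len(sub.frequencies) == 0:
        raise ValueError("empty frequency band")
    y = sub.amplitudes
    thr = min_prominence * float(np.max(y)) if len(y) else 0.0
    return _extrema(y, sub.frequencies, thr, report_grid, y)


def detect_valleys(
    spectrum: AmplitudeSpectrum,
    band: Optional[tuple[float, float]] = None,
    min_prominence: float = DEFAULT_PROMINENCE,
    report_grid: float = REPORT_GRID,
) -> list[tuple[float, float]]:
    """Strict local minima: the peak definition applied to the negated
    spectrum, with prominence measured on the same amplitude scale and the
    original (positive) amplitude reported."""
    sub = spectrum if band is None else spectrum.restrict(band)
    if len(sub.frequencies) == 0:
        raise ValueError("empty frequency band")
    y = sub.amplitudes
    thr = min_prominence * float(np.max(y)) if len(y) else 0.0
    return _extrema(-y, sub.frequencies, thr, report_grid, y)


def detect_plateau(
    spectrum: AmplitudeSpectrum,
    slope_tolerance: float = 3.0,
    min_width: float = 1.0,
    slope_window: float = 0.3,
    edge_correction: Optional[float] = None,
    min_level_frac: float = 0.1,
    report_grid: float = REPORT_GRID,
) -> list[tuple[float, float]]:
    """Maximal near-flat elevated regions of the spectrum.

    The local slope is estimated by a centred difference over
    ``slope_window`` Hz; maximal runs where |slope| <= ``slope_tolerance``
    (pT/Hz) and the run is at least ``min_width`` Hz wide are reported as
    (onset, end).  A run must additionally sit at or above
    ``min_level_frac`` of the spectrum's maximum: an injury shelf is an
    *elevated* flat region, whereas the noise floor between well-separated
    peaks is flat but low (set the fraction to 0 for the bare slope
    criterion).

    Because both the smoothing of the spectrum and the slope stencil blur
    a sharp plateau edge outward, the reported onset and end are widened
    by half the combined blur; ``edge_correction`` defaults to the
    spectrum's recorded smoothing width.

    Returns an empty list when nothing qualifies.
    """
    freqs = spectrum.frequencies
    y = spectrum.amplitudes
    if len(freqs) < 5:
        return []
    df = spectrum.df
    if edge_correction is None:
        edge_correction = spectrum.smoothing_width
    h = max(1, int(round(slope_window / (2.0 * df))))
    slope = np.full(len(y), np.inf)
    slope[h:-h] = (y[2 * h :] - y[: -2 * h]) / (2.0 * h * df)
    flat = np.abs(slope) <= slope_tolerance
    blur = h * df + edge_correction / 2.0
    level_floor = min_level_frac * float(np.max(y))
    out: list[tuple[float, float]] = []
    i = 0
    while i < len(flat):
        if not flat[i]:
            i += 1
            continue
        j = i
        while j < len(flat) and flat[j]:
            j += 1
        raw_width = float(freqs[j - 1] - freqs[i])
        # the stencil eats h bins off each true edge; credit those back
        if raw_width + 2 * h * df >= min_width and float(np.mean(y[i:j])) >= level_floor:
            onset = max(float(freqs[i]) - blur, float(freqs[0]))
            end = min(float(freqs[j - 1]) + blur, float(freqs[-1]))
            out.append((_snap(onset, report_grid), _snap(end, report_grid)))
        i = j
    return out


def slope_change_variability(features: SpectralFeatures) -> float:
    """Spread of the successive differences of inter-extremum slopes.

    Consecutive extrema (peaks and valleys merged by frequency) define
    line segments; the statistic is the sample standard deviation of the
    differences between consecutive segment slopes.  Fewer than three
    segments give 0 (flagged via the features' warning mechanism by the
    extraction routine).
    """
    pts = sorted(list(features.peaks) + list(features.valleys))
    return _slope_change_sd(pts)


def _slope_change_sd(points: Sequence[tuple[float, float]]) -> float:
    # a peak and valley can snap to the same reporting-grid frequency;
    # keep one point per frequency so segment slopes stay finite
    dedup: dict[float, float] = {}
    for freq, amp in points:
        dedup.setdefault(freq, amp)
    points = sorted(dedup.items())
    if len(points) < 4:
        return 0.0
    f = np.array([p[0] for p in points])
    a = np.array([p[1] for p in points])
    slopes = np.diff(a) / np.diff(f)
    changes = np.diff(slopes)
    if len(changes) < 2:
        return 0.0
    return float(np.std(changes, ddof=1))


def peak_spacing_dispersion(peaks: Sequence[Union[float, tuple[float, float]]]) -> float:
    """Sample standard deviation of consecutive inter-peak intervals.

    A single interval (two peaks) gives 0; fewer than two peaks is
    undefined and returns 0 with a warning.
    """
    freqs = sorted(p[0] if isinstance(p, tuple) else float(p) for p in peaks)
    if len(freqs) < 2:
        warnings.warn("peak_spacing_dispersion undefined for fewer than two peaks")
        return 0.0
    intervals = np.diff(freqs)
    if len(intervals) < 2:
        return 0.0
    return float(np.std(intervals, ddof=1))


def extract_features(
    spectrum: AmplitudeSpectrum,
    band: tuple[float, float] = ANALYSIS_BAND,
    min_prominence: float = DEFAULT_PROMINENCE,
    report_grid: float = REPORT_GRID,
    slope_tolerance: float = 3.0,
    plateau_min_width: float = 1.0,
) -> SpectralFeatures:
    """Full feature set of one spectrum over the analysis band."""
    peaks = tuple(detect_peaks(spectrum, band, min_prominence, report_grid))
    valleys = tuple(detect_valleys(spectrum, band, min_prominence, report_grid))
    plateaus = tuple(
        (on, end)
        for on, end in detect_plateau(
            spectrum.restrict(band), slope_tolerance, plateau_min_width, report_grid=report_grid
        )
    )
    warns = []
    if len(peaks) + len(valleys) < 3:
        warns.append("fewer than three extrema; slope-change variability set to 0")
    if len(peaks) < 2:
        warns.append("fewer than two peaks; spacing dispersion set to 0")
    feats = SpectralFeatures(
        peaks=peaks,
        valleys=valleys,
        plateaus=plateaus,
        warnings=tuple(warns),
    )
    scv = slope_change_variability(feats)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        psd = peak_spacing_dispersion(peaks)
    return SpectralFeatures(
        peaks=peaks,
        valleys=valleys,
        plateaus=plateaus,
        slope_change_variability=scv,
        peak_spacing_dispersion=psd,
        warnings=tuple(warns),
    )
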