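"""Acquisition-chain emulation: anti-alias low-pass filter, gain and
16-bit quantization, and selection of clean 20-s analysis bins.

The recording protocol this models digitises each sensor at 5,000
samples/s through a 2 kHz low-pass filter and a 10x gain stage into a
16-bit card, then analyses 20-second bins (100,000 samples at the default
rate) during which the subject held still.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy import signal

from .synth import RawRecording


@dataclass(frozen=True)
class AcquisitionSettings:
    """Front-end electronics parameters.

    ``volts_per_picotesla`` is the sensor transduction applied before the
    gain stage; the default 0.1 mV/pT puts the packaged synthetic signals
    (a few thousand pT peak) comfortably inside the +-5 V full scale
    after 10x gain.
    """

    lowpass_cutoff: float = 2000.0  # Hz
    gain: float = 10.0
    bit_depth: int = 16
    full_scale: float = 5.0  # V at the digitiser input
    sampling_rate: float = 5000.0
    volts_per_picotesla: float = 1e-4

    def __post_init__(self) -> None:
        if self.lowpass_cutoff > self.sampling_rate / 2.0:
            raise ValueError(
                f"low-pass cutoff {self.lowpass_cutoff} Hz exceeds the Nyquist "
                f"frequency {self.sampling_rate / 2.0} Hz"
            )
        if self.gain <= 0:
            raise ValueError("gain must be > 0")
        if not 8 <= self.bit_depth <= 24:
            raise ValueError("bit_depth must be within [8, 24]")
        if self.full_scale <= 0:
            raise ValueError("full_scale must be > 0")

    @property
    def lsb(self) -> float:
        """Least significant bit in volts."""
        return 2.0 * self.full_scale / 2**self.bit_depth


@dataclass(frozen=True)
class QuantizedRecording:
    """Integer codes plus the scale needed to reconstruct amplitudes."""

    sensor_id: str
    sampling_rate: float
    codes: np.ndarray  # int32
    lsb: float  # V per code
    gain: float
    volts_per_picotesla: float
    clipped_fraction: float
    seed: int
    config_digest: str = ""

    def reconstruct(self) -> RawRecording:
        """Undo quantization, gain and transduction back to picotesla."""
        x = self.codes.astype(float) * self.lsb / (self.gain * self.volts_per_picotesla)
        return RawRecording(
            sensor_id=self.sensor_id,
            sampling_rate=self.sampling_rate,
            samples=x,
            seed=self.seed,
            config_digest=self.config_digest,
        )


@dataclass(frozen=True)
class Bin:
    """One clean, fixed-length analysis window of a recording."""

    sensor_id: str
    start_time: float
    sampling_rate: float
    samples: np.ndarray
    motion_score: float

    @property
    def length(self) -> float:
        return len(self.samples) / self.sampling_rate


def _lowpass_sos(cutoff: float, sampling_rate: float):
    """Elliptic low-pass meeting, after forward-backward application,
    <=1 % passband deviation below 0.8x cutoff and >=40 dB attenuation
    above 1.25x cutoff (where that band exists below Nyquist)."""
    nyq = sampling_rate / 2.0
    wp = 0.8 * cutoff / nyq
    ws = min(1.25 * cutoff, 0.999 * nyq) / nyq
    # single-pass budget: half the ripple, half the (dB) attenuation
    order, wn = signal.ellipord(wp, ws, gpass=0.0435, gstop=20.0)
    return signal.ellip(order, 0.0435, 20.0, wn, btype="low", output="sos")


def lowpass_filter(recording: RawRecording, settings: AcquisitionSettings) -> RawRecording:
    """Zero-phase (forward-backward) anti-alias filter.

    Zero-phase application preserves the location of spectral peaks; the
    elliptic design keeps the passband flat to within 1 % below 0.8x the
    cutoff while attenuating the stopband by at least 40 dB.
    """
    if settings.lowpass_cutoff > recording.sampling_rate / 2.0:
        raise ValueError("cutoff above Nyquist for this recording")
    sos = _lowpass_sos(settings.lowpass_cutoff, recording.sampling_rate)
    y = signal.sosfiltfilt(sos, recording.samples)
    return replace(recording, samples=y)


def gain_and_quantize(recording: RawRecording, settings: AcquisitionSettings) -> QuantizedRecording:
    """Apply transduction, gain and ideal mid-tread quantization.

    Codes are ``round(clip(g * x, +-FS) / LSB)`` so the reconstruction
    error of every in-range sample is at most half an LSB.  Clipping is
    never an error; the clipped fraction is reported on the result.
    """
    v = recording.samples * settings.volts_per_picotesla * settings.gain
    clipped = np.abs(v) > settings.full_scale
    v = np.clip(v, -settings.full_scale, settings.full_scale)
    codes = np.round(v / settings.lsb).astype(np.int32)
    return QuantizedRecording(
        sensor_id=recording.sensor_id,
        sampling_rate=recording.sampling_rate,
        codes=codes,
        lsb=settings.lsb,
        gain=settings.gain,
        volts_per_picotesla=settings.volts_per_picotesla,
        clipped_fraction=float(np.mean(clipped)),
        seed=recording.seed,
        config_digest=recording.config_digest,
    )


def motion_profile(recording: RawRecording, window: float = 1.0) -> np.ndarray:
    """Per-second rolling-RMS excess over the session median RMS.

    Values near 1 indicate a still subject; movement artifacts inflate the
    local RMS well above the median.
    """
    fs = recording.sampling_rate
    n_win = int(round(window * fs))
    n = len(recording.samples) // n_win
    if n == 0:
        return np.empty(0)
    seg = recording.samples[: n * n_win].reshape(n, n_win)
    rms = np.sqrt(np.mean(seg**2, axis=1))
    med = np.median(rms)
    if med == 0:
        return np.ones_like(rms)
    return rms / med


def select_bins(
    recording: RawRecording,
    bin_length: float = 20.0,
    motion_threshold: float = 3.0,
    motion_window: float = 1.0,
) -> list[Bin]:
    """Extract consecutive non-overlapping clean bins.

    The recording is scored in 1-s windows (rolling RMS normalised by the
    session median); maximal stretches of windows below
    ``motion_threshold`` are tiled with consecutive ``bin_length``-second
    bins starting at each stretch's beginning.  A recording shorter than
    one bin yields an empty list.
    """
    fs = recording.sampling_rate
    n_bin = int(round(bin_length * fs))
    if len(recording.samples) < n_bin:
        return []
    profile = motion_profile(recording, motion_window)
    clean = profile < motion_threshold
    n_win = int(round(motion_window * fs))
    bins: list[Bin] = []
    i = 0
    while i < len(clean):
        if not clean[i]:
            i += 1
            continue
        j = i
        while j < len(clean) and clean[j]:
            j += 1
        # tile the clean stretch [i, j) with consecutive bins
        start = i
        wins_per_bin = int(round(bin_length / motion_window))
        while start + wins_per_bin <= j:
            s0 = start * n_win
            samples = recording.samples[s0 : s0 + n_bin]
            if len(samples) == n_bin:
                bins.append(
                    Bin(
                        sensor_id=recording.sensor_id,
                        start_time=s0 / fs,
                        sampling_rate=fs,
                        samples=samples,
                        motion_score=float(np.max(profile[start : start + wins_per_bin])),
                    )
                )
            start += wins_per_bin
        i = j
    return bins
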