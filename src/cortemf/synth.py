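"""Synthetic cortical electromagnetic-field (EMF) generator.

Produces multi-sensor magnetometer time series whose 20-s amplitude
spectra carry the structure the downstream analysis looks for: a set of
narrowband oscillatory components (spectral peaks), carved valleys on a
smooth pink broadband background, a post-injury flat "shelf" (plateau)
starting at a configurable onset frequency, and a multi-day scenario that
interpolates from the injured structure back toward baseline.

The generative model is a sum of sinusoids plus structured pink noise
plus white sensor noise.  The pink background is synthesised with
deterministic per-bin magnitudes and random phases so that the *shape*
of the amplitude spectrum (and hence peak/valley locations) is stable
across sessions while the waveform itself differs per seed.

Units: amplitudes in picotesla (pT), frequencies in Hz, noise densities
in pT/sqrt(Hz).
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

SENSOR_IDS = ("B319", "Bx", "By", "Bz")

#: Analysis-bin length (s) on whose frequency grid the structured
#: background is synthesised; 20 s gives the 0.05 Hz reference grid.
REFERENCE_BIN_S = 20.0

#: Amplitude scaling applied to the non-target parietal/frontal sensors.
#: Only B319 (over the lesion) is analysed; the others merely exist.
OFF_TARGET_GAIN = 0.5

_GOLDEN = 2.0 * math.pi * (math.sqrt(5.0) - 1.0) / 2.0


def _golden_phase(k: int) -> float:
    """Deterministic low-discrepancy phase for the k-th component."""
    return (k * _GOLDEN) % (2.0 * math.pi)


@dataclass(frozen=True)
class CircuitComponent:
    """One narrowband oscillation of a cortical circuit."""

    frequency: float  # Hz
    amplitude: float  # pT (zero-to-peak sinusoid amplitude)
    phase: float = 0.0  # rad

    def __post_init__(self) -> None:
        if not self.frequency > 0:
            raise ValueError(f"component frequency must be > 0, got {self.frequency}")
        if self.amplitude < 0:
            raise ValueError(f"component amplitude must be >= 0, got {self.amplitude}")


@dataclass(frozen=True)
class SpectralNotch:
    """A carved valley in the broadband background at a fixed frequency.

    ``depth`` is the fractional attenuation of the background at the notch
    centre (0 = no notch, 1 = background fully suppressed); ``width`` is the
    Gaussian sigma in Hz.
    """

    frequency: float
    depth: float = 0.75
    width: float = 0.12

    def __post_init__(self) -> None:
        if not 0.0 <= self.depth <= 1.0:
            raise ValueError("notch depth must be in [0, 1]")
        if self.width <= 0:
            raise ValueError("notch width must be > 0")


@dataclass(frozen=True)
class Plateau:
    """Flat elevated noise shelf over [onset, onset + span].

    ``level`` is the shelf amplitude spectral density in pT/sqrt(Hz); at the
    reference 0.05 Hz bin width of a 20-s window this corresponds to a
    per-bin amplitude of ``level * sqrt(2 * 0.05)``.
    """

    onset: float = 1.6
    span: float = 3.95
    level: float = 380.0

    def __post_init__(self) -> None:
        if self.span < 0 or self.level < 0:
            raise ValueError("plateau span and level must be >= 0")


@dataclass(frozen=True)
class BaselineConfig:
    """Generator configuration for one cortical state.

    components
        Narrowband oscillations, sorted by frequency, unique within 0.05 Hz.
    pink_noise_level
        Background amplitude spectral density at 1 Hz (pT/sqrt(Hz)).  The
        background magnitude falls off as ``f ** -pink_exponent`` and is
        confined to ``background_band``.
    sensor_noise_floor
        White instrument noise density (pT/sqrt(Hz)); the sensors used to
        motivate this model are specified at 1 pT/sqrt(Hz) at 1 Hz.
    valley_notches
        Deterministic dips carved into the background; these fix where the
        amplitude-spectrum valleys fall.
    plateau
        Optional injured-state shelf (None for a healthy baseline).
    """

    components: tuple[CircuitComponent, ...] = ()
    pink_noise_level: float = 114.0
    pink_exponent: float = 0.5
    sensor_noise_floor: float = 1.0
    background_band: tuple[float, float] = (0.5, 14.0)
    valley_notches: tuple[SpectralNotch, ...] = ()
    plateau: Optional[Plateau] = None

    def __post_init__(self) -> None:
        if self.pink_noise_level < 0 or self.sensor_noise_floor < 0:
            raise ValueError("noise levels must be >= 0")
        freqs = [c.frequency for c in self.components]
        if freqs != sorted(freqs):
            raise ValueError("components must be sorted by frequency")
        if any(b - a < 0.05 for a, b in zip(freqs, freqs[1:])):
            raise ValueError("component frequencies must be unique within 0.05 Hz")

    def digest(self) -> str:
        """Stable hash of the configuration, recorded in every recording."""
        payload = json.dumps(
            {
                "components": [(c.frequency, c.amplitude, round(c.phase, 12)) for c in self.components],
                "pink": (self.pink_noise_level, self.pink_exponent),
                "white": self.sensor_noise_floor,
                "band": self.background_band,
                "notches": [(n.frequency, n.depth, n.width) for n in self.valley_notches],
                "plateau": None
                if self.plateau is None
                else (self.plateau.onset, self.plateau.span, self.plateau.level),
            },
            sort_keys=True,
        )
        return hashlib.sha1(payload.encode()).hexdigest()[:16]

    def max_component_frequency(self) -> float:
        return max((c.frequency for c in self.components), default=0.0)


@dataclass(frozen=True)
class InjuryConfig:
    """Transformation of a baseline configuration into the post-impact state.

    attenuation
        Fraction of each baseline component amplitude removed (1.0 = the
        pre-injury oscillations disappear entirely).
    broadening
        Spectral broadening (Hz) applied to surviving components: each is
        split into a triplet at f - b, f, f + b carrying 25/50/25 % of the
        amplitude.
    added_components
        New oscillations of the injured circuit (the default set includes a
        1.6 Hz line that forms the leading edge of the plateau).
    plateau_onset / plateau_span / plateau_level
        Flat shelf parameters; onset defaults to 1.6 Hz.
    valley_notches
        Valley positions of the injured background, replacing the baseline
        set.
    """

    plateau_onset: float = 1.6
    plateau_span: float = 3.95
    plateau_level: float = 380.0
    attenuation: float = 1.0
    broadening: float = 0.2
    added_components: tuple[CircuitComponent, ...] = ()
    valley_notches: tuple[SpectralNotch, ...] = ()

    def __post_init__(self) -> None:
        if not 0.0 <= self.attenuation <= 1.0:
            raise ValueError("attenuation must be in [0, 1]")
        if self.plateau_onset <= 0:
            raise ValueError("plateau onset must be positive")


@dataclass(frozen=True)
class RawRecording:
    """One sensor's time series plus provenance."""

    sensor_id: str
    sampling_rate: float
    samples: np.ndarray
    seed: int
    config_digest: str = ""

    def __post_init__(self) -> None:
        if self.sensor_id not in SENSOR_IDS:
            raise ValueError(f"unknown sensor_id {self.sensor_id!r}; expected one of {SENSOR_IDS}")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sampling_rate


# ---------------------------------------------------------------------------
# default study configurations
# ---------------------------------------------------------------------------

_BASELINE_LINES = (
    (2.5, 600.0),
    (3.9, 40.0),  # conserved minor line, shared with the injured circuit
    (5.5, 420.0),
    (6.7, 300.0),
    (7.9, 270.0),
    (8.8, 240.0),
    (10.0, 210.0),
    (10.5, 180.0),
)

_BASELINE_VALLEYS = (1.8, 3.2, 5.2, 6.1, 7.4, 8.5, 9.5)

# Injured-circuit oscillations: near-uniform amplitudes (the injured spectrum
# shows smaller, more evenly sized peaks spread over more frequencies).
_INJURED_LINES = (
    (1.6, 120.0),  # leading edge of the plateau shelf
    (3.9, 210.0),
    (4.5, 252.0),
    (6.4, 240.0),
    (7.2, 228.0),
    (8.2, 216.0),
    (9.1, 204.0),
    (10.5, 180.0),
)

_INJURED_VALLEYS = (1.2, 3.6, 4.2, 4.8, 6.1, 6.7, 7.6, 8.9, 10.0)


def default_baseline() -> BaselineConfig:
    """Pre-injury configuration.

    The component set carries the six prominent baseline peaks (2.5, 5.5,
    6.7, 7.9, 8.8 and 10 Hz, with 2.5 Hz dominant) plus two weaker lines at
    3.9 and 10.5 Hz that recur in both the pre-operative and post-stimulation
    record.  Valleys are carved at 1.8, 3.2, 5.2, 6.1, 7.4, 8.5 and 9.5 Hz.
    """
    comps = tuple(
        CircuitComponent(f, a, _golden_phase(k)) for k, (f, a) in enumerate(_BASELINE_LINES)
    )
    notches = tuple(SpectralNotch(f) for f in _BASELINE_VALLEYS)
    return BaselineConfig(components=comps, valley_notches=notches)


def default_injury() -> InjuryConfig:
    """Post-impact transformation: baseline oscillations collapse, a flat
    shelf appears from 1.6 Hz, and a new, more dispersed set of peaks with
    near-uniform amplitudes emerges."""
    added = tuple(
        CircuitComponent(f, a, _golden_phase(100 + k)) for k, (f, a) in enumerate(_INJURED_LINES)
    )
    notches = tuple(SpectralNotch(f) for f in _INJURED_VALLEYS)
    return InjuryConfig(added_components=added, valley_notches=notches)


# ---------------------------------------------------------------------------
# signal synthesis
# ---------------------------------------------------------------------------

#: Broadband pedestal under each oscillation, as a fraction of the pink
#: envelope at that frequency.
PEDESTAL_FRAC = 0.35
#: Envelope fraction at the upper edge of the background band.
EDGE_FRAC = 0.25


def _background_magnitudes(config: BaselineConfig, freqs: np.ndarray, df: float) -> np.ndarray:
    """Deterministic per-bin background magnitude (pT per bin).

    The broadband background is a shape-preserving (PCHIP) curve through
    control points pinned to the pink envelope
    ``pink_noise_level * sqrt(2 df) * f**-exponent``: valley notches pull
    it down to ``(1 - depth)`` of the envelope, components cap it at a
    pedestal fraction.  Monotone interpolation guarantees the background
    has local extrema only at these control frequencies, so the spectrum's
    peaks and valleys fall exactly where the configuration says.
    """
    from scipy.interpolate import PchipInterpolator

    lo, hi = config.background_band
    mag = np.zeros_like(freqs)
    in_band = (freqs >= lo) & (freqs <= hi)
    f = freqs[in_band]
    if f.size and config.pink_noise_level > 0:
        def envelope(x: float) -> float:
            return config.pink_noise_level * math.sqrt(2.0 * df) * x ** (-config.pink_exponent)

        factors: dict[float, float] = {round(lo, 6): 1.0, round(hi, 6): EDGE_FRAC}
        features: list[float] = []
        for notch in config.valley_notches:
            if lo < notch.frequency < hi:
                key = round(notch.frequency, 6)
                factors[key] = factors.get(key, 1.0) * (1.0 - notch.depth)
                features.append(notch.frequency)
        for comp in config.components:
            if lo < comp.frequency < hi and comp.amplitude > 0:
                key = round(comp.frequency, 6)
                factors[key] = min(factors.get(key, 1.0), PEDESTAL_FRAC)
                features.append(comp.frequency)
        # anchor the curve to the pink envelope away from the structured
        # region, so sparse control points cannot pull it off 1/f shape
        f_lo = min(features) - 0.5 if features else lo
        f_hi = max(features) + 0.5 if features else lo
        for anchor in np.geomspace(lo, hi, 16):
            if anchor <= f_lo or anchor >= f_hi:
                key = round(float(anchor), 6)
                if all(abs(key - x) > 0.2 for x in factors):
                    factors[key] = 1.0
        xs = sorted(factors)
        ys = [factors[x] * envelope(max(x, 1e-6)) for x in xs]
        mag[in_band] = np.clip(PchipInterpolator(xs, ys)(f), 0.0, None)
    plateau = config.plateau
    if plateau is not None and plateau.level > 0 and plateau.span > 0:
        shelf_bin = plateau.level * math.sqrt(2.0 * df)
        sel = (freqs >= plateau.onset - 1e-9) & (freqs <= plateau.onset + plateau.span + 1e-9)
        # components own their bins: the shelf fills every other bin of the
        # span, so a line never beats against a same-bin shelf phasor (a
        # line weaker than the shelf shows as a deterministic dip instead)
        for comp in config.components:
            if plateau.onset <= comp.frequency <= plateau.onset + plateau.span:
                if comp.amplitude > 0:
                    sel &= np.abs(freqs - comp.frequency) > 0.5 * df
        mag[sel] = np.maximum(mag[sel], shelf_bin)
    return mag


def generate_signal(
    config: BaselineConfig,
    duration: float,
    sampling_rate: float = 5000.0,
    seed: int = 0,
    sensor_id: str = "B319",
) -> RawRecording:
    """Synthesise one sensor recording.

    The output is ``sum_k a_k sin(2 pi f_k t + phi_k)`` plus the structured
    pink background plus white sensor noise, bit-identical for a fixed
    (config, seed, sensor) triple.

    Raises
    ------
    ValueError
        If a component frequency is at or above the Nyquist frequency.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    nyquist = sampling_rate / 2.0
    fmax = config.max_component_frequency()
    if fmax >= nyquist:
        raise ValueError(
            f"component frequency {fmax} Hz is not below the Nyquist frequency "
            f"{nyquist} Hz at {sampling_rate} samples/s"
        )
    n = int(round(duration * sampling_rate))
    t = np.arange(n) / sampling_rate
    gain = 1.0 if sensor_id == "B319" else OFF_TARGET_GAIN

    x = np.zeros(n)
    for comp in config.components:
        if comp.amplitude:
            x += (gain * comp.amplitude) * np.sin(2.0 * math.pi * comp.frequency * t + comp.phase)

    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, _sensor_code(sensor_id)]))
    # The structured background is synthesised on the analysis-bin grid
    # (1 / REFERENCE_BIN_S = 0.05 Hz) and continued periodically: every
    # background line then completes an integer number of cycles inside
    # any 20-s analysis window, so bins taken at arbitrary offsets see no
    # spectral leakage from the background.
    n_ref = int(round(REFERENCE_BIN_S * sampling_rate))
    df_ref = 1.0 / REFERENCE_BIN_S
    freqs_ref = np.fft.rfftfreq(n_ref, d=1.0 / sampling_rate)
    mag = _background_magnitudes(config, freqs_ref, df_ref) * gain
    if np.any(mag > 0):
        phases = rng.uniform(0.0, 2.0 * math.pi, freqs_ref.size)
        block = np.fft.irfft((mag * (n_ref / 2.0)) * np.exp(1j * phases), n_ref)
        reps = -(-n // n_ref)  # ceil
        x += np.tile(block, reps)[:n]
    if config.sensor_noise_floor > 0:
        x += rng.normal(0.0, config.sensor_noise_floor * math.sqrt(nyquist), n)

    return RawRecording(
        sensor_id=sensor_id,
        sampling_rate=sampling_rate,
        samples=x,
        seed=seed,
        config_digest=config.digest(),
    )


def _sensor_code(sensor_id: str) -> int:
    return SENSOR_IDS.index(sensor_id) + 1


# ---------------------------------------------------------------------------
# injury and scenario evolution
# ---------------------------------------------------------------------------

def apply_injury(config: BaselineConfig, injury: InjuryConfig) -> BaselineConfig:
    """Return the generator configuration of the injured cortex.

    Baseline components are attenuated by ``injury.attenuation`` (and
    broadened if any survive), the injured oscillation set is added, the
    valley notches are replaced by the injured set, and the plateau shelf is
    installed over [onset, onset + span].
    """
    surviving: list[CircuitComponent] = []
    for comp in config.components:
        a = comp.amplitude * (1.0 - injury.attenuation)
        if a <= 0:
            continue
        b = injury.broadening
        if b > 0:
            surviving.extend(
                [
                    CircuitComponent(comp.frequency - b, 0.25 * a, comp.phase),
                    CircuitComponent(comp.frequency, 0.5 * a, comp.phase),
                    CircuitComponent(comp.frequency + b, 0.25 * a, comp.phase),
                ]
            )
        else:
            surviving.append(CircuitComponent(comp.frequency, a, comp.phase))
    merged = _merge_components(surviving + list(injury.added_components))
    plateau = None
    if injury.plateau_span > 0 and injury.plateau_level > 0:
        plateau = Plateau(injury.plateau_onset, injury.plateau_span, injury.plateau_level)
    notches = injury.valley_notches if injury.valley_notches else config.valley_notches
    if injury.attenuation == 0 and injury.broadening == 0 and not injury.added_components \
            and plateau is None and not injury.valley_notches:
        return config
    return replace(config, components=merged, valley_notches=notches, plateau=plateau)


def _merge_components(comps: Sequence[CircuitComponent], tol: float = 0.049) -> tuple[CircuitComponent, ...]:
    """Sort by frequency and coalesce components closer than ``tol`` Hz."""
    out: list[CircuitComponent] = []
    for comp in sorted(comps, key=lambda c: c.frequency):
        if out and comp.frequency - out[-1].frequency < tol:
            prev = out[-1]
            out[-1] = CircuitComponent(prev.frequency, prev.amplitude + comp.amplitude, prev.phase)
        else:
            out.append(comp)
    return tuple(out)


PHASES = ("preop", "post_cci", "pre_stim", "post_stim")


@dataclass(frozen=True)
class DayPlan:
    """One scheduled session of the study."""

    day_index: int  # postoperative day for post-injury phases, study day for preop
    phase_label: str
    mixture_weight: float  # 1 = baseline structure, 0 = fully injured

    def __post_init__(self) -> None:
        if self.phase_label not in PHASES:
            raise ValueError(f"unknown phase label {self.phase_label!r}")
        if not 0.0 <= self.mixture_weight <= 1.0:
            raise ValueError("mixture_weight must be in [0, 1]")


@dataclass(frozen=True)
class Scenario:
    """Multi-day study trajectory: baseline -> injury -> convergence.

    ``days`` lists every session in study order.  After stimulation begins,
    ``mixture_weight`` rises monotonically and reaches a value at or above
    the pattern-analysis convergence threshold exactly at
    ``convergence_day`` (counted in postoperative days).  The plateau shelf
    persists until ``valley_recovery_day``, which is what delays the
    recovery of the low-frequency valleys relative to the peaks.
    """

    days: tuple[DayPlan, ...]
    convergence_day: int = 10
    valley_recovery_day: int = 17
    seed: int = 0
    weight_cap: float = 0.75  # pre-convergence ceiling of the ramp

    def __post_init__(self) -> None:
        post = [d for d in self.days if d.phase_label == "post_stim"]
        if post:
            pods = [d.day_index for d in post]
            if pods != sorted(pods):
                raise ValueError("post-stimulation days must be ordered")
            weights = [d.mixture_weight for d in post]
            if any(b < a - 1e-12 for a, b in zip(weights, weights[1:])):
                raise ValueError("mixture_weight must be non-decreasing after stimulation onset")
            if not any(d.day_index >= self.convergence_day for d in post):
                raise ValueError("convergence_day lies outside the post-stimulation day range")

    def preop_days(self) -> tuple[DayPlan, ...]:
        return tuple(d for d in self.days if d.phase_label == "preop")

    def post_stim_days(self) -> tuple[DayPlan, ...]:
        return tuple(d for d in self.days if d.phase_label == "post_stim")


def default_scenario(
    seed: int = 0,
    convergence_day: int = 10,
    valley_recovery_day: int = 17,
    n_preop: int = 12,
    last_post_day: int = 21,
) -> Scenario:
    """The packaged immediate-stimulation study.

    Twelve pre-operative sessions, one injured pre-stimulation session on
    postoperative day 0, and daily post-stimulation sessions on
    postoperative days 0..21.  The mixture weight climbs linearly to a
    ceiling of 0.75 and snaps to 1 at the convergence day: recovery is
    gradual but completes abruptly once the stimulated circuit re-locks.
    """
    days = [DayPlan(d, "preop", 1.0) for d in range(n_preop)]
    days.append(DayPlan(0, "post_cci", 0.0))
    for d in range(last_post_day + 1):
        w = 1.0 if d >= convergence_day else 0.75 * d / convergence_day
        days.append(DayPlan(d, "post_stim", w))
    return Scenario(
        days=tuple(days),
        convergence_day=convergence_day,
        valley_recovery_day=valley_recovery_day,
        seed=seed,
    )


def mixture_config(
    baseline: BaselineConfig,
    injured: BaselineConfig,
    weight: float,
    shelf_on: bool = True,
) -> BaselineConfig:
    """Interpolate component amplitudes and notch depths between the injured
    (weight 0) and baseline (weight 1) structures.

    The plateau shelf is not interpolated: it is either fully present or
    absent (``shelf_on``), reflecting that the injured noise shelf persists
    until late recovery rather than fading with the oscillatory pattern.
    """
    if not 0.0 <= weight <= 1.0:
        raise ValueError("weight must be in [0, 1]")
    by_freq: dict[float, list] = {}
    for comp in baseline.components:
        by_freq.setdefault(round(comp.frequency, 3), [0.0, 0.0, comp.phase])[0] = comp.amplitude
    for comp in injured.components:
        entry = by_freq.setdefault(round(comp.frequency, 3), [0.0, 0.0, comp.phase])
        entry[1] = comp.amplitude
    comps = []
    for f in sorted(by_freq):
        a_base, a_inj, phase = by_freq[f]
        a = weight * a_base + (1.0 - weight) * a_inj
        if a > 0:
            comps.append(CircuitComponent(f, a, phase))
    notches = [
        SpectralNotch(n.frequency, n.depth * weight, n.width)
        for n in baseline.valley_notches
        if n.depth * weight > 0
    ] + [
        SpectralNotch(n.frequency, n.depth * (1.0 - weight), n.width)
        for n in injured.valley_notches
        if n.depth * (1.0 - weight) > 0
    ]
    notches.sort(key=lambda n: n.frequency)
    plateau = injured.plateau if (shelf_on and injured.plateau is not None) else None
    return replace(
        baseline,
        components=_merge_components(comps),
        valley_notches=tuple(notches),
        plateau=plateau,
    )


def evolve_scenario(
    scenario: Scenario,
    baseline: Optional[BaselineConfig] = None,
    injury: Optional[InjuryConfig] = None,
) -> list[tuple[DayPlan, BaselineConfig]]:
    """Per-session generator configurations for a scenario.

    Pre-operative sessions use the baseline configuration; post-injury
    sessions use the mixture at that day's weight, with the plateau shelf
    active until ``scenario.valley_recovery_day``.
    """
    baseline = default_baseline() if baseline is None else baseline
    injury = default_injury() if injury is None else injury
    injured = apply_injury(baseline, injury)
    out = []
    for plan in scenario.days:
        if plan.phase_label == "preop":
            out.append((plan, baseline))
            continue
        shelf_on = plan.day_index < scenario.valley_recovery_day
        out.append((plan, mixture_config(baseline, injured, plan.mixture_weight, shelf_on)))
    return out


def session_seed(scenario_seed: int, phase_label: str, day_index: int) -> int:
    """Deterministic per-session seed below 2**31."""
    code = PHASES.index(phase_label) + 1
    return (scenario_seed * 1000003 + code * 9176 + day_index * 37) % (2**31 - 1)


# ---------------------------------------------------------------------------
# movement artifacts
# ---------------------------------------------------------------------------

def add_artifacts(
    recording: RawRecording,
    artifact_times: Sequence[float],
    artifact_scale: float = 50.0,
    burst_duration: float = 1.0,
    require_clean_bin: bool = True,
    bin_length: float = 20.0,
) -> RawRecording:
    """Insert movement-artifact bursts (windowed noise) at the given times.

    Each burst is a Tukey-windowed white-noise transient of RMS
    ``artifact_scale`` times the clean-recording RMS.  With
    ``require_clean_bin`` set, the schedule must leave at least one
    artifact-free stretch of ``bin_length`` seconds.

    Raises
    ------
    ValueError
        If an artifact time falls outside the recording, or the guard flag
        is set and no clean bin would remain.
    """
    from scipy.signal import windows

    if not artifact_times:
        return recording
    fs = recording.sampling_rate
    duration = recording.duration
    for t0 in artifact_times:
        if not 0.0 <= t0 <= duration:
            raise ValueError(f"artifact time {t0} s outside recording of {duration} s")
    if require_clean_bin:
        edges = sorted([0.0] + [float(t) for t in artifact_times] + [duration])
        margin = burst_duration
        gaps = [(b - margin) - (a + margin) for a, b in zip(edges[:-1], edges[1:])]
        if max(gaps) < bin_length:
            raise ValueError(
                f"artifact schedule leaves no clean {bin_length}-s stretch"
            )
    x = recording.samples.copy()
    clean_rms = float(np.sqrt(np.mean(x**2))) or 1.0
    n_burst = int(round(burst_duration * fs))
    win = windows.tukey(n_burst, alpha=0.5)
    rng = np.random.default_rng(np.random.SeedSequence([recording.seed & 0x7FFFFFFF, 0x5EED]))
    for t0 in artifact_times:
        i0 = int(round(t0 * fs))
        i1 = min(i0 + n_burst, len(x))
        burst = rng.normal(0.0, artifact_scale * clean_rms, i1 - i0) * win[: i1 - i0]
        x[i0:i1] += burst
    return replace(recording, samples=x)
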