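"""Stimulation waveform and 17-session protocol schedule.

The stimulation signal is a DC-offset sinusoid delivered through the
sensor over the lesion (B319): phase 1 runs 2.5 Hz with a +500 mV offset
at 1 V amplitude for three minutes per session, twice on the day of
surgery and then once daily, 11 sessions in total; phase 2 switches the
frequency to 5.5 Hz for the remaining six sessions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .synth import BaselineConfig, CircuitComponent, _merge_components

PHASE1_FREQ = 2.5  # Hz
PHASE2_FREQ = 5.5  # Hz
OFFSET_MV = 500.0
AMPLITUDE_V = 1.0  # zero-to-peak
SESSION_DURATION_S = 180.0  # "three minutes"
N_PHASE1_SESSIONS = 11
N_SESSIONS = 17
TARGET_SENSOR = "B319"


@dataclass(frozen=True)
class StimulationSettings:
    """Signal-generator settings for one session."""

    frequency: float = PHASE1_FREQ  # Hz
    offset: float = OFFSET_MV  # mV
    amplitude: float = AMPLITUDE_V  # V, zero-to-peak
    duration: float = SESSION_DURATION_S  # s

    def __post_init__(self) -> None:
        if self.frequency <= 0:
            raise ValueError("frequency must be > 0")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")


@dataclass(frozen=True)
class ProtocolSession:
    """One entry of the 17-session stimulation schedule."""

    session_index: int  # 1..17
    day_index: int  # postoperative day
    settings: StimulationSettings
    target_sensor: str = TARGET_SENSOR

    def __post_init__(self) -> None:
        if not 1 <= self.session_index <= N_SESSIONS:
            raise ValueError("session_index must be within 1..17")
        if self.target_sensor != TARGET_SENSOR:
            raise ValueError(f"stimulation is delivered through {TARGET_SENSOR}")


def make_waveform(settings: StimulationSettings, sampling_rate: float = 1000.0) -> np.ndarray:
    """Sampled stimulation waveform in volts.

    x(t) = offset + amplitude * sin(2 pi f t); over any integer number of
    cycles the time average equals the offset exactly (to float
    precision).
    """
    if sampling_rate < 2.0 * settings.frequency:
        raise ValueError(
            f"sampling rate {sampling_rate} S/s is below twice the stimulation "
            f"frequency {settings.frequency} Hz"
        )
    n = int(round(settings.duration * sampling_rate))
    t = np.arange(n) / sampling_rate
    return settings.offset / 1000.0 + settings.amplitude * np.sin(
        2.0 * math.pi * settings.frequency * t
    )


def protocol_schedule() -> list[ProtocolSession]:
    """The full 17-session schedule.

    Sessions 1 and 2 both fall on postoperative day 0 (two trials while
    anesthetised); sessions 3 onward run once per day from day 1.  The
    first 11 sessions use the 2.5 Hz settings, the remaining six 5.5 Hz.
    """
    sessions = []
    for s in range(1, N_SESSIONS + 1):
        freq = PHASE1_FREQ if s <= N_PHASE1_SESSIONS else PHASE2_FREQ
        day = 0 if s <= 2 else s - 2
        sessions.append(ProtocolSession(s, day, StimulationSettings(frequency=freq)))
    return sessions


def apply_stimulation_day(
    day_config: BaselineConfig,
    session: ProtocolSession,
    entrainment_gain: float = 0.25,
    reference: float | None = None,
) -> BaselineConfig:
    """Phenomenological entrainment: boost (or create) the spectral
    component at the session's stimulation frequency.

    The boost is ``entrainment_gain`` times ``reference`` -- by default
    the configuration's largest component amplitude.  The boost adds to
    whatever is already at the stimulation frequency, so for a fixed
    reference entrainment is additive and order-independent across
    distinct stimulation frequencies (callers applying several sessions
    to one day should therefore pass the day's reference explicitly).
    """
    if entrainment_gain < 0:
        raise ValueError("entrainment_gain must be >= 0")
    if entrainment_gain == 0:
        return day_config
    if reference is None:
        reference = max((c.amplitude for c in day_config.components), default=1.0)
    boost = entrainment_gain * reference
    f_stim = session.settings.frequency
    comps = list(day_config.components)
    for i, comp in enumerate(comps):
        if abs(comp.frequency - f_stim) <= 0.049:
            comps[i] = CircuitComponent(comp.frequency, comp.amplitude + boost, comp.phase)
            break
    else:
        comps.append(CircuitComponent(f_stim, boost, 0.0))
    from dataclasses import replace

    return replace(day_config, components=_merge_components(comps))
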