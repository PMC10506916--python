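"""File formats: columnar recordings, feature tables, and JSON reports.

Recordings are written as plain-text columnar files with ``# key: value``
header lines followed by one amplitude per row.  Features travel as a
CSV table with one row per peak/valley/plateau, the exchange format
between the spectral and pattern stages.  Reports and manifests are
JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .chain import Bin
from .spectral import SpectralFeatures
from .synth import RawRecording

FORMAT_VERSION = "1"
FEATURE_KINDS = ("peak", "valley", "plateau")


class ParseError(ValueError):
    """Malformed file; the message names the offending line."""


# ---------------------------------------------------------------------------
# recordings
# ---------------------------------------------------------------------------

def write_recording(path: Union[str, Path], recording: Union[RawRecording, Bin]) -> None:
    path = Path(path)
    header = {
        "format_version": FORMAT_VERSION,
        "sensor_id": recording.sensor_id,
        "sampling_rate": repr(float(recording.sampling_rate)),
    }
    if isinstance(recording, RawRecording):
        header["seed"] = str(recording.seed)
        header["config_digest"] = recording.config_digest
    else:
        header["start_time"] = repr(float(recording.start_time))
        header["motion_score"] = repr(float(recording.motion_score))
    with path.open("w") as fh:
        for key, value in header.items():
            fh.write(f"# {key}: {value}\n")
        np.savetxt(fh, recording.samples, fmt="%.17g")


def read_recording(path: Union[str, Path]) -> Union[RawRecording, Bin]:
    path = Path(path)
    header: dict[str, str] = {}
    data_start = 0
    with path.open() as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.startswith("#"):
                data_start = lineno
                break
            try:
                key, value = line[1:].split(":", 1)
            except ValueError:
                raise ParseError(f"{path}:{lineno}: malformed header line {line!r}")
            header[key.strip()] = value.strip()
    for required in ("format_version", "sensor_id", "sampling_rate"):
        if required not in header:
            raise ParseError(f"{path}:{data_start or 1}: missing header field {required!r}")
    samples = np.loadtxt(path, comments="#", ndmin=1)
    if "start_time" in header:
        return Bin(
            sensor_id=header["sensor_id"],
            start_time=float(header["start_time"]),
            sampling_rate=float(header["sampling_rate"]),
            samples=samples,
            motion_score=float(header.get("motion_score", 0.0)),
        )
    return RawRecording(
        sensor_id=header["sensor_id"],
        sampling_rate=float(header["sampling_rate"]),
        samples=samples,
        seed=int(header.get("seed", 0)),
        config_digest=header.get("config_digest", ""),
    )


# ---------------------------------------------------------------------------
# feature tables
# ---------------------------------------------------------------------------

def features_to_frame(
    session: str, sensor: str, features: SpectralFeatures
) -> pd.DataFrame:
    """One row per feature: columns session, sensor, kind, frequency_hz,
    amplitude, extra (plateau end frequency; empty otherwise)."""
    rows = []
    for f, a in features.peaks:
        rows.append((session, sensor, "peak", f, a, ""))
    for f, a in features.valleys:
        rows.append((session, sensor, "valley", f, a, ""))
    for onset, end in features.plateaus:
        rows.append((session, sensor, "plateau", onset, np.nan, repr(end)))
    return pd.DataFrame(
        rows, columns=["session", "sensor", "kind", "frequency_hz", "amplitude", "extra"]
    )


def write_features(path: Union[str, Path], frame: pd.DataFrame) -> None:
    bad = set(frame["kind"]) - set(FEATURE_KINDS)
    if bad:
        raise ValueError(f"unknown feature kind(s) {sorted(bad)}")
    frame.to_csv(path, index=False)


def read_features(path: Union[str, Path]) -> pd.DataFrame:
    frame = pd.read_csv(path, keep_default_na=True)
    expected = ["session", "sensor", "kind", "frequency_hz", "amplitude", "extra"]
    if list(frame.columns) != expected:
        raise ParseError(f"{path}:1: expected columns {expected}, found {list(frame.columns)}")
    bad = set(frame["kind"]) - set(FEATURE_KINDS)
    if bad:
        first = frame.index[frame["kind"].isin(bad)][0] + 2  # header + 1-based
        raise ParseError(f"{path}:{first}: unknown feature kind(s) {sorted(bad)}")
    return frame


def frame_to_features(frame: pd.DataFrame) -> SpectralFeatures:
    """Rebuild a SpectralFeatures object from (one session's) table rows."""
    peaks = tuple(
        (float(r.frequency_hz), float(r.amplitude))
        for r in frame[frame["kind"] == "peak"].itertuples()
    )
    valleys = tuple(
        (float(r.frequency_hz), float(r.amplitude))
        for r in frame[frame["kind"] == "valley"].itertuples()
    )
    plateaus = tuple(
        (float(r.frequency_hz), float(r.extra))
        for r in frame[frame["kind"] == "plateau"].itertuples()
    )
    return SpectralFeatures(peaks=peaks, valleys=valleys, plateaus=plateaus)


# ---------------------------------------------------------------------------
# generator configurations and scenarios (JSON)
# ---------------------------------------------------------------------------

def config_to_dict(config) -> dict:
    """JSON-ready form of a BaselineConfig (frequencies in Hz, amplitudes
    in pT, noise densities in pT/sqrt(Hz))."""
    return {
        "components": [
            {"frequency_hz": c.frequency, "amplitude_pt": c.amplitude, "phase_rad": c.phase}
            for c in config.components
        ],
        "pink_noise_level": config.pink_noise_level,
        "pink_exponent": config.pink_exponent,
        "sensor_noise_floor": config.sensor_noise_floor,
        "background_band_hz": list(config.background_band),
        "valley_notches": [
            {"frequency_hz": n.frequency, "depth": n.depth, "width_hz": n.width}
            for n in config.valley_notches
        ],
        "plateau": None
        if config.plateau is None
        else {
            "onset_hz": config.plateau.onset,
            "span_hz": config.plateau.span,
            "level_pt_rthz": config.plateau.level,
        },
    }


def config_from_dict(payload: dict):
    from .synth import BaselineConfig, CircuitComponent, Plateau, SpectralNotch

    plateau = payload.get("plateau")
    return BaselineConfig(
        components=tuple(
            CircuitComponent(c["frequency_hz"], c["amplitude_pt"], c.get("phase_rad", 0.0))
            for c in payload.get("components", [])
        ),
        pink_noise_level=payload.get("pink_noise_level", 0.0),
        pink_exponent=payload.get("pink_exponent", 0.5),
        sensor_noise_floor=payload.get("sensor_noise_floor", 0.0),
        background_band=tuple(payload.get("background_band_hz", (0.5, 14.0))),
        valley_notches=tuple(
            SpectralNotch(n["frequency_hz"], n.get("depth", 0.75), n.get("width_hz", 0.12))
            for n in payload.get("valley_notches", [])
        ),
        plateau=None
        if plateau is None
        else Plateau(plateau["onset_hz"], plateau["span_hz"], plateau["level_pt_rthz"]),
    )


def scenario_to_dict(scenario) -> dict:
    return {
        "days": [
            {"day_index": d.day_index, "phase_label": d.phase_label, "mixture_weight": d.mixture_weight}
            for d in scenario.days
        ],
        "convergence_day": scenario.convergence_day,
        "valley_recovery_day": scenario.valley_recovery_day,
        "seed": scenario.seed,
    }


def scenario_from_dict(payload: dict):
    from .synth import DayPlan, Scenario

    return Scenario(
        days=tuple(
            DayPlan(d["day_index"], d["phase_label"], d["mixture_weight"])
            for d in payload["days"]
        ),
        convergence_day=payload.get("convergence_day", 10),
        valley_recovery_day=payload.get("valley_recovery_day", 17),
        seed=payload.get("seed", 0),
    )


def write_config(path: Union[str, Path], obj) -> None:
    from .synth import Scenario

    payload = scenario_to_dict(obj) if isinstance(obj, Scenario) else config_to_dict(obj)
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_config(path: Union[str, Path]):
    payload = json.loads(Path(path).read_text())
    if "days" in payload:
        return scenario_from_dict(payload)
    return config_from_dict(payload)


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

def write_report(path: Union[str, Path], report: dict) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")


def read_report(path: Union[str, Path]) -> dict:
    try:
        return json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}:{exc.lineno}: {exc.msg}") from exc
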