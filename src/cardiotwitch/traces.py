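"""Containers and plain-text I/O for sarcomere-length traces and striation image stacks.

A recording is either a directly measured sarcomere-length time series
(:class:`SarcomereLengthTrace`) or a stack of 1-D optical-intensity line
profiles (:class:`IntensityFrameStack`) from which the length trace is
recovered by spectral periodicity analysis (:mod:`cardiotwitch.tracking`).
Traces travel as a CSV file (``time_s``, ``sarcomere_length_um``) with a JSON
sidecar holding stimulus times, sampling metadata and, for synthetic data,
ground truth — so downstream analysis is agnostic to whether a trace came
straight from the generator or through the tracking stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SarcomereLengthTrace",
    "IntensityFrameStack",
    "read_trace",
    "write_trace",
    "read_stack",
    "write_stack",
]


@dataclass
class SarcomereLengthTrace:
    """Per-cell sarcomere length vs. time, with pacing stimulus timestamps.

    Attributes
    ----------
    time
        Sample times in seconds, strictly increasing at ``1/sample_rate``.
    sl
        Sarcomere length in µm per sample. ``nan`` marks samples the tracker
        flagged as unreliable (never silently interpolated).
    stimulus_times
        Field-stimulus onset times in seconds.
    sample_rate
        Acquisition rate in Hz (240 Hz in the reference protocol).
    quality
        Optional per-sample confidence (spectral peak prominence for tracked
        traces; ``None`` for directly simulated ones).
    """

    time: np.ndarray
    sl: np.ndarray
    stimulus_times: np.ndarray
    sample_rate: float
    quality: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.sl = np.asarray(self.sl, dtype=float)
        self.stimulus_times = np.asarray(self.stimulus_times, dtype=float)
        if self.time.shape != self.sl.shape:
            raise ValueError("time and sl must have the same length")
        if self.time.size >= 2 and np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0]) + 1.0 / self.sample_rate


@dataclass
class IntensityFrameStack:
    """Stack of 1-D optical-intensity profiles along a myocyte ROI.

    ``frames[i, j]`` is the intensity of frame ``i`` at position
    ``j * pixel_pitch`` µm. The bright/dark striation pattern encodes the
    Z-band spacing; ≥ 8 sarcomere periods per profile are required for a
    usable spectral estimate.
    """

    frames: np.ndarray
    pixel_pitch: float  # µm per pixel
    frame_rate: float  # Hz
    stimulus_times: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.frames = np.atleast_2d(np.asarray(self.frames, dtype=float))
        self.stimulus_times = np.asarray(self.stimulus_times, dtype=float)
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be positive")

    @property
    def roi_length(self) -> float:
        """Physical profile length in µm."""
        return self.frames.shape[1] * self.pixel_pitch

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


def write_trace(trace: SarcomereLengthTrace, csv_path: str | Path, extra: dict | None = None) -> Path:
    """Write a trace as CSV plus a JSON sidecar (``<stem>.json``).

    ``extra`` is merged into the sidecar — the generator stores concentration
    periods and ground truth there.
    """
    csv_path = Path(csv_path)
    pd.DataFrame({"time_s": trace.time, "sarcomere_length_um": trace.sl}).to_csv(
        csv_path, index=False, float_format="%.6f"
    )
    sidecar = {
        "sample_rate_hz": trace.sample_rate,
        "stimulus_times_s": [round(float(t), 9) for t in trace.stimulus_times],
    }
    if trace.quality is not None:
        sidecar["quality"] = [round(float(q), 4) for q in trace.quality]
    if extra:
        sidecar.update(extra)
    sidecar_path = csv_path.with_suffix(".json")
    sidecar_path.write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    return sidecar_path


def read_trace(csv_path: str | Path) -> tuple[SarcomereLengthTrace, dict]:
    """Read a trace CSV + sidecar; returns ``(trace, sidecar_dict)``."""
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    sidecar = json.loads(csv_path.with_suffix(".json").read_text())
    quality = np.asarray(sidecar["quality"]) if "quality" in sidecar else None
    trace = SarcomereLengthTrace(
        time=df["time_s"].to_numpy(),
        sl=df["sarcomere_length_um"].to_numpy(),
        stimulus_times=np.asarray(sidecar.get("stimulus_times_s", [])),
        sample_rate=float(sidecar["sample_rate_hz"]),
        quality=quality,
    )
    return trace, sidecar


def write_stack(stack: IntensityFrameStack, matrix_path: str | Path) -> Path:
    """Write frames as a whitespace-delimited dense matrix (rows = frames) plus JSON header."""
    matrix_path = Path(matrix_path)
    np.savetxt(matrix_path, stack.frames, fmt="%.5f")
    header = {
        "pixel_pitch_um": stack.pixel_pitch,
        "frame_rate_hz": stack.frame_rate,
        "stimulus_times_s": [round(float(t), 9) for t in stack.stimulus_times],
        "n_frames": int(stack.n_frames),
    }
    header_path = matrix_path.with_suffix(".json")
    header_path.write_text(json.dumps(header, indent=1, sort_keys=True))
    return header_path


def read_stack(matrix_path: str | Path) -> IntensityFrameStack:
    matrix_path = Path(matrix_path)
    header = json.loads(matrix_path.with_suffix(".json").read_text())
    frames = np.loadtxt(matrix_path)
    return IntensityFrameStack(
        frames=frames,
        pixel_pitch=float(header["pixel_pitch_um"]),
        frame_rate=float(header["frame_rate_hz"]),
        stimulus_times=np.asarray(header.get("stimulus_times_s", [])),
    )
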