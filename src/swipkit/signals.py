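"""Core time-series containers shared across the pipeline.

Two objects flow through every stage: the per-animal joint-angle series
(tracker output / generator intermediate) and the per-animal swim-frequency
trace, the central object of the kinetic analysis.  Both are thin dataclasses
around numpy arrays with the CSV dialects the pipeline exchanges on disk:

* trace CSV:  header ``time_s,frequency_hz``
* angle CSV:  header ``time_s,joint1_rad,joint2_rad,joint3_rad``

Ground-truth traces written by the generator and traces estimated from angle
series use the same dialect and are interchangeable downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "AngleSeries",
    "FrequencyTrace",
    "read_angles",
    "read_trace",
    "write_angles",
    "write_trace",
]


@dataclass
class FrequencyTrace:
    """Swim frequency (Hz) versus time for one animal.

    Parameters
    ----------
    times
        Sample times in seconds, strictly increasing.  These are frame times
        for ground-truth / extrema traces and window centers for FFT traces.
    frequency
        Non-negative frequency in Hz, one value per time point.
    method
        Provenance tag: ``"ground_truth"``, ``"fft"`` or ``"extrema"``.
    meta
        Free-form quality metadata (e.g. inter-method discrepancy,
        low-confidence window flags, smoothing window applied).
    """

    times: np.ndarray
    frequency: np.ndarray
    method: str = "ground_truth"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.frequency = np.asarray(self.frequency, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.frequency.shape:
            raise ValueError("times and frequency must be 1-d arrays of equal length")
        if self.times.size == 0:
            raise ValueError("empty trace")
        if not np.all(np.isfinite(self.times)) or not np.all(np.isfinite(self.frequency)):
            raise ValueError("trace contains non-finite values")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.frequency < 0):
            raise ValueError("frequency must be non-negative")

    @property
    def dt(self) -> float:
        """Median sample spacing in seconds (1.0 for a single-point trace)."""
        if self.times.size < 2:
            return 1.0
        return float(np.median(np.diff(self.times)))

    @property
    def duration(self) -> float:
        """Continuous-time span covered by the trace.

        Each sample is taken to represent one sample period, so the span is
        ``last - first + dt``; a 600-point trace on a 1 s grid covers 600 s.
        """
        return float(self.times[-1] - self.times[0] + self.dt)


@dataclass
class AngleSeries:
    """Three joint-angle signals (radians) on a uniform frame grid."""

    times: np.ndarray
    angles: np.ndarray  # (n_frames, 3)
    frame_rate: float
    phase: np.ndarray | None = None  # generator oscillation phase, cycles
    degenerate: bool = False  # zero-amplitude (flat) series

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.angles = np.asarray(self.angles, dtype=float)
        if self.angles.ndim != 2 or self.angles.shape[1] != 3:
            raise ValueError("angles must have shape (n_frames, 3)")
        if self.times.shape[0] != self.angles.shape[0]:
            raise ValueError("times and angles must have matching length")
        if not np.all(np.isfinite(self.angles)):
            raise ValueError("angles contain non-finite values")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.times.size > 1:
            spacing = np.diff(self.times)
            # atol admits the 1e-6 rounding of CSV-round-tripped times
            if not np.allclose(spacing, 1.0 / self.frame_rate, rtol=1e-6, atol=2e-6):
                raise ValueError("times must lie on a uniform 1/frame_rate grid")

    @property
    def n_frames(self) -> int:
        return int(self.times.size)

    @property
    def nyquist(self) -> float:
        return self.frame_rate / 2.0


# CSV round trips use a fixed float format so that regenerating a cohort with
# the same seed produces byte-identical files.
_FLOAT_FMT = "%.6f"


def write_trace(trace: FrequencyTrace, path: str | Path) -> None:
    df = pd.DataFrame({"time_s": trace.times, "frequency_hz": trace.frequency})
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_trace(path: str | Path, method: str = "ground_truth") -> FrequencyTrace:
    df = pd.read_csv(path)
    expected = ["time_s", "frequency_hz"]
    if list(df.columns) != expected:
        raise ValueError(f"{path}: expected columns {expected}, found {list(df.columns)}")
    return FrequencyTrace(df["time_s"].to_numpy(), df["frequency_hz"].to_numpy(), method=method)


def write_angles(angles: AngleSeries, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "time_s": angles.times,
            "joint1_rad": angles.angles[:, 0],
            "joint2_rad": angles.angles[:, 1],
            "joint3_rad": angles.angles[:, 2],
        }
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_angles(path: str | Path, frame_rate: float | None = None) -> AngleSeries:
    df = pd.read_csv(path)
    expected = ["time_s", "joint1_rad", "joint2_rad", "joint3_rad"]
    if list(df.columns) != expected:
        raise ValueError(f"{path}: expected columns {expected}, found {list(df.columns)}")
    times = df["time_s"].to_numpy()
    if frame_rate is None:
        if times.size < 2:
            raise ValueError(f"{path}: cannot infer frame rate from a single row")
        frame_rate = 1.0 / float(np.median(np.diff(times)))
    return AngleSeries(times, df[expected[1:]].to_numpy(), frame_rate)
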