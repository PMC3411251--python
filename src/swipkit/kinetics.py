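"""Paralysis / reversion classification and per-animal kinetic metrics.

The analysis core: smooth each frequency trace with a moving window, screen
cohort outliers with a modified z-score, then classify behavior by the
published threshold rules —

* an animal is **paralyzed** if its frequency falls below 20% of its own
  maximal (smoothed) value and stays below that threshold for at least 20 s;
  the latency to paralyze is the start of the first such qualifying run;
* a paralyzed animal is a **revertant** if, after the latency, it recrosses
  50% of its maximum for any length of time; each maximal contiguous
  supra-threshold run is one reversion event.

Per-animal metrics follow: reversion frequency (events/animal), reversion
probability (total time in reversion / total time after paralysis onset),
time to first reversion, average reversion event length, and reversion
strength (area under the frequency curve during all reversion events).

Time conventions: each sample represents one sample period, so a run of
``n`` consecutive points at spacing ``dt`` spans ``n·dt`` seconds (a 20 s
dwell at 1 Hz sampling needs 20 consecutive sub-threshold points), while a
reversion event's extent is [first point time, last point time] — "any
length of time" means a single-point event counts, with zero length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .signals import FrequencyTrace

__all__ = [
    "AnalysisConfig",
    "KineticsSummary",
    "ParalysisCall",
    "detect_paralysis",
    "detect_reversions",
    "flag_outliers",
    "modified_zscores",
    "smooth_trace",
    "summarize_kinetics",
]


@dataclass(frozen=True)
class AnalysisConfig:
    """User-settable classification parameters.

    Defaults encode the published definitions: paralysis threshold 20% of
    the per-animal maximum held for >= 20 s; reversion threshold 50%;
    outlier cutoff 3.5 on the modified z-score.

    The smoothing window trades noise suppression against sensitivity to
    short reversion bouts, which count for *any* length of time: a boxcar
    of width ``w`` drops a bout of length ``b < w`` to a fraction ``b/w``
    of its height, so the 50%-of-max threshold loses bouts shorter than
    about ``w/2``.  Since the reversion definition puts a premium on
    sensitivity, the default is the smallest window that still averages a
    useful number of frames: 1 s (15 frames at the default frame rate,
    a ~4x noise reduction), hiding only sub-half-second bouts.
    """

    smooth_window_s: float = 1.0
    paralysis_fraction: float = 0.20
    paralysis_dwell_s: float = 20.0
    reversion_fraction: float = 0.50
    outlier_z_threshold: float = 3.5

    def __post_init__(self) -> None:
        if not (0 < self.paralysis_fraction < self.reversion_fraction <= 1):
            raise ValueError("need 0 < paralysis_fraction < reversion_fraction <= 1")
        if self.paralysis_dwell_s <= 0:
            raise ValueError("paralysis_dwell_s must be positive")
        if self.smooth_window_s <= 0:
            raise ValueError("smooth_window_s must be positive")
        if self.outlier_z_threshold <= 0:
            raise ValueError("outlier_z_threshold must be positive")


def smooth_trace(trace: FrequencyTrace, window_s: float) -> FrequencyTrace:
    """Centered moving average, window truncated at the edges.

    The window is converted to an odd number of samples (rounded from
    ``window_s / dt``) so the average is symmetric; edge points average over
    the samples actually available.  The output grid is unchanged.
    """
    dt = trace.dt
    if window_s < dt:
        raise ValueError(f"window_s={window_s} shorter than the trace spacing {dt}")
    n = max(1, int(round(window_s / dt)))
    if n % 2 == 0:
        n += 1
    smoothed = (
        pd.Series(trace.frequency).rolling(n, center=True, min_periods=1).mean().to_numpy()
    )
    meta = dict(trace.meta)
    meta["smooth_window_s"] = window_s
    return FrequencyTrace(trace.times.copy(), smoothed, method=trace.method, meta=meta)


# --------------------------------------------------------------------------
# outlier screen
# --------------------------------------------------------------------------

def modified_zscores(values: np.ndarray) -> np.ndarray:
    """Modified z-scores M = 0.6745·(x − median)/MAD.

    When the MAD is exactly zero (a majority of tied values) the standard
    fallback M = 0.7979·(x − median)/meanAD is used; if the mean absolute
    deviation is also zero the data are degenerate and all scores are 0.
    """
    x = np.asarray(values, dtype=float)
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad > 0:
        return 0.6745 * (x - med) / mad
    mean_ad = np.mean(np.abs(x - med))
    if mean_ad > 0:
        return 0.7979 * (x - med) / mean_ad
    return np.zeros_like(x)


def flag_outliers(
    traces_or_values, threshold: float = 3.5
) -> np.ndarray:
    """Per-animal outlier flags over a cohort.

    Accepts a sequence of (smoothed) traces — the statistic is each animal's
    mean frequency — or a 1-d array of per-animal statistics.  Animals with
    |modified z-score| above the threshold are flagged for exclusion
    downstream; they are never deleted from the input.
    """
    values = np.asarray(
        [
            t.frequency.mean() if isinstance(t, FrequencyTrace) else float(t)
            for t in traces_or_values
        ]
    )
    if values.size < 3:
        raise ValueError(f"outlier screen needs >= 3 animals, got {values.size}")
    scores = modified_zscores(values)
    if np.all(scores == 0) and np.ptp(values) == 0:
        warnings.warn("degenerate cohort spread (all statistics equal); no outliers flagged",
                      stacklevel=2)
        return np.zeros(values.size, dtype=bool)
    return np.abs(scores) > threshold


# --------------------------------------------------------------------------
# classification
# --------------------------------------------------------------------------

def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (first, last) inclusive index pairs."""
    if not mask.any():
        return []
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[::2], edges[1::2] - 1
    return list(zip(starts.tolist(), ends.tolist()))


@dataclass
class ParalysisCall:
    """Result of the paralysis rule on one smoothed trace."""

    paralyzed: bool
    latency: float | None
    max_frequency: float
    # qualifying sub-threshold runs as closed [start, end] time intervals,
    # where a run of points t_i..t_j covers [t_i, t_j + dt]
    runs: list[tuple[float, float]] = field(default_factory=list)


def detect_paralysis(trace: FrequencyTrace, config: AnalysisConfig = AnalysisConfig()) -> ParalysisCall:
    """Apply the paralysis rule to a smoothed trace.

    The threshold is ``paralysis_fraction`` × the trace maximum; the animal
    is paralyzed iff some contiguous run of points strictly below the
    threshold spans at least ``paralysis_dwell_s``, and the latency is the
    start time of the first such run.  An all-zero trace is a degenerate
    never-swimmer: classified paralyzed with latency at the trace start.
    """
    freq = trace.frequency
    max_f = float(freq.max())
    times = trace.times
    dt = trace.dt
    if max_f == 0.0:
        warnings.warn("all-zero trace: degenerate never-swimming animal", stacklevel=2)
        return ParalysisCall(True, float(times[0]), 0.0,
                             runs=[(float(times[0]), float(times[-1] + dt))])
    threshold = config.paralysis_fraction * max_f
    below = freq < threshold
    qualifying = []
    for i0, i1 in _runs(below):
        span = times[i1] - times[i0] + dt
        if span >= config.paralysis_dwell_s - 1e-9:
            qualifying.append((float(times[i0]), float(times[i1] + dt)))
    if not qualifying:
        return ParalysisCall(False, None, max_f)
    return ParalysisCall(True, qualifying[0][0], max_f, runs=qualifying)


def detect_reversions(
    trace: FrequencyTrace,
    latency: float,
    max_frequency: float,
    config: AnalysisConfig = AnalysisConfig(),
) -> list[tuple[float, float]]:
    """Reversion events of a paralyzed animal.

    After the latency, every maximal contiguous run of points at or above
    ``reversion_fraction`` × the maximum is one event, however short; the
    event extends from its first to its last point time.
    """
    if latency is None:
        raise ValueError("detect_reversions called on a non-paralyzed animal")
    threshold = config.reversion_fraction * max_frequency
    mask = (trace.times >= latency) & (trace.frequency >= threshold)
    return [
        (float(trace.times[i0]), float(trace.times[i1])) for i0, i1 in _runs(mask)
    ]


@dataclass
class KineticsSummary:
    """Per-animal kinetic metrics (one row of the cohort summary table)."""

    animal_id: str
    max_frequency: float
    paralyzed: bool
    latency_to_paralyze: float | None
    revertant: bool
    reversion_events: list[tuple[float, float]]
    reversion_frequency: int | None  # events/animal
    reversion_probability: float | None  # time in reversion / time after onset
    time_to_first_reversion: float | None
    average_reversion_event_length: float | None
    reversion_strength: float | None  # Hz·s, area under curve during events


def summarize_kinetics(
    trace: FrequencyTrace,
    config: AnalysisConfig = AnalysisConfig(),
    animal_id: str = "",
) -> KineticsSummary:
    """Full kinetic summary of one (already smoothed) trace."""
    call = detect_paralysis(trace, config)
    if not call.paralyzed:
        return KineticsSummary(
            animal_id, call.max_frequency, False, None, False, [],
            None, None, None, None, None,
        )
    events = detect_reversions(trace, call.latency, call.max_frequency, config)
    duration = trace.duration
    time_after = duration - (call.latency - trace.times[0])
    total_rev = sum(e - s for s, e in events)
    if total_rev > time_after + 1e-9:
        raise AssertionError("total reversion time exceeds time after paralysis")
    if events:
        strength = 0.0
        for s, e in events:
            sel = (trace.times >= s) & (trace.times <= e)
            if sel.sum() >= 2:
                strength += float(np.trapezoid(trace.frequency[sel], trace.times[sel]))
        return KineticsSummary(
            animal_id, call.max_frequency, True, call.latency, True, events,
            len(events),
            total_rev / time_after if time_after > 0 else 0.0,
            events[0][0] - call.latency,
            total_rev / len(events),
            strength,
        )
    return KineticsSummary(
        animal_id, call.max_frequency, True, call.latency, False, [],
        0, 0.0, None, None, 0.0,
    )
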