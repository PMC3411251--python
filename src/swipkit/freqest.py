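"""Swim-frequency estimation from joint-angle series.

Two estimators, following the platform's dual approach:

* :func:`freq_fft` — sliding-window FFT: per window and joint channel, the
  in-band spectral peak (parabolically interpolated on the log-spectrum to
  beat bin quantization); the trace value is the median across the three
  channels, timestamped at the window center.
* :func:`freq_extrema` — counting frames between angular extrema: each pair
  of successive alternating extrema spaced Δt contributes a half-period
  estimate f = 1/(2Δt) at the pair midpoint; extremum times are refined to
  sub-frame precision by a parabolic fit, channel estimates are pooled and
  resampled to a common grid, and sustained quiescence maps to 0 Hz.

:func:`estimate_frequency` dispatches between them and, for ``method="both"``,
attaches the mean absolute inter-method discrepancy as quality metadata.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import find_peaks, get_window

from .signals import AngleSeries, FrequencyTrace

__all__ = ["estimate_frequency", "freq_extrema", "freq_fft"]

DEFAULT_BAND = (0.2, 3.0)  # Hz; brackets all reported thrashing frequencies
DEFAULT_WINDOW_S = 10.0
DEFAULT_STEP_S = 1.0
# spectral peak-to-median power ratio below which a window is flagged
LOW_CONFIDENCE_PROMINENCE = 10.0
_POWER_FLOOR = 1e-18  # windows with less in-band power than this report 0 Hz


def _parabolic_refine(y: np.ndarray, i: np.ndarray) -> np.ndarray:
    """Sub-sample offset of a local extremum at index i from a 3-point fit."""
    ym = y[..., 0]
    y0 = y[..., 1]
    yp = y[..., 2]
    denom = ym - 2 * y0 + yp
    with np.errstate(divide="ignore", invalid="ignore"):
        delta = 0.5 * (ym - yp) / denom
    delta = np.where(np.isfinite(delta), delta, 0.0)
    return np.clip(delta, -0.5, 0.5)


def freq_fft(
    angles: AngleSeries,
    window_s: float = DEFAULT_WINDOW_S,
    step_s: float = DEFAULT_STEP_S,
    band: tuple[float, float] = DEFAULT_BAND,
) -> FrequencyTrace:
    """Windowed-FFT dominant-frequency trace.

    Windows are Hann-tapered and zero-padded 8x; the in-band peak of each
    channel's log-spectrum is refined by parabolic interpolation and the
    median across channels reported at the window center.  Windows whose
    in-band spectral peak barely rises above the in-band median power are
    flagged low-confidence in ``meta["low_confidence"]``.
    """
    f_lo, f_hi = band
    nyq = angles.nyquist
    if not (0 < f_lo < f_hi < nyq + 1e-12):
        raise ValueError(f"band {band} must lie within (0, Nyquist={nyq:.3g})")
    if window_s < 2.0 / f_lo:
        raise ValueError(f"window_s={window_s} too short for f_lo={f_lo}; need >= {2.0 / f_lo}")
    fr = angles.frame_rate
    n_win = int(round(window_s * fr))
    step = max(1, int(round(step_s * fr)))
    x = angles.angles
    if x.shape[0] < n_win:
        raise ValueError(f"series of {x.shape[0]} frames shorter than one {n_win}-frame window")

    windows = sliding_window_view(x, n_win, axis=0)[::step]  # (W, 3, n_win)
    windows = windows - windows.mean(axis=-1, keepdims=True)
    taper = get_window("hann", n_win, fftbins=True)
    nfft = 8 * n_win
    spec = np.abs(np.fft.rfft(windows * taper, n=nfft, axis=-1)) ** 2
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fr)
    in_band = (freqs >= f_lo) & (freqs <= f_hi)
    band_idx = np.flatnonzero(in_band)
    band_spec = spec[..., band_idx]  # (W, 3, B)

    peak = band_idx[np.argmax(band_spec, axis=-1)]  # (W, 3) global bin index
    # parabolic interpolation on the log-spectrum around the peak
    i0 = np.clip(peak, 1, freqs.size - 2)
    w_idx = np.arange(spec.shape[0])[:, None]
    c_idx = np.arange(3)[None, :]
    tri = np.stack(
        [spec[w_idx, c_idx, i0 - 1], spec[w_idx, c_idx, i0], spec[w_idx, c_idx, i0 + 1]],
        axis=-1,
    )
    delta = _parabolic_refine(np.log(tri + 1e-300), i0)
    f_est = (i0 + delta) * fr / nfft

    peak_power = band_spec.max(axis=-1)
    median_power = np.median(band_spec, axis=-1)
    silent = peak_power < _POWER_FLOOR
    f_est = np.where(silent, 0.0, f_est)
    channel_conf = peak_power / np.maximum(median_power, 1e-300)

    freq = np.clip(np.median(f_est, axis=1), 0.0, nyq)
    low_conf = np.median(channel_conf, axis=1) < LOW_CONFIDENCE_PROMINENCE
    starts = np.arange(0, x.shape[0] - n_win + 1, step)
    centers = angles.times[0] + (starts + (n_win - 1) / 2.0) / fr
    return FrequencyTrace(
        centers, freq, method="fft", meta={"low_confidence": low_conf, "window_s": window_s}
    )


def _channel_extrema(x: np.ndarray, dt: float, min_prominence: float) -> tuple[np.ndarray, np.ndarray]:
    """Alternating extrema of one channel: (times, signs)."""
    events = []
    for sign, y in ((1, x), (-1, -x)):
        idx, _ = find_peaks(y, prominence=min_prominence)
        idx = idx[(idx > 0) & (idx < x.size - 1)]
        if idx.size:
            tri = np.stack([y[idx - 1], y[idx], y[idx + 1]], axis=-1)
            delta = _parabolic_refine(tri, idx)
            for t, v in zip((idx + delta) * dt, y[idx]):
                events.append((t, sign, v))
    events.sort()
    # enforce max/min alternation: among consecutive same-sign extrema keep
    # the most extreme one
    kept: list[tuple[float, int, float]] = []
    for ev in events:
        if kept and kept[-1][1] == ev[1]:
            if ev[2] > kept[-1][2]:
                kept[-1] = ev
        else:
            kept.append(ev)
    if not kept:
        return np.empty(0), np.empty(0)
    arr = np.array(kept)
    return arr[:, 0], arr[:, 1]


def freq_extrema(
    angles: AngleSeries,
    min_prominence: float = 0.1,
    quiescence_s: float = 5.0,
    grid_step_s: float = DEFAULT_STEP_S,
) -> FrequencyTrace:
    """Inter-extrema half-period frequency trace.

    Extrema below the prominence floor are ignored (ripple rejection); grid
    points farther than ``quiescence_s`` from any extremum-pair midpoint are
    assigned 0 Hz, mapping sustained stillness to paralysis-level output.
    """
    if min_prominence <= 0:
        raise ValueError("min_prominence must be positive")
    dt = 1.0 / angles.frame_rate
    est_t: list[np.ndarray] = []
    est_f: list[np.ndarray] = []
    for ch in range(3):
        t_ext, _ = _channel_extrema(angles.angles[:, ch], dt, min_prominence)
        if t_ext.size >= 2:
            half_periods = np.diff(t_ext)
            mids = (t_ext[:-1] + t_ext[1:]) / 2.0
            valid = half_periods > 0
            est_t.append(mids[valid] + angles.times[0])
            est_f.append(1.0 / (2.0 * half_periods[valid]))

    grid = np.arange(angles.times[0], angles.times[-1] + 1e-9, grid_step_s)
    if not est_t:
        return FrequencyTrace(grid, np.zeros_like(grid), method="extrema")
    t_all = np.concatenate(est_t)
    f_all = np.concatenate(est_f)
    order = np.argsort(t_all, kind="stable")
    t_all, f_all = t_all[order], f_all[order]

    freq = np.interp(grid, t_all, f_all)
    # quiescence: zero out grid points with no nearby extremum-pair estimate
    pos = np.searchsorted(t_all, grid)
    left = np.where(pos > 0, grid - t_all[np.maximum(pos - 1, 0)], np.inf)
    right = np.where(pos < t_all.size, t_all[np.minimum(pos, t_all.size - 1)] - grid, np.inf)
    freq = np.where(np.minimum(left, right) > quiescence_s, 0.0, freq)
    freq = np.clip(freq, 0.0, angles.nyquist)
    return FrequencyTrace(grid, freq, method="extrema", meta={"n_extrema_pairs": t_all.size})


def estimate_frequency(
    angles: AngleSeries, method: str = "both", **settings
) -> FrequencyTrace:
    """Dispatch to an estimator; ``both`` cross-checks FFT against extrema.

    With ``method="both"`` the returned trace is the FFT trace with
    ``meta["method_discrepancy"]`` set to the mean absolute difference
    between the two estimators on the FFT grid.
    """
    fft_keys = {"window_s", "step_s", "band"}
    ext_keys = {"min_prominence", "quiescence_s", "grid_step_s"}
    unknown = set(settings) - fft_keys - ext_keys
    if unknown:
        raise ValueError(f"unknown settings: {sorted(unknown)}")
    fft_kw = {k: v for k, v in settings.items() if k in fft_keys}
    ext_kw = {k: v for k, v in settings.items() if k in ext_keys}
    if method == "fft":
        return freq_fft(angles, **fft_kw)
    if method == "extrema":
        return freq_extrema(angles, **ext_kw)
    if method == "both":
        fft_trace = freq_fft(angles, **fft_kw)
        ext_trace = freq_extrema(angles, **ext_kw)
        ext_on_fft = np.interp(fft_trace.times, ext_trace.times, ext_trace.frequency)
        fft_trace.meta["method_discrepancy"] = float(
            np.mean(np.abs(fft_trace.frequency - ext_on_fft))
        )
        return fft_trace
    raise ValueError(f"unknown method {method!r}; expected fft, extrema or both")
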