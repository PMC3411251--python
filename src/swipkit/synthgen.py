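"""Synthetic swimming recordings with genotype-dependent paralysis kinetics.

Swimming-induced paralysis (Swip) is the phenotype in which a worm dropped in
water thrashes briefly and then stops; hyperdopaminergic mutants paralyze
early and may transiently "revert" to near-normal thrashing.  This module
generates per-animal recordings with exactly that structure so every
downstream stage — spine tracking, frequency estimation, kinetic analysis and
cohort reporting — can be exercised and validated without any raw video.

The behavioral model is a three-state continuous-time Markov chain:

* **swim** — instantaneous body-bend frequency equals a per-animal baseline
  (drawn from the genotype's normal distribution) with optional slow
  exponential fatigue drift and white measurement noise;
* **paralyzed** — a small residual movement level; entered from swim with a
  constant hazard and absorbing except for reversion bouts;
* **reverting** — transient return to the swim-level frequency, entered from
  paralyzed with a constant hazard and exited back to paralyzed likewise.

All holding times are exponential.  Joint-angle series are synthesized from
the frequency ground truth as sinusoids of the accumulated oscillation phase
with fixed per-joint phase offsets (a crude traveling body wave), and can be
rendered to binary-mask frame stacks via the five-point spine model to test
the tracker end to end.

Genotype presets emulate the published kinetic attributes of wild-type (N2)
and hyperdopaminergic mutant strains: maximal frequencies of ~1.1–1.8 Hz,
paralysis latencies of ~80–340 s within the 10-min assay, reversion
incidences of 0.05–0.8 and mean reversion bouts of ~4–6 s.
"""

from __future__ import annotations

import dataclasses
import json
import math
import shutil
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from .signals import AngleSeries, FrequencyTrace, write_angles, write_trace
from .spinetrack import Spine, spine_points

__all__ = [
    "GenotypeParams",
    "GroundTruth",
    "MovieGeometry",
    "PRESETS",
    "RecordingSpec",
    "angles_from_frequency",
    "animal_seed",
    "make_cohort",
    "read_movie",
    "render_movie",
    "sample_trace",
    "write_movie",
]

# Fixed per-joint phase offsets of the synthetic body wave (radians).
JOINT_PHASE_OFFSETS = np.array([0.0, 0.8, 1.6])


@dataclass(frozen=True)
class GenotypeParams:
    """Behavioral parameters of one genotype.

    Rates are per second; frequencies in Hz; angles in radians.  A
    ``paralysis_hazard`` of 0 means the genotype never paralyzes.
    """

    label: str
    base_freq_mean: float
    base_freq_sd: float = 0.05
    freq_decay_rate: float = 0.0  # fraction/s slow fatigue drift of swim frequency
    paralysis_hazard: float = 0.0  # 1/s, constant hazard of swim → paralyzed
    paralyzed_freq: float = 0.05  # Hz residual movement while paralyzed
    reversion_rate: float = 0.0  # 1/s, paralyzed → reverting
    reversion_exit_rate: float = 0.25  # 1/s, reverting → paralyzed
    angle_amplitude: float = 0.6  # radians
    noise_sd_angle: float = 0.05  # radians
    noise_sd_freq: float = 0.05  # Hz

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if f.name == "label":
                if not v:
                    raise ValueError("label must be non-empty")
                continue
            if not math.isfinite(v):
                raise ValueError(f"parameter {f.name!r} is non-finite: {v!r}")
        for f in ("base_freq_mean", "base_freq_sd", "freq_decay_rate", "paralysis_hazard",
                  "paralyzed_freq", "reversion_rate", "reversion_exit_rate",
                  "noise_sd_angle", "noise_sd_freq"):
            if getattr(self, f) < 0:
                raise ValueError(f"parameter {f!r} must be >= 0")
        if not self.base_freq_mean > self.paralyzed_freq:
            raise ValueError("base_freq_mean must exceed paralyzed_freq")
        if not (0 < self.angle_amplitude <= np.pi / 2):
            raise ValueError("angle_amplitude must lie in (0, pi/2]")


@dataclass(frozen=True)
class RecordingSpec:
    """Assay recording parameters; the default emulates a 10-min assay."""

    duration: float = 600.0  # s
    frame_rate: float = 15.0  # frames/s
    seed: int = 0
    n_animals_per_genotype: int = 8

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.n_animals_per_genotype < 1:
            raise ValueError("n_animals_per_genotype must be >= 1")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.frame_rate))

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate

    def validate_for(self, params: GenotypeParams) -> None:
        if self.frame_rate < 4.0 * params.base_freq_mean:
            raise ValueError(
                f"frame_rate {self.frame_rate} Hz below 4x base_freq_mean "
                f"({params.base_freq_mean} Hz) for genotype {params.label!r}"
            )


@dataclass
class GroundTruth:
    """The exact behavioral events drawn for one animal."""

    onset: float | None  # paralysis onset time (s), None if never paralyzed
    reversion_intervals: list[tuple[float, float]]
    base_frequency: float  # the animal's drawn swim baseline (Hz)
    duration: float

    def __post_init__(self) -> None:
        if self.onset is None and self.reversion_intervals:
            raise ValueError("reversion intervals require a paralysis onset")
        prev_end = -np.inf
        for start, end in self.reversion_intervals:
            if self.onset is not None and start < self.onset:
                raise ValueError("reversion interval starts before onset")
            if not (self.onset <= start <= end <= self.duration):
                raise ValueError("reversion interval outside [onset, duration]")
            if start < prev_end:
                raise ValueError("reversion intervals overlap")
            prev_end = end

    @property
    def revertant(self) -> bool:
        return bool(self.reversion_intervals)


# --------------------------------------------------------------------------
# presets emulating published genotype kinetics
# --------------------------------------------------------------------------
# Hazards invert the observed (duration-censored) mean latencies; reversion
# hazards invert 1 − exp(−r · mean time after onset) = incidence; bout exit
# rates are 1 / mean bout length.  docs/methods.md derives the numbers.
PRESETS: dict[str, GenotypeParams] = {
    "n2": GenotypeParams(
        label="n2", base_freq_mean=1.76, base_freq_sd=0.07, freq_decay_rate=3e-4,
    ),
    "dat1": GenotypeParams(
        label="dat1", base_freq_mean=1.45, base_freq_sd=0.28,
        paralysis_hazard=1.0 / 210.0, reversion_rate=6.8e-4,
        reversion_exit_rate=1.0 / 5.77,
    ),
    "vt25": GenotypeParams(
        label="vt25", base_freq_mean=1.28, base_freq_sd=0.27,
        paralysis_hazard=1.0 / 215.0, reversion_rate=7.4e-4,
        reversion_exit_rate=1.0 / 4.22,
    ),
    "vt29": GenotypeParams(
        label="vt29", base_freq_mean=1.13, base_freq_sd=0.24,
        paralysis_hazard=1.0 / 82.0, reversion_rate=1.1e-4,
        reversion_exit_rate=1.0 / 3.59,
    ),
}


def _exponential(rng: np.random.Generator, rate: float) -> float:
    return float(rng.exponential(1.0 / rate)) if rate > 0 else np.inf


def sample_trace(
    params: GenotypeParams, spec: RecordingSpec, animal_seed: int
) -> tuple[FrequencyTrace, GroundTruth]:
    """Draw one animal's behavioral history and its frequency trace.

    The three-state chain is simulated exactly (exponential event times),
    then the instantaneous frequency is sampled on the frame grid: swim and
    reverting states carry the drifting baseline, paralyzed carries the
    residual level, plus white noise, clipped to [0, Nyquist].
    """
    spec.validate_for(params)
    rng = np.random.default_rng(animal_seed)

    base = float(rng.normal(params.base_freq_mean, params.base_freq_sd))
    base = min(max(base, params.paralyzed_freq + 1e-3), spec.frame_rate / 2 - 1e-3)

    onset = _exponential(rng, params.paralysis_hazard)
    intervals: list[tuple[float, float]] = []
    if onset < spec.duration:
        t = onset
        while t < spec.duration:
            wait = _exponential(rng, params.reversion_rate)
            start = t + wait
            if start >= spec.duration:
                break
            length = _exponential(rng, params.reversion_exit_rate)
            end = min(start + length, spec.duration)
            intervals.append((start, end))
            t = end
        truth = GroundTruth(onset, intervals, base, spec.duration)
    else:
        truth = GroundTruth(None, [], base, spec.duration)

    times = spec.times
    swim_level = base * np.exp(-params.freq_decay_rate * times)
    swim_level = np.maximum(swim_level, params.paralyzed_freq)
    paralyzed = np.zeros(times.size, dtype=bool)
    if truth.onset is not None:
        paralyzed = times >= truth.onset
        for start, end in intervals:
            paralyzed &= ~((times >= start) & (times < end))
    freq = np.where(paralyzed, params.paralyzed_freq, swim_level)
    if params.noise_sd_freq > 0:
        freq = freq + rng.normal(0.0, params.noise_sd_freq, size=freq.shape)
    freq = np.clip(freq, 0.0, spec.frame_rate / 2)
    return FrequencyTrace(times, freq, method="ground_truth"), truth


def angles_from_frequency(
    trace: FrequencyTrace,
    params: GenotypeParams,
    spec: RecordingSpec,
    rng: np.random.Generator | None = None,
) -> AngleSeries:
    """Synthesize joint angles whose oscillation follows a frequency trace.

    Each joint angle is ``A·sin(2π·φ(t) + ψ_j) + noise`` where φ(t) is the
    cumulative integral of the instantaneous frequency (in cycles) and ψ_j
    are the fixed per-joint phase offsets.  The exact phase is retained on
    the returned series for test oracles.
    """
    if np.any(trace.frequency > spec.frame_rate / 2 + 1e-12):
        raise ValueError("frequency trace exceeds the Nyquist limit of the frame grid")
    phase = cumulative_trapezoid(trace.frequency, trace.times, initial=0.0)
    osc = np.sin(2 * np.pi * phase[:, None] + JOINT_PHASE_OFFSETS[None, :])
    angles = params.angle_amplitude * osc
    if params.noise_sd_angle > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        angles = angles + rng.normal(0.0, params.noise_sd_angle, size=angles.shape)
    degenerate = bool(np.allclose(angles, 0.0))
    return AngleSeries(trace.times, angles, spec.frame_rate, phase=phase,
                       degenerate=degenerate)


# --------------------------------------------------------------------------
# rendering
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MovieGeometry:
    """Rendering geometry; 1 px is the fixed unit, no physical calibration."""

    segment_length: float = 12.0  # px
    half_width: float = 2.5  # px
    image_size: int = 96  # px, square frames
    center: tuple[float, float] | None = None  # defaults to the frame center
    rotation: float = 0.0  # body rotation w.r.t. the vertical axis


def render_movie(
    angles: AngleSeries, geometry: MovieGeometry = MovieGeometry()
) -> tuple[np.ndarray, list[Spine]]:
    """Render an angle series to a binary-mask frame stack.

    Each frame draws the five-point spine polyline (fixed segment length,
    fixed center and rotation — the synthetic worm thrashes in place) and
    dilates it to the body half-width.  Returns the stack and the exact
    per-frame spines used, the ground truth for tracker tests.
    """
    size = geometry.image_size
    cx, cy = geometry.center if geometry.center is not None else ((size - 1) / 2.0,) * 2
    masks = np.zeros((angles.n_frames, size, size), dtype=bool)
    spines: list[Spine] = []
    margin = geometry.half_width + 1.0
    yy, xx = np.mgrid[0:size, 0:size]
    for i in range(angles.n_frames):
        spine = Spine(cx, cy, geometry.rotation, angles.angles[i])
        pts = spine_points(spine, geometry.segment_length)
        if (pts.min() < margin) or (pts.max() > size - 1 - margin):
            raise ValueError(f"spine leaves image bounds at frame {i}")
        masks[i] = _rasterize_points(pts, geometry.half_width, xx, yy)
        spines.append(spine)
    return masks, spines


def _rasterize_points(pts: np.ndarray, half_width: float, xx: np.ndarray, yy: np.ndarray) -> np.ndarray:
    """Exact distance-to-polyline rasterization of the dilated body."""
    dist = np.full(xx.shape, np.inf)
    for a, b in zip(pts[:-1], pts[1:]):
        ab = b - a
        denom = float(ab @ ab)
        t = ((xx - a[0]) * ab[0] + (yy - a[1]) * ab[1]) / denom
        t = np.clip(t, 0.0, 1.0)
        px = a[0] + t * ab[0]
        py = a[1] + t * ab[1]
        d2 = (xx - px) ** 2 + (yy - py) ** 2
        dist = np.minimum(dist, d2)
    return dist <= half_width**2


def write_movie(movie: np.ndarray, path: str | Path) -> None:
    """Write a frame stack as one multi-page TIFF or a directory of PNGs."""
    path = Path(path)
    data = (np.asarray(movie).astype(np.uint8)) * 255
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        tifffile.imwrite(path, data, compression="zlib")
    else:
        from PIL import Image

        path.mkdir(parents=True, exist_ok=True)
        for i, frame in enumerate(data):
            Image.fromarray(frame).save(path / f"frame_{i:05d}.png")


def read_movie(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.is_dir():
        from PIL import Image

        files = sorted(path.glob("frame_*.png"))
        if not files:
            raise ValueError(f"no frame_*.png files in {path}")
        return np.stack([np.asarray(Image.open(f)) > 0 for f in files])
    import tifffile

    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    return data > 0


# --------------------------------------------------------------------------
# cohorts
# --------------------------------------------------------------------------

def animal_seed(cohort_seed: int, genotype_index: int, animal_index: int) -> int:
    """Stated per-animal seed splitting rule.

    Seeds derive from the cohort seed and the (genotype, animal) indices via
    ``numpy.random.SeedSequence`` so cohorts are reproducible and extensible
    (adding animals or genotypes never reshuffles existing ones).
    """
    ss = np.random.SeedSequence(entropy=(int(cohort_seed), genotype_index, animal_index))
    return int(ss.generate_state(1, dtype=np.uint32)[0])


def make_cohort(
    genotypes: list[GenotypeParams],
    spec: RecordingSpec,
    out_dir: str | Path,
    movies: bool = False,
    geometry: MovieGeometry = MovieGeometry(),
    overwrite: bool = False,
) -> pd.DataFrame:
    """Generate an on-disk cohort: one trace/angle file per animal plus
    annotation (TSV: animal_id, genotype, file) and a ground-truth JSON.

    Deterministic under a fixed ``spec.seed``; regenerating with the same
    seed yields byte-identical files.  Returns the annotation table.
    """
    labels = [g.label for g in genotypes]
    if len(set(labels)) != len(labels):
        raise ValueError("genotype labels must be unique")
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()):
        if not overwrite:
            raise FileExistsError(f"output directory {out} exists; pass overwrite=True")
        shutil.rmtree(out)
    (out / "traces").mkdir(parents=True, exist_ok=True)
    (out / "angles").mkdir(exist_ok=True)
    if movies:
        (out / "movies").mkdir(exist_ok=True)

    rows = []
    truths: dict[str, dict] = {}
    for gi, params in enumerate(genotypes):
        for ai in range(spec.n_animals_per_genotype):
            aid = f"{params.label}_{ai:03d}"
            seed = animal_seed(spec.seed, gi, ai)
            trace, truth = sample_trace(params, spec, seed)
            angle_rng = np.random.default_rng(seed + 1)
            angles = angles_from_frequency(trace, params, spec, rng=angle_rng)
            trace_file = f"traces/{aid}.csv"
            write_trace(trace, out / trace_file)
            write_angles(angles, out / "angles" / f"{aid}.csv")
            if movies:
                movie, _ = render_movie(angles, geometry)
                write_movie(movie, out / "movies" / f"{aid}.tif")
            rows.append({"animal_id": aid, "genotype": params.label, "file": trace_file})
            truths[aid] = {
                "onset": truth.onset,
                "reversion_intervals": truth.reversion_intervals,
                "base_frequency": truth.base_frequency,
                "duration": truth.duration,
                "seed": seed,
            }
    annotation = pd.DataFrame(rows)
    annotation.to_csv(out / "annotation.tsv", sep="\t", index=False)
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(truths, fh, indent=1, sort_keys=True)
    return annotation


def read_ground_truth(path: str | Path) -> dict[str, GroundTruth]:
    """Load a cohort's ground-truth file back into :class:`GroundTruth`."""
    with open(path) as fh:
        raw = json.load(fh)
    return {
        aid: GroundTruth(
            rec["onset"],
            [tuple(iv) for iv in rec["reversion_intervals"]],
            rec["base_frequency"],
            rec["duration"],
        )
        for aid, rec in raw.items()
    }
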