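"""Five-point spine model and particle-filter tracking of binary-mask movies.

The worm body is modelled as a five-point spine: four rigid segments of a
shared fixed length joined at three bending joints.  A spine is parameterized
by the (x, y) position of its center point, its rotation with respect to the
vertical image axis, and the three joint angles.  The tracker fits this model
to each frame of a binary-mask movie with a particle filter gated by simple
frame-difference motion detection, and exports joint-angle time series for
the frequency estimators.

Coordinate conventions
----------------------
Points are (x, y) with y increasing down the image (row index).  A segment
heading ``a`` (radians from the vertical axis) corresponds to the unit vector
``(sin a, cos a)``; a horizontal body therefore has rotation ±π/2.  The five
points p0..p4 are reconstructed from the parameters as

    s1 = rot − β2/2,  s2 = rot + β2/2,  s0 = s1 − β1,  s3 = s2 + β3
    p2 = center,  p1 = p2 − L·d(s1),  p0 = p1 − L·d(s0),
    p3 = p2 + L·d(s2),  p4 = p3 + L·d(s3)

where β1..β3 are the joint angles at p1, p2, p3 and L the segment length.
Head and tail are not distinguished: reversing the point order maps
(rot, β1, β2, β3) → (rot+π, −β3, −β2, −β1), and tracking keeps whichever
orientation the initializer picked by minimizing frame-to-frame change.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.morphology import skeletonize

from .signals import AngleSeries

__all__ = [
    "Spine",
    "SpineTrack",
    "TrackerSettings",
    "TrackingLostError",
    "extract_angles",
    "flip_spine",
    "initialize_spine",
    "rasterize_spine",
    "spine_from_points",
    "spine_points",
    "track_movie",
    "read_track",
    "write_track",
]


def _wrap(a):
    """Wrap angles to (−π, π]."""
    a = np.asarray(a, dtype=float)
    out = -((-a + np.pi) % (2 * np.pi) - np.pi)
    return out


@dataclass
class Spine:
    """One frame's five-point body model."""

    center_x: float
    center_y: float
    rotation: float
    joint_angles: np.ndarray  # (3,) radians, each in (−π, π]

    def __post_init__(self) -> None:
        self.joint_angles = np.asarray(self.joint_angles, dtype=float)
        if self.joint_angles.shape != (3,):
            raise ValueError("joint_angles must have exactly 3 entries")
        self.rotation = float(_wrap(self.rotation))
        self.joint_angles = _wrap(self.joint_angles)

    def as_vector(self) -> np.ndarray:
        return np.array(
            [self.center_x, self.center_y, self.rotation, *self.joint_angles], dtype=float
        )

    @classmethod
    def from_vector(cls, v: np.ndarray) -> "Spine":
        return cls(float(v[0]), float(v[1]), float(v[2]), np.asarray(v[3:6], dtype=float))


def spine_points(spine: Spine, segment_length: float) -> np.ndarray:
    """Deterministic (5, 2) array of (x, y) body points for a spine."""
    pts = _points_batch(spine.as_vector()[None, :], segment_length)
    return pts[0]


def _points_batch(states: np.ndarray, segment_length: float) -> np.ndarray:
    """Vectorized point construction: states (P, 6) → points (P, 5, 2)."""
    cx, cy, rot = states[:, 0], states[:, 1], states[:, 2]
    b1, b2, b3 = states[:, 3], states[:, 4], states[:, 5]
    s1 = rot - b2 / 2.0
    s2 = rot + b2 / 2.0
    s0 = s1 - b1
    s3 = s2 + b3
    L = segment_length

    def d(a):
        return np.stack([np.sin(a), np.cos(a)], axis=-1)

    p2 = np.stack([cx, cy], axis=-1)
    p1 = p2 - L * d(s1)
    p0 = p1 - L * d(s0)
    p3 = p2 + L * d(s2)
    p4 = p3 + L * d(s3)
    return np.stack([p0, p1, p2, p3, p4], axis=1)


def spine_from_points(points: np.ndarray) -> tuple[Spine, float]:
    """Invert :func:`spine_points`: fit parameters to 5 ordered body points.

    Returns the spine and the mean segment length.  Segment headings are
    unwrapped along the body so a body crossing the ±π seam does not produce
    spurious joint angles.
    """
    points = np.asarray(points, dtype=float)
    if points.shape != (5, 2):
        raise ValueError("points must have shape (5, 2)")
    seg = np.diff(points, axis=0)
    lengths = np.hypot(seg[:, 0], seg[:, 1])
    if np.any(lengths == 0):
        raise ValueError("degenerate spine: coincident consecutive points")
    headings = np.arctan2(seg[:, 0], seg[:, 1])
    headings = np.unwrap(headings)
    b1 = headings[1] - headings[0]
    b2 = headings[2] - headings[1]
    b3 = headings[3] - headings[2]
    rot = (headings[1] + headings[2]) / 2.0
    return Spine(points[2, 0], points[2, 1], rot, np.array([b1, b2, b3])), float(lengths.mean())


def flip_spine(spine: Spine) -> Spine:
    """Equivalent spine with head/tail order reversed."""
    b1, b2, b3 = spine.joint_angles
    return Spine(
        spine.center_x,
        spine.center_y,
        spine.rotation + np.pi,
        np.array([-b3, -b2, -b1]),
    )


def rasterize_spine(
    spine: Spine, segment_length: float, half_width: float, shape: tuple[int, int]
) -> np.ndarray:
    """Binary body mask: the spine polyline dilated to the body half-width."""
    pts = spine_points(spine, segment_length)
    canvas = np.zeros(shape, dtype=bool)
    samples = _polyline_samples(pts[None], n_per_segment=max(8, int(np.ceil(segment_length * 2))))
    xi = np.clip(np.round(samples[0, :, 0]).astype(int), 0, shape[1] - 1)
    yi = np.clip(np.round(samples[0, :, 1]).astype(int), 0, shape[0] - 1)
    canvas[yi, xi] = True
    dist = ndimage.distance_transform_edt(~canvas)
    return dist <= half_width


def _polyline_samples(points: np.ndarray, n_per_segment: int = 10) -> np.ndarray:
    """Sample each of the 4 segments densely: (P, 5, 2) → (P, 4*n, 2)."""
    t = np.linspace(0.0, 1.0, n_per_segment, endpoint=False)
    a = points[:, :-1, None, :]  # (P, 4, 1, 2)
    b = points[:, 1:, None, :]
    samp = a + (b - a) * t[None, None, :, None]
    # include the very last body point
    samp = np.concatenate([samp.reshape(points.shape[0], -1, 2), points[:, -1:, :]], axis=1)
    return samp


# --------------------------------------------------------------------------
# scoring
# --------------------------------------------------------------------------

def _score_batch(
    states: np.ndarray,
    edt_fg: np.ndarray,
    fg_area: float,
    segment_length: float,
    half_width: float,
) -> np.ndarray:
    """Overlap score for a batch of candidate spines.

    Coverage is measured along the spine polyline: a sample point whose
    distance-to-background (``edt_fg``, the Euclidean distance transform of
    the foreground) is at least the body half-width has its whole body disk
    inside the foreground; partial penetration scores proportionally.  The
    score subtracts a penalty for foreground area the spine body leaves
    unexplained, and is clipped to [0, 1].
    """
    pts = _points_batch(states, segment_length)
    samples = _polyline_samples(pts)
    h, w = edt_fg.shape
    xi = np.clip(np.round(samples[..., 0]).astype(int), 0, w - 1)
    yi = np.clip(np.round(samples[..., 1]).astype(int), 0, h - 1)
    depth = edt_fg[yi, xi]
    coverage = np.clip(depth / max(half_width, 1e-9), 0.0, 1.0).mean(axis=1)
    body_area = 4 * segment_length * 2 * half_width + np.pi * half_width**2
    if fg_area > 0:
        unexplained = np.clip((fg_area - coverage * body_area) / fg_area, 0.0, 1.0)
    else:
        unexplained = np.ones_like(coverage)
    return np.clip(coverage - 0.5 * unexplained, 0.0, 1.0)


def spine_score(
    spine: Spine,
    mask: np.ndarray,
    segment_length: float,
    half_width: float,
) -> float:
    """Fit score of a single spine against a binary frame, in [0, 1]."""
    fg = mask.astype(bool)
    edt_fg = ndimage.distance_transform_edt(fg)
    return float(
        _score_batch(spine.as_vector()[None], edt_fg, float(fg.sum()), segment_length, half_width)[0]
    )


# --------------------------------------------------------------------------
# initialization
# --------------------------------------------------------------------------

def _skeleton_path(mask: np.ndarray) -> np.ndarray:
    """Ordered (n, 2) (x, y) coordinates along the skeleton's longest path."""
    skel = skeletonize(mask)
    coords = np.argwhere(skel)  # (n, 2) as (row, col)
    if coords.shape[0] < 5:
        raise ValueError("skeleton too short to carry a five-point spine")
    index = {tuple(c): i for i, c in enumerate(coords)}
    neighbors: list[list[int]] = [[] for _ in range(coords.shape[0])]
    offsets = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    for i, (r, c) in enumerate(coords):
        for dr, dc in offsets:
            j = index.get((r + dr, c + dc))
            if j is not None:
                neighbors[i].append(j)

    def bfs(start: int) -> tuple[int, dict[int, int]]:
        parent = {start: -1}
        q = deque([start])
        last = start
        while q:
            u = q.popleft()
            last = u
            for v in neighbors[u]:
                if v not in parent:
                    parent[v] = u
                    q.append(v)
        return last, parent

    far, _ = bfs(0)
    end, parent = bfs(far)
    path = [end]
    while parent[path[-1]] != -1:
        path.append(parent[path[-1]])
    rc = coords[np.array(path)]
    return rc[:, ::-1].astype(float)  # (x, y)


def initialize_spine(mask: np.ndarray, min_area: int = 10) -> Spine:
    """Fit a spine to the first frame of a movie from its skeleton.

    The mask must contain exactly one foreground component of plausible worm
    area.  Five equally spaced points along the skeleton's longest path give
    the body points; the segment length implied by them is the skeleton
    length / 4.  Head/tail order is arbitrary.
    """
    fg = np.asarray(mask).astype(bool)
    labels, n = ndimage.label(fg)
    if n != 1:
        raise ValueError(f"expected exactly 1 foreground component, found {n}")
    if fg.sum() < min_area:
        raise ValueError(f"foreground area {int(fg.sum())} below plausible worm area {min_area}")
    path = _skeleton_path(fg)
    seglen = np.hypot(*np.diff(path, axis=0).T)
    arclen = np.concatenate([[0.0], np.cumsum(seglen)])
    # trim the skeleton ends: thinning leaves short diagonal stubs of about
    # one body half-width at blunt body tips, which would bend the end segments
    half_width = max(1.0, _estimate_half_width(fg, arclen[-1]))
    trim = min(half_width, 0.15 * arclen[-1])
    targets = np.linspace(trim, arclen[-1] - trim, 5)
    pts = np.column_stack(
        [np.interp(targets, arclen, path[:, 0]), np.interp(targets, arclen, path[:, 1])]
    )
    spine, L = spine_from_points(pts)
    score = spine_score(spine, fg, L, half_width=half_width)
    if score < 0.5:
        warnings.warn(f"initial spine fit score {score:.2f} below 0.5", stacklevel=2)
    return spine


def _estimate_half_width(mask: np.ndarray, skeleton_length: float) -> float:
    """Body half-width from area / (2 × centerline length)."""
    if skeleton_length <= 0:
        return 1.0
    return float(mask.sum()) / (2.0 * skeleton_length)


def estimate_segment_length(mask: np.ndarray) -> float:
    """Fixed segment length: first-frame skeleton length / 4."""
    path = _skeleton_path(np.asarray(mask).astype(bool))
    return float(np.hypot(*np.diff(path, axis=0).T).sum() / 4.0)


# --------------------------------------------------------------------------
# particle filter
# --------------------------------------------------------------------------

class TrackingLostError(RuntimeError):
    """Raised when the fit score stays below the floor for too many frames."""

    def __init__(self, frame: int, score: float):
        super().__init__(f"tracking lost at frame {frame} (score {score:.3f})")
        self.frame = frame


@dataclass
class TrackerSettings:
    """Particle-filter configuration.

    Proposal standard deviations are per-frame random-walk scales; at 15 fps
    a 2 Hz, 0.6 rad oscillation moves a joint by at most ~0.5 rad per frame,
    so the defaults cover the full plausible motion when combined over a few
    frames of particle diversity.  Each frame runs ``n_anneal_layers``
    refinement passes with proposal scales shrunk by ``anneal_shrink`` per
    pass, concentrating the cloud on the score optimum before the weighted
    mean is recorded.
    """

    n_particles: int = 300
    sd_center: float = 1.0  # px
    sd_rotation: float = 0.10  # rad
    sd_joint: float = 0.20  # rad
    seed: int = 0
    score_temperature: float = 0.01
    n_anneal_layers: int = 4
    anneal_shrink: float = 0.5
    score_floor: float = 0.2
    max_low_frames: int = 15
    motion_dilation: int = 3  # px added around changed pixels for the gate

    def __post_init__(self) -> None:
        if self.n_particles < 1:
            raise ValueError("n_particles must be >= 1")


@dataclass
class SpineTrack:
    """Per-frame fitted spines with fit scores."""

    spines: list[Spine]
    scores: np.ndarray
    frame_rate: float
    segment_length: float = field(default=np.nan)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.spines) != self.scores.size:
            raise ValueError("one score per spine required")
        if np.any((self.scores < 0) | (self.scores > 1)):
            raise ValueError("scores must lie in [0, 1]")


def _systematic_resample(weights: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    n = weights.size
    positions = (rng.random() + np.arange(n)) / n
    return np.searchsorted(np.cumsum(weights), positions)


def track_movie(
    movie: np.ndarray,
    init: Spine,
    segment_length: float,
    half_width: float,
    settings: TrackerSettings | None = None,
    frame_rate: float = np.nan,
) -> SpineTrack:
    """Track a binary-mask movie frame by frame.

    Each frame, particles perturb the previous frame's spine estimate with
    Gaussian proposal noise, are weighted by the overlap score against the
    frame's foreground restricted to the motion gate (dilated changed pixels
    plus the previous body estimate), and the weighted-mean spine is
    recorded.  Frames identical to their predecessor propagate the previous
    spine unchanged.  Deterministic under a fixed settings seed.
    """
    settings = settings or TrackerSettings()
    movie = np.asarray(movie).astype(bool)
    if movie.ndim != 3:
        raise ValueError("movie must be a (frames, h, w) stack")
    rng = np.random.default_rng(settings.seed)
    n_frames = movie.shape[0]
    shape = movie.shape[1:]

    state = init.as_vector()
    particles = np.tile(state, (settings.n_particles, 1))
    sds = np.array(
        [
            settings.sd_center,
            settings.sd_center,
            settings.sd_rotation,
            settings.sd_joint,
            settings.sd_joint,
            settings.sd_joint,
        ],
        dtype=float,
    )

    spines: list[Spine] = []
    scores = np.empty(n_frames)
    low_run = 0
    prev_frame = None
    gate_iters = max(1, int(settings.motion_dilation))

    for i in range(n_frames):
        frame = movie[i]
        if prev_frame is not None:
            changed = frame ^ prev_frame
            if not changed.any():
                # static frame: no motion, keep the previous estimate exactly
                spines.append(Spine.from_vector(state))
                scores[i] = scores[i - 1]
                if scores[i] < settings.score_floor:
                    low_run += 1
                    if low_run > settings.max_low_frames:
                        raise TrackingLostError(i, scores[i])
                prev_frame = frame
                continue
            gate = ndimage.binary_dilation(changed, iterations=gate_iters)
            body = rasterize_spine(
                Spine.from_vector(state), segment_length, half_width + 1.0, shape
            )
            fg = frame & (gate | body)
            if not fg.any():  # motion far from the tracked body; fall back
                fg = frame
        else:
            fg = frame

        edt_fg = ndimage.distance_transform_edt(fg)
        fg_area = float(fg.sum())

        cur_sds = sds.copy()
        cand = particles
        weights = np.full(settings.n_particles, 1.0 / settings.n_particles)
        n_layers = settings.n_anneal_layers if i > 0 else 1
        for layer in range(n_layers):
            base = particles if (layer == 0 and i > 0) else np.tile(state, (settings.n_particles, 1))
            cand = base + rng.standard_normal(base.shape) * (cur_sds if i > 0 else 0.0)
            cand[0] = state  # always keep the running estimate in the cloud
            w_scores = _score_batch(cand, edt_fg, fg_area, segment_length, half_width)
            logw = w_scores / max(settings.score_temperature, 1e-9)
            logw -= logw.max()
            weights = np.exp(logw)
            weights /= weights.sum()
            state = cand.T @ weights
            cur_sds *= settings.anneal_shrink
        est_score = float(
            _score_batch(state[None], edt_fg, fg_area, segment_length, half_width)[0]
        )
        spines.append(Spine.from_vector(state))
        scores[i] = est_score

        if est_score < settings.score_floor:
            low_run += 1
            if low_run > settings.max_low_frames:
                raise TrackingLostError(i, est_score)
        else:
            low_run = 0

        idx = _systematic_resample(weights, rng)
        particles = cand[idx]
        prev_frame = frame

    return SpineTrack(spines, scores, frame_rate=frame_rate, segment_length=segment_length)


def extract_angles(track: SpineTrack, frame_rate: float | None = None) -> AngleSeries:
    """Joint-angle series from a spine track, with >π jumps unwrapped."""
    if not track.spines:
        raise ValueError("empty track")
    fr = frame_rate if frame_rate is not None else track.frame_rate
    if not np.isfinite(fr) or fr <= 0:
        raise ValueError("frame rate must be provided (track carries none)")
    raw = np.stack([s.joint_angles for s in track.spines])
    unwrapped = np.unwrap(raw, axis=0)
    times = np.arange(raw.shape[0]) / fr
    return AngleSeries(times, unwrapped, fr)


# --------------------------------------------------------------------------
# I/O
# --------------------------------------------------------------------------

_TRACK_COLS = [
    "frame",
    "center_x",
    "center_y",
    "rotation_rad",
    "joint1_rad",
    "joint2_rad",
    "joint3_rad",
    "score",
]


def write_track(track: SpineTrack, path: str | Path) -> None:
    rows = []
    for i, (s, sc) in enumerate(zip(track.spines, track.scores)):
        rows.append([i, s.center_x, s.center_y, s.rotation, *s.joint_angles, sc])
    pd.DataFrame(rows, columns=_TRACK_COLS).to_csv(path, index=False, float_format="%.6f")


def read_track(path: str | Path, frame_rate: float = np.nan) -> SpineTrack:
    df = pd.read_csv(path)
    if list(df.columns) != _TRACK_COLS:
        raise ValueError(f"{path}: unexpected track columns {list(df.columns)}")
    spines = [
        Spine(r.center_x, r.center_y, r.rotation_rad,
              np.array([r.joint1_rad, r.joint2_rad, r.joint3_rad]))
        for r in df.itertuples()
    ]
    return SpineTrack(spines, df["score"].to_numpy(), frame_rate)
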