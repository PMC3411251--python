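# Methods

## The behavioral model behind the synthetic generator

Each synthetic animal follows a three-state continuous-time Markov chain:

```
swim --(paralysis_hazard)--> paralyzed <--(reversion_exit_rate)-- reverting
                             paralyzed --(reversion_rate)-------> reverting
```

All holding times are exponential; paralysis is absorbing except for
reversion bouts. The instantaneous body-bend frequency is

* **swim / reverting**: a per-animal baseline drawn once from
  N(`base_freq_mean`, `base_freq_sd`), multiplied by a slow fatigue drift
  `exp(−freq_decay_rate·t)`;
* **paralyzed**: the residual level `paralyzed_freq`;

plus white Gaussian measurement noise (`noise_sd_freq`), clipped to
[0, Nyquist], sampled on the frame grid. A CTMC with exponential holding
times is the simplest process that reproduces the kinetic summary statistics
the analysis reports (latency distributions, reversion incidence and bout
lengths); it is *not* a mechanistic model of dopamine signaling.

Joint angles are synthesized as `A·sin(2πφ(t) + ψ_j)` with φ the cumulative
integral of the frequency trace (cycles), fixed per-joint phase offsets
ψ = (0, 0.8, 1.6) rad forming a crude traveling wave, and Gaussian angle
noise. The renderer draws the five-point spine polyline (four segments of
fixed length — the body is treated as inextensible) dilated to a body
half-width on a square frame; 1 px is the fixed unit, with no physical
calibration.

### Genotype presets

Presets emulate the published kinetic attributes of the wild type and three
hyperdopaminergic genotypes. Rate parameters invert the printed summary
statistics through the model:

* `paralysis_hazard`: chosen so the *duration-censored* mean onset
  E[T | T < 600 s] = 1/λ − 600·e^(−600λ)/(1 − e^(−600λ)) matches the printed
  mean latency (e.g. 1/210 s⁻¹ reproduces ~174 s for the `dat1` preset;
  1/82 s⁻¹ reproduces ~81 s for `vt29`);
* `reversion_rate`: from incidence ≈ 1 − exp(−r·E[time after onset]);
* `reversion_exit_rate`: 1 / mean bout length.

`base_freq_sd` converts the printed SEM via SD = SEM·√n. Defaults
elsewhere: `paralyzed_freq` 0.05 Hz, `noise_sd_freq` 0.05 Hz,
`noise_sd_angle` 0.05 rad, `angle_amplitude` 0.6 rad.

### Recording defaults

* `duration` 600 s — the 10-min assay.
* `frame_rate` 15 frames/s — not a documented property of the original rig
  (which is unstated); chosen as ≥ 8× the fastest preset frequency
  (1.76 Hz), comfortably above Nyquist for every estimator.
* Per-animal seeds derive from `SeedSequence((cohort_seed, genotype_index,
  animal_index))`, so cohorts are bit-reproducible and extensible without
  reshuffling existing animals.

## Spine tracking

A spine is (center x, center y, rotation w.r.t. the vertical image axis,
three joint angles); the five body points follow deterministically from
these plus the shared segment length (see the module docstring for the
exact construction). Head and tail are not distinguished; reversing the
point order maps (rot, β₁, β₂, β₃) → (rot + π, −β₃, −β₂, −β₁), and tracking
simply keeps the initializer's orientation, which minimizes frame-to-frame
change.

**Initialization** skeletonizes the first frame, walks the skeleton's
longest path, trims one body half-width from each end (thinning leaves
diagonal stubs at blunt tips), and places five equally spaced points along
it; segment length = trimmed path length / 4.

**Scoring.** A candidate spine is scored against a frame by sampling points
densely along its polyline and reading the foreground distance transform:
a sample whose distance-to-background is at least the body half-width has
its whole body disk inside the worm. The score is mean coverage minus half
the fraction of foreground area the spine body leaves unexplained, clipped
to [0, 1]. This is one concrete choice of overlap score; nothing downstream
depends on its exact form.

**Filtering.** Per frame, particles perturb the previous estimate with
Gaussian proposal noise (defaults: 1 px center, 0.10 rad rotation, 0.20 rad
joints), are weighted by `exp(score/τ)` with τ = 0.01, and the weighted-mean
spine is recorded; the cloud is then systematically resampled. Each frame
runs 4 annealing passes with proposal scales halved per pass, which
concentrates the cloud on the score optimum and roughly halves the
round-trip error relative to a single pass at equal particle count.
Motion detection is plain frame differencing: an unchanged frame propagates
the previous spine exactly, and otherwise the scoring foreground is gated to
(dilated changed pixels ∪ previous body estimate). Tracking aborts with a
frame-indexed error when the fit score stays below 0.2 for more than 15
frames. With 300 particles the render→track→extract round trip on a
noise-free 60 s, 15 fps movie recovers joint angles with RMSE ≈ 0.07 rad.

## Frequency estimation

* **FFT**: 10 s Hann-tapered windows, 1 s step, 8× zero-padding, in-band
  (0.2–3.0 Hz) peak with parabolic interpolation on the log-spectrum; the
  trace value is the median across the three joint channels (robust to one
  poorly tracked joint). The 10 s window gives 0.1 Hz native bin resolution;
  interpolation reduces tone error to ~10⁻³ Hz. The band floor is 0.2 Hz
  because a 10 s window must contain at least two cycles of the slowest
  in-band frequency; 0.2–3.0 Hz brackets every reported thrashing frequency
  (1.1–1.8 Hz) with a wide margin. Windows whose spectral peak is less than
  10× the in-band median power are flagged low-confidence.
* **Extrema**: per channel, alternating maxima/minima above a prominence
  floor (default 0.1 rad) with sub-frame peak localization by parabolic
  fit; successive extrema Δt apart yield half-period estimates f = 1/(2Δt)
  at the pair midpoint; channel estimates are pooled and interpolated onto
  a 1 s grid. Grid points farther than 5 s from any estimate are set to
  0 Hz — sustained stillness must read as zero for the paralysis detector.
  Sub-frame localization matters: raw frame quantization alone would give
  errors of ~0.2 Hz at 2 Hz/15 fps, far above the ~0.01 Hz achieved.
* `estimate_frequency(..., method="both")` returns the FFT trace and
  attaches the mean absolute inter-method difference as quality metadata.

Frequency here means the body-bend oscillation frequency of the joint-angle
signals, and half-periods are counted as `1/(2Δt)`; whether the original
software counted full thrash cycles instead (half this rate) cannot be
resolved from printed magnitudes alone.

## Kinetic classification

On the **smoothed** trace (centered moving average, truncated at the edges):

* `max_frequency` = trace maximum. Using the smoothed trace keeps single
  noise spikes from inflating the 20%/50% thresholds, at the cost of a
  small max-statistic bias (~+0.03 Hz at the default noise level).
* *Paralysis*: a contiguous run of points strictly below
  0.20·`max_frequency` spanning ≥ 20 s. A run of n points at spacing dt
  spans n·dt (each sample represents one sample period), so a 20 s dwell at
  1 Hz sampling needs 20 consecutive points. Latency is the start of the
  first qualifying run — printed latencies well before the assay end plus
  reversions beginning ~2 min after paralysis are consistent with
  onset-anchored timing, and whether the original measured to the start or
  end of the dwell window is not documented.
* *Reversion*: after latency, each maximal run of points ≥
  0.50·`max_frequency` is one event, however short (a single sample counts,
  with zero length); an event ends when frequency drops back below the 50%
  threshold. Post-reversion time still counts toward "time after paralysis"
  in the probability denominator. Ties favor swimming (strictly below for
  paralysis, ≥ for reversion).
* An all-zero trace is classified paralyzed with latency 0 and a warning.
* *Outliers*: per-animal statistic = mean smoothed frequency; modified
  z-score M = 0.6745·(x − median)/MAD, |M| > 3.5 flagged. When MAD = 0 (a
  majority of exact ties) the standard fallback M = 0.7979·(x − median)/
  meanAD is used; when both are zero the cohort is degenerate: a warning,
  nothing flagged. Flagged animals are excluded downstream but logged,
  never deleted.

### Smoothing window

The window trades noise suppression against bout sensitivity: a boxcar of
width w attenuates a bout of length b < w to b/w of its height, so the 50%
threshold hides bouts shorter than ~w/2. With bout durations in the 4–6 s
range and exponentially distributed (many short bouts), a 5 s window
silently drops ~25–35% of single-bout revertants; 2 s still drops ~15%.
Because the reversion definition counts recrossings of *any* length, the
default is the smallest window that still averages a useful number of
frames: **1 s** (15 frames at 15 fps, ~4× noise reduction). At the modeled
noise levels the probability of a noise-induced threshold crossing remains
negligible at this width; for noisier real recordings users should widen
the window and accept the derived bout-length floor of ~w/2.

## Cohort reporting

* Traces are resampled onto a shared 1 s grid by linear interpolation
  (matching the FFT step); trace durations differing by more than 5% abort
  assembly with the offending file names.
* Heat-map row order (bottom → top, per genotype block): paralyzers by
  latency ascending, then non-paralyzers by mean frequency descending; ties
  break on animal id so figures are reproducible. Colormap red (high) →
  green (low), scale shared across genotypes. Whether the original ordering
  also folded reversion behavior into "strength of paralysis" is not
  documented; latency-first is the simplest reading.
* Genotype summaries: mean ± SEM (SD with n−1 denominator over √n); latency
  over paralyzers; reversion metrics over revertants only; incidence =
  revertants/paralyzers, undefined (NaN, not 0) when a genotype has no
  paralyzers.
* Population Swip at time t: an animal counts as paralyzed iff t lies in a
  qualifying sub-threshold run and not inside a reversion event, mirroring
  by-eye scoring of "animals swimming / total animals".
* Reversion-incidence comparison: Pearson χ² on the 2×2 revertant table,
  df = 1, no continuity correction.

## What the generator does and does not emulate

It reproduces the statistical structure the analysis consumes: frequency
scales, latency distributions, reversion bout processes, genotype
orderings, cohort file layout. It does **not** model swimming biomechanics,
gradual (non-exponential) fatigue into paralysis, partial-amplitude
reversion, grayscale appearance, camera noise, multi-worm scenes, or
head/tail asymmetry. Passing round-trip and recovery tests therefore
demonstrates internal consistency of tracker, estimators and classifier on
data matching the model's assumptions — not performance on real video,
which additionally requires segmentation quality the binary-mask renderer
sidesteps by construction.

## Problem sizes and determinism

The test suite tracks a 10 s rendered movie (round-trip and invariance
checks) and a 60 s movie in the end-to-end test; classifier cross-checks
use 1000 random piecewise-constant traces; cohort-scale recovery uses
n = 100 animals per genotype at 15 fps × 600 s. `scripts/acceptance.py`
re-runs all of these, deriving every RNG from `--seed` via `SeedSequence`.
Fixed seeds make every simulation, tracker run and cohort byte-reproducible.

## Known limitations

* The particle filter's state model, particle count and score were never
  published for the original tracker; this is a faithful-in-spirit
  reconstruction validated only by the renderer round trip.
* Head/tail identity is never resolved; joint-angle signs are consistent
  within a track but arbitrary up to the end-to-end flip.
* The extrema estimator reports half-period rate; see the frequency note
  above on the cycle-counting ambiguity.
* Reversion bouts shorter than ~half the smoothing window are invisible by
  construction; the recovery tests quantify the resulting incidence bias
  (≲ 0.03 at default settings).
* The χ² and summary tables are reporting plumbing; no ANOVA/multiple-
  comparison machinery is provided.
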