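"""Cohort assembly and reporting surfaces.

Assembles per-animal frequency traces into a genotype-annotated animals ×
time matrix, and reproduces the platform's reporting outputs: heat maps
ordered by strength of paralysis (fastest paralyzers at the bottom of each
genotype block), mean-frequency-vs-time plots, binned-frequency histograms,
a per-genotype kinetic summary table (mean ± SEM), population Swip
fractions, and the chi-square comparison of reversion incidence between two
groups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")  # all figures regenerable headlessly
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy import stats

from .kinetics import (
    AnalysisConfig,
    KineticsSummary,
    detect_paralysis,
    detect_reversions,
    flag_outliers,
    smooth_trace,
    summarize_kinetics,
)
from .signals import FrequencyTrace, read_trace

__all__ = [
    "CohortMatrix",
    "assemble_cohort",
    "compare_reversion_incidence",
    "genotype_mean_traces",
    "population_swip",
    "render_heatmap",
    "summarize_cohort",
    "summarize_genotypes",
    "binned_frequency_histogram",
]

GRID_STEP_S = 1.0  # common resampling grid for the data matrix
DURATION_TOLERANCE = 0.05  # fractional mismatch in trace durations tolerated


@dataclass
class CohortMatrix:
    """Animals × time frequency matrix with genotype annotation.

    Rows hold the smoothed, resampled traces of *all* animals; ``included``
    marks those passing the outlier screen.  Excluded animals stay in the
    matrix (logged, never deleted) but are skipped by every downstream
    computation.
    """

    matrix: np.ndarray  # (n_animals, n_times), Hz
    times: np.ndarray  # shared grid, s
    annotation: pd.DataFrame  # columns: animal_id, genotype
    included: np.ndarray  # (n_animals,) bool
    config: AnalysisConfig = field(default_factory=AnalysisConfig)

    def __post_init__(self) -> None:
        if self.matrix.shape[0] != len(self.annotation):
            raise ValueError("matrix row count must equal annotation rows")
        if self.matrix.shape[1] != self.times.size:
            raise ValueError("matrix column count must equal time grid length")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("time grid must be strictly increasing")

    @property
    def excluded_ids(self) -> list[str]:
        return self.annotation.loc[~self.included, "animal_id"].tolist()

    def trace(self, row: int) -> FrequencyTrace:
        return FrequencyTrace(self.times, np.clip(self.matrix[row], 0.0, None))

    def genotypes(self) -> list[str]:
        seen: list[str] = []
        for g in self.annotation["genotype"]:
            if g not in seen:
                seen.append(g)
        return seen


def assemble_cohort(
    annotation: str | Path | pd.DataFrame,
    base_dir: str | Path | None = None,
    config: AnalysisConfig = AnalysisConfig(),
) -> CohortMatrix:
    """Build the cohort matrix from trace files listed in an annotation TSV.

    Each trace is smoothed with the configured window and linearly
    interpolated onto a shared 1 s grid spanning the common time range;
    animals failing the modified z-score screen are marked excluded.
    """
    if isinstance(annotation, (str, Path)):
        ann_path = Path(annotation)
        ann = pd.read_csv(ann_path, sep="\t")
        if base_dir is None:
            base_dir = ann_path.parent
    else:
        ann = annotation.copy()
        if base_dir is None:
            base_dir = Path(".")
    required = {"animal_id", "genotype", "file"}
    if not required.issubset(ann.columns):
        raise ValueError(f"annotation must have columns {sorted(required)}")
    dupes = ann["animal_id"][ann["animal_id"].duplicated()].tolist()
    if dupes:
        raise ValueError(f"duplicate animal_id(s): {dupes}")

    traces: list[FrequencyTrace] = []
    for row in ann.itertuples():
        path = Path(base_dir) / row.file
        if not path.exists():
            raise FileNotFoundError(f"annotation references missing trace file: {path}")
        traces.append(smooth_trace(read_trace(path), config.smooth_window_s))

    durations = np.array([t.duration for t in traces])
    if durations.max() - durations.min() > DURATION_TOLERANCE * durations.max():
        lo = ann["file"].iloc[int(durations.argmin())]
        hi = ann["file"].iloc[int(durations.argmax())]
        raise ValueError(
            f"trace durations differ beyond tolerance: {lo} ({durations.min():.1f} s) "
            f"vs {hi} ({durations.max():.1f} s)"
        )

    t0 = max(t.times[0] for t in traces)
    t1 = min(t.times[-1] for t in traces)
    grid = np.arange(t0, t1 + 1e-9, GRID_STEP_S)
    matrix = np.stack([np.interp(grid, t.times, t.frequency) for t in traces])
    flags = flag_outliers([m.mean() for m in matrix], config.outlier_z_threshold)
    return CohortMatrix(matrix, grid, ann[["animal_id", "genotype"]].reset_index(drop=True),
                        included=~flags, config=config)


def summarize_cohort(cohort: CohortMatrix) -> list[KineticsSummary]:
    """Kinetic summary of every included animal, in annotation order."""
    out = []
    for i in np.flatnonzero(cohort.included):
        out.append(
            summarize_kinetics(
                cohort.trace(i), cohort.config, animal_id=cohort.annotation["animal_id"].iloc[i]
            )
        )
    return out


# --------------------------------------------------------------------------
# heat map
# --------------------------------------------------------------------------

def heatmap_row_order(cohort: CohortMatrix, summaries: list[KineticsSummary]) -> list[str]:
    """Bottom-to-top row order of the heat map.

    Within each genotype block paralyzers sit below non-paralyzers, sorted by
    latency ascending from the bottom (fastest paralyzers lowest);
    non-paralyzers are sub-ordered by mean frequency descending.  Ties break
    lexicographically on animal_id for reproducibility.
    """
    by_id = {s.animal_id: s for s in summaries}
    means = {
        cohort.annotation["animal_id"].iloc[i]: float(cohort.matrix[i].mean())
        for i in range(len(cohort.annotation))
    }
    order: list[str] = []
    for genotype in cohort.genotypes():
        sel = (cohort.annotation["genotype"] == genotype) & pd.Series(cohort.included)
        ids = cohort.annotation.loc[sel.to_numpy(), "animal_id"].tolist()
        paralyzers = [a for a in ids if by_id[a].paralyzed]
        swimmers = [a for a in ids if not by_id[a].paralyzed]
        paralyzers.sort(key=lambda a: (by_id[a].latency_to_paralyze, a))
        swimmers.sort(key=lambda a: (-means[a], a))
        order.extend(paralyzers + swimmers)
    return order


def render_heatmap(
    cohort: CohortMatrix,
    summaries: list[KineticsSummary] | None = None,
    out_path: str | Path | None = None,
) -> tuple[list[str], plt.Figure]:
    """Paralysis-ordered cohort heat map.

    Color runs red (high frequency) to green (low) on a scale shared across
    genotypes.  Returns the bottom-to-top row order (as data, for testing)
    and the figure; writes PNG and PDF when ``out_path`` is given (suffix
    replaced per format).
    """
    if len(cohort.annotation) == 0:
        raise ValueError("empty cohort")
    if summaries is None:
        summaries = summarize_cohort(cohort)
    order = heatmap_row_order(cohort, summaries)
    idx = {a: i for i, a in enumerate(cohort.annotation["animal_id"])}
    data = cohort.matrix[[idx[a] for a in order]]

    fig, ax = plt.subplots(figsize=(8, max(2, 0.12 * len(order) + 1)))
    im = ax.imshow(
        data,
        aspect="auto",
        origin="lower",  # first-ordered (fastest paralyzer) row at the bottom
        cmap="RdYlGn_r",
        vmin=0.0,
        vmax=max(float(cohort.matrix.max()), 1e-9),
        extent=(cohort.times[0], cohort.times[-1], 0, len(order)),
        interpolation="nearest",
    )
    ax.set_xlabel("time (s)")
    ax.set_ylabel("animal (fastest paralyzers at bottom)")
    fig.colorbar(im, ax=ax, label="frequency (Hz)")
    if out_path is not None:
        out_path = Path(out_path)
        fig.savefig(out_path.with_suffix(".png"), dpi=150)
        fig.savefig(out_path.with_suffix(".pdf"))
    return order, fig


# --------------------------------------------------------------------------
# genotype summaries
# --------------------------------------------------------------------------

def _mean_sem(values: list[float]) -> tuple[float, float]:
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        return math.nan, math.nan
    sem = float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else math.nan
    return float(arr.mean()), sem


def summarize_genotypes(
    cohort: CohortMatrix, summaries: list[KineticsSummary] | None = None
) -> pd.DataFrame:
    """Per-genotype kinetic summary table (mean ± SEM columns).

    Latency is averaged over paralyzers; reversion metrics over revertants
    only; incidence = revertants / paralyzers, reported as NaN (not 0) for a
    genotype with no paralyzers.
    """
    if summaries is None:
        summaries = summarize_cohort(cohort)
    geno_of = dict(zip(cohort.annotation["animal_id"], cohort.annotation["genotype"]))
    rows = []
    for genotype in cohort.genotypes():
        subset = [s for s in summaries if geno_of[s.animal_id] == genotype]
        paralyzers = [s for s in subset if s.paralyzed]
        revertants = [s for s in paralyzers if s.revertant]
        max_mean, max_sem = _mean_sem([s.max_frequency for s in subset])
        lat_mean, lat_sem = _mean_sem([s.latency_to_paralyze for s in paralyzers])
        incidence = len(revertants) / len(paralyzers) if paralyzers else math.nan
        rf_mean, rf_sem = _mean_sem([s.reversion_frequency for s in revertants])
        rp_mean, rp_sem = _mean_sem([s.reversion_probability for s in revertants])
        tf_mean, tf_sem = _mean_sem([s.time_to_first_reversion for s in revertants])
        el_mean, el_sem = _mean_sem([s.average_reversion_event_length for s in revertants])
        rows.append(
            {
                "genotype": genotype,
                "n": len(subset),
                "n_paralyzed": len(paralyzers),
                "n_revertant": len(revertants),
                "max_frequency_hz": max_mean,
                "max_frequency_sem": max_sem,
                "latency_s": lat_mean,
                "latency_sem": lat_sem,
                "reversion_incidence": incidence,
                "reversion_frequency": rf_mean,
                "reversion_frequency_sem": rf_sem,
                "reversion_probability": rp_mean,
                "reversion_probability_sem": rp_sem,
                "time_to_first_reversion_s": tf_mean,
                "time_to_first_reversion_sem": tf_sem,
                "avg_reversion_event_length_s": el_mean,
                "avg_reversion_event_length_sem": el_sem,
            }
        )
    return pd.DataFrame(rows)


def genotype_mean_traces(cohort: CohortMatrix) -> pd.DataFrame:
    """Per-time-point mean frequency of each genotype's included animals."""
    data = {"time_s": cohort.times}
    for genotype in cohort.genotypes():
        sel = (cohort.annotation["genotype"] == genotype).to_numpy() & cohort.included
        data[genotype] = cohort.matrix[sel].mean(axis=0)
    return pd.DataFrame(data)


def binned_frequency_histogram(
    cohort: CohortMatrix, bin_width_hz: float = 0.25
) -> pd.DataFrame:
    """Pooled binned-frequency counts per genotype (histogram output)."""
    top = max(float(cohort.matrix.max()), bin_width_hz)
    edges = np.arange(0.0, top + bin_width_hz, bin_width_hz)
    out = {"bin_left_hz": edges[:-1], "bin_right_hz": edges[1:]}
    for genotype in cohort.genotypes():
        sel = (cohort.annotation["genotype"] == genotype).to_numpy() & cohort.included
        counts, _ = np.histogram(cohort.matrix[sel].ravel(), bins=edges)
        out[genotype] = counts
    return pd.DataFrame(out)


def plot_mean_traces(cohort: CohortMatrix, out_path: str | Path | None = None) -> plt.Figure:
    df = genotype_mean_traces(cohort)
    fig, ax = plt.subplots(figsize=(7, 4))
    for genotype in cohort.genotypes():
        ax.plot(df["time_s"], df[genotype], label=genotype)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("mean frequency (Hz)")
    ax.legend()
    if out_path is not None:
        out_path = Path(out_path)
        fig.savefig(out_path.with_suffix(".png"), dpi=150)
        fig.savefig(out_path.with_suffix(".pdf"))
    return fig


def plot_histogram(cohort: CohortMatrix, out_path: str | Path | None = None,
                   bin_width_hz: float = 0.25) -> plt.Figure:
    df = binned_frequency_histogram(cohort, bin_width_hz)
    fig, ax = plt.subplots(figsize=(7, 4))
    centers = (df["bin_left_hz"] + df["bin_right_hz"]) / 2
    width = bin_width_hz / (len(cohort.genotypes()) + 1)
    for k, genotype in enumerate(cohort.genotypes()):
        ax.bar(centers + k * width, df[genotype], width=width, label=genotype)
    ax.set_xlabel("frequency (Hz)")
    ax.set_ylabel("time points")
    ax.legend()
    if out_path is not None:
        out_path = Path(out_path)
        fig.savefig(out_path.with_suffix(".png"), dpi=150)
        fig.savefig(out_path.with_suffix(".pdf"))
    return fig


# --------------------------------------------------------------------------
# population scoring and incidence comparison
# --------------------------------------------------------------------------

def population_swip(cohort: CohortMatrix, at_time_s: float) -> dict[str, float]:
    """Fraction of animals paralyzed at a time point, per genotype.

    An animal counts as paralyzed at ``t`` iff ``t`` falls inside one of its
    qualifying sub-threshold runs and not inside a reversion event — a
    paralyzer mid-bout is scored swimming, matching by-eye population
    scoring of animals swimming / total animals at the assay endpoint.
    """
    dt = float(np.median(np.diff(cohort.times))) if cohort.times.size > 1 else 1.0
    if not (cohort.times[0] <= at_time_s <= cohort.times[-1] + dt):
        raise ValueError(
            f"at_time_s={at_time_s} outside trace span "
            f"[{cohort.times[0]}, {cohort.times[-1] + dt}]"
        )
    counts: dict[str, list[int]] = {}
    for i in np.flatnonzero(cohort.included):
        genotype = cohort.annotation["genotype"].iloc[i]
        trace = cohort.trace(i)
        call = detect_paralysis(trace, cohort.config)
        paralyzed_now = False
        if call.paralyzed and any(s <= at_time_s <= e for s, e in call.runs):
            events = detect_reversions(trace, call.latency, call.max_frequency, cohort.config)
            paralyzed_now = not any(s <= at_time_s <= e for s, e in events)
        counts.setdefault(genotype, []).append(int(paralyzed_now))
    return {g: float(np.mean(v)) for g, v in counts.items()}


def compare_reversion_incidence(
    group_a: tuple[int, int], group_b: tuple[int, int]
) -> tuple[float, float]:
    """Pearson chi-square (df=1, no continuity correction) on a 2×2 table of
    (revertant, non-revertant) counts for two groups.  Returns (χ², p)."""
    table = np.array([group_a, group_b], dtype=float)
    if table.shape != (2, 2) or np.any(table < 0):
        raise ValueError("expected two (revertant, non-revertant) count pairs")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("chi-square undefined: a table margin is zero")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)
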