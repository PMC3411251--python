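"""Generator behavior: CTMC event statistics, angle synthesis, cohorts."""

import hashlib
import json
from pathlib import Path

import numpy as np
import pytest
from scipy import stats

import swipkit as sk
from swipkit.synthgen import read_ground_truth


def quiet_params(**kw):
    base = dict(label="test", base_freq_mean=1.0, base_freq_sd=0.0,
                noise_sd_angle=0.0, noise_sd_freq=0.0)
    base.update(kw)
    return sk.GenotypeParams(**base)


class TestSampleTrace:
    def test_zero_hazard_yields_constant_trace(self):
        params = quiet_params(base_freq_mean=1.76)
        spec = sk.RecordingSpec(duration=60, frame_rate=15, seed=0)
        trace, truth = sk.sample_trace(params, spec, 3)
        assert truth.onset is None
        assert truth.reversion_intervals == []
        np.testing.assert_allclose(trace.frequency, 1.76)

    def test_onset_times_are_exponential(self):
        """Mean onset ~ 1/hazard and KS agreement with Exponential(hazard)."""
        params = quiet_params(paralysis_hazard=0.01)
        spec = sk.RecordingSpec(duration=2000, frame_rate=5, seed=0)
        onsets = []
        for i in range(1000):
            _, truth = sk.sample_trace(params, spec, 1000 + i)
            if truth.onset is not None:
                onsets.append(truth.onset)
        onsets = np.array(onsets)
        assert onsets.size >= 995  # P(onset > 2000 s) is ~2e-9
        se = 100.0 / np.sqrt(onsets.size)
        assert abs(onsets.mean() - 100.0) < 2 * se
        assert stats.kstest(onsets, "expon", args=(0, 100.0)).pvalue > 0.01

    def test_preset_max_frequency_ordering(self):
        """Wild-type-like cohorts out-swim the severe mutant-like preset."""
        spec = sk.RecordingSpec(duration=30, frame_rate=15, seed=0)
        means = {}
        for name in ("n2", "vt29"):
            maxima = [
                sk.sample_trace(sk.PRESETS[name], spec, 900 + i)[0].frequency.max()
                for i in range(30)
            ]
            means[name] = np.mean(maxima)
        assert means["n2"] > means["vt29"]

    def test_reversion_incidence_monotone_in_rate(self):
        spec = sk.RecordingSpec(duration=600, frame_rate=5, seed=0)
        fractions = []
        for rate in (2e-4, 1e-3, 5e-3):
            params = quiet_params(paralysis_hazard=1 / 100, reversion_rate=rate,
                                  reversion_exit_rate=0.25)
            revertant = []
            for i in range(500):
                _, truth = sk.sample_trace(params, spec, 7_000 + i)
                if truth.onset is not None:
                    revertant.append(truth.revertant)
            fractions.append(np.mean(revertant))
        assert fractions[0] < fractions[1] < fractions[2]

    def test_ground_truth_intervals_disjoint_and_after_onset(self):
        params = quiet_params(paralysis_hazard=1 / 50, reversion_rate=5e-3,
                              reversion_exit_rate=0.2)
        spec = sk.RecordingSpec(duration=600, frame_rate=5, seed=0)
        checked = 0
        for i in range(100):
            _, truth = sk.sample_trace(params, spec, i)
            prev_end = truth.onset
            for start, end in truth.reversion_intervals:
                assert truth.onset <= start <= end <= spec.duration
                assert start >= prev_end
                prev_end = end
                checked += 1
        assert checked > 20

    def test_nonfinite_parameter_rejected_with_field_name(self):
        with pytest.raises(ValueError, match="paralysis_hazard"):
            quiet_params(paralysis_hazard=float("nan"))

    def test_frame_rate_must_oversample_base_frequency(self):
        params = quiet_params(base_freq_mean=1.76)
        with pytest.raises(ValueError, match="frame_rate"):
            sk.sample_trace(params, sk.RecordingSpec(duration=10, frame_rate=5), 0)


class TestAnglesFromFrequency:
    def test_constant_frequency_gives_pure_sinusoid(self):
        params = quiet_params()
        spec = sk.RecordingSpec(duration=20, frame_rate=15, seed=0)
        trace = sk.FrequencyTrace(spec.times, np.ones(spec.n_frames))
        angles = sk.angles_from_frequency(trace, params, spec)
        t = spec.times
        np.testing.assert_allclose(angles.phase, t, atol=1e-12)
        for j, off in enumerate([0.0, 0.8, 1.6]):
            np.testing.assert_allclose(
                angles.angles[:, j], 0.6 * np.sin(2 * np.pi * t + off), atol=1e-12
            )

    def test_piecewise_frequency_changes_extrema_spacing(self):
        """1.5 Hz → 0.1 Hz: half-periods jump from 1/3 s to 5 s."""
        from scipy.signal import find_peaks

        params = quiet_params(base_freq_mean=1.5)
        spec = sk.RecordingSpec(duration=150, frame_rate=15, seed=0)
        freq = np.where(spec.times < 100, 1.5, 0.1)
        angles = sk.angles_from_frequency(
            sk.FrequencyTrace(spec.times, freq), params, spec
        )
        x = angles.angles[:, 0]
        peaks = np.sort(np.concatenate(
            [find_peaks(x)[0], find_peaks(-x)[0]])) / spec.frame_rate
        early = np.diff(peaks[peaks < 95])
        late = np.diff(peaks[peaks > 105])
        assert np.allclose(early, 1 / 3, atol=0.1)
        assert np.allclose(late, 5.0, atol=0.5)

    def test_phase_unwrapping_oracle_recovers_frequency(self):
        """Quadrature phase reconstruction returns the input trace exactly."""
        params = quiet_params(base_freq_mean=1.3)
        spec = sk.RecordingSpec(duration=30, frame_rate=15, seed=0)
        trace = sk.FrequencyTrace(spec.times, np.full(spec.n_frames, 1.3))
        angles = sk.angles_from_frequency(trace, params, spec)
        a, psi = 0.6, 0.8
        s0 = angles.angles[:, 0] / a  # sin θ
        s1 = angles.angles[:, 1] / a  # sin(θ + ψ)
        c0 = (s1 - s0 * np.cos(psi)) / np.sin(psi)  # cos θ
        theta = np.unwrap(np.arctan2(s0, c0))
        f_rec = np.gradient(theta, spec.times) / (2 * np.pi)
        assert np.abs(f_rec - 1.3).max() < 1e-9

    def test_near_zero_amplitude_flagged_degenerate(self):
        params = quiet_params(angle_amplitude=1e-12)
        spec = sk.RecordingSpec(duration=10, frame_rate=15, seed=0)
        trace = sk.FrequencyTrace(spec.times, np.ones(spec.n_frames))
        angles = sk.angles_from_frequency(trace, params, spec)
        assert angles.degenerate
        np.testing.assert_allclose(angles.angles, 0.0, atol=1e-10)

    def test_zero_amplitude_is_invalid(self):
        with pytest.raises(ValueError, match="angle_amplitude"):
            quiet_params(angle_amplitude=0.0)

    def test_super_nyquist_trace_rejected(self):
        params = quiet_params()
        spec = sk.RecordingSpec(duration=10, frame_rate=15, seed=0)
        trace = sk.FrequencyTrace(spec.times, np.full(spec.n_frames, 7.4))
        trace.frequency[5] = 8.0
        with pytest.raises(ValueError, match="Nyquist"):
            sk.angles_from_frequency(trace, params, spec)


class TestRenderMovie:
    def test_straight_body_centroid_matches_center(self):
        spec = sk.RecordingSpec(duration=1, frame_rate=5, seed=0)
        angles = sk.AngleSeries(spec.times, np.zeros((spec.n_frames, 3)), 5.0)
        movie, spines = sk.render_movie(angles)
        ys, xs = np.nonzero(movie[0])
        assert abs(xs.mean() - spines[0].center_x) <= 1.0
        assert abs(ys.mean() - spines[0].center_y) <= 1.0

    def test_mirrored_angles_reflect_the_mask(self):
        spec = sk.RecordingSpec(duration=1, frame_rate=5, seed=0)
        base = np.tile([0.4, -0.3, 0.2], (spec.n_frames, 1))
        m1, _ = sk.render_movie(sk.AngleSeries(spec.times, base, 5.0))
        m2, _ = sk.render_movie(sk.AngleSeries(spec.times, -base, 5.0))
        # center sits at x = 47.5, so the mirror is an exact column reversal
        np.testing.assert_array_equal(m2[0], m1[0][:, ::-1])

    def test_foreground_area_nearly_constant(self):
        """Inextensible body: per-frame area varies < 10%."""
        params = quiet_params(base_freq_mean=1.5)
        spec = sk.RecordingSpec(duration=20, frame_rate=15, seed=0)
        trace = sk.FrequencyTrace(spec.times, np.full(spec.n_frames, 1.5))
        angles = sk.angles_from_frequency(trace, params, spec)
        movie, _ = sk.render_movie(angles)
        areas = movie.sum(axis=(1, 2))
        assert areas.max() - areas.min() < 0.1 * areas.mean()

    def test_out_of_bounds_spine_names_frame(self):
        spec = sk.RecordingSpec(duration=1, frame_rate=5, seed=0)
        angles = sk.AngleSeries(spec.times, np.zeros((spec.n_frames, 3)), 5.0)
        geom = sk.MovieGeometry(image_size=96, center=(2.0, 48.0))
        with pytest.raises(ValueError, match="frame 0"):
            sk.render_movie(angles, geom)

    def test_movie_io_roundtrip(self, tmp_path):
        spec = sk.RecordingSpec(duration=1, frame_rate=5, seed=0)
        angles = sk.AngleSeries(spec.times, np.zeros((spec.n_frames, 3)), 5.0)
        movie, _ = sk.render_movie(angles)
        for name in ("movie.tif", "frames"):
            sk.write_movie(movie, tmp_path / name)
            np.testing.assert_array_equal(sk.read_movie(tmp_path / name), movie)


def _tree_hash(root: Path) -> str:
    digest = hashlib.sha256()
    for f in sorted(root.rglob("*")):
        if f.is_file():
            digest.update(f.relative_to(root).as_posix().encode())
            digest.update(f.read_bytes())
    return digest.hexdigest()


class TestMakeCohort:
    spec = sk.RecordingSpec(duration=60, frame_rate=15, seed=5, n_animals_per_genotype=3)

    def genos(self):
        return [quiet_params(label="a", paralysis_hazard=1 / 30),
                quiet_params(label="b")]

    def test_file_counts_and_annotation(self, tmp_path):
        ann = sk.make_cohort(self.genos(), self.spec, tmp_path / "c")
        assert len(ann) == 6
        assert len(list((tmp_path / "c" / "traces").glob("*.csv"))) == 6
        assert set(ann["genotype"]) == {"a", "b"}

    def test_same_seed_is_byte_identical(self, tmp_path):
        sk.make_cohort(self.genos(), self.spec, tmp_path / "c1")
        sk.make_cohort(self.genos(), self.spec, tmp_path / "c2")
        assert _tree_hash(tmp_path / "c1") == _tree_hash(tmp_path / "c2")

    def test_animals_draw_distinct_onsets(self, tmp_path):
        spec = sk.RecordingSpec(duration=600, frame_rate=5, seed=5,
                                n_animals_per_genotype=6)
        sk.make_cohort([quiet_params(label="a", paralysis_hazard=1 / 50)],
                       spec, tmp_path / "c")
        truth = read_ground_truth(tmp_path / "c" / "ground_truth.json")
        onsets = [v.onset for v in truth.values() if v.onset is not None]
        assert len(set(onsets)) == len(onsets) >= 4

    def test_existing_directory_refused_without_overwrite(self, tmp_path):
        sk.make_cohort(self.genos(), self.spec, tmp_path / "c")
        with pytest.raises(FileExistsError):
            sk.make_cohort(self.genos(), self.spec, tmp_path / "c")
        sk.make_cohort(self.genos(), self.spec, tmp_path / "c", overwrite=True)

    def test_duplicate_labels_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="unique"):
            sk.make_cohort([quiet_params(label="a"), quiet_params(label="a")],
                           self.spec, tmp_path / "c")

    def test_ground_truth_file_round_trips(self, tmp_path):
        sk.make_cohort(self.genos(), self.spec, tmp_path / "c")
        raw = json.loads((tmp_path / "c" / "ground_truth.json").read_text())
        parsed = read_ground_truth(tmp_path / "c" / "ground_truth.json")
        assert set(raw) == set(parsed)
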