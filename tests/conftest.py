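import numpy as np
import pytest
from hypothesis import settings as hypothesis_settings

import swipkit as sk

hypothesis_settings.register_profile("deterministic", derandomize=True)
hypothesis_settings.load_profile("deterministic")


@pytest.fixture
def tone_series():
    """Factory for noise-free sinusoidal joint-angle series."""

    def make(freq_hz, frame_rate=15.0, duration=60.0, amplitude=0.6,
             offsets=(0.0, 0.8, 1.6)):
        t = np.arange(int(round(duration * frame_rate))) / frame_rate
        ang = np.stack(
            [amplitude * np.sin(2 * np.pi * freq_hz * t + o) for o in offsets], axis=1
        )
        return sk.AngleSeries(t, ang, frame_rate)

    return make


@pytest.fixture(scope="session")
def rendered_movie():
    """A 10 s noise-free 1.0 Hz rendered movie with its ground-truth spines."""
    spec = sk.RecordingSpec(duration=10.0, frame_rate=15.0, seed=0)
    params = sk.GenotypeParams(
        label="clean", base_freq_mean=1.0, base_freq_sd=0.0,
        noise_sd_angle=0.0, noise_sd_freq=0.0,
    )
    trace = sk.FrequencyTrace(spec.times, np.full(spec.n_frames, 1.0))
    angles = sk.angles_from_frequency(trace, params, spec)
    geometry = sk.MovieGeometry()
    movie, spines = sk.render_movie(angles, geometry)
    return {"movie": movie, "spines": spines, "angles": angles, "geometry": geometry}


def make_cohort_matrix(traces, genotypes, ids=None, config=None):
    """Assemble a CohortMatrix directly from in-memory trace rows."""
    config = config or sk.AnalysisConfig()
    times = traces[0].times
    matrix = np.stack([t.frequency for t in traces])
    import pandas as pd

    ids = ids or [f"a{i:02d}" for i in range(len(traces))]
    ann = pd.DataFrame({"animal_id": ids, "genotype": genotypes})
    return sk.CohortMatrix(matrix, times, ann, np.ones(len(traces), dtype=bool), config)


@pytest.fixture
def cohort_builder():
    return make_cohort_matrix
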