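import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_feature_table():
    """Normalized features from a 20-session synthetic dataset (300 vectors)."""
    from piezopose import generate_dataset
    from piezopose.pipeline import featurize_traces

    traces = generate_dataset(20, subject_variation=0.10, seed=123)
    return featurize_traces(traces, normalization="dataset")


@pytest.fixture()
def noise_free_sweep():
    """Exact model output on a 40-point strain grid, known parameters."""
    from piezopose import PiezoParams, StrainSweep, resistance

    params = PiezoParams(a=0.8, c=0.04, d=5e5)
    eps = np.geomspace(1e-3, 0.5, 40)
    return StrainSweep(eps, resistance(eps, params)), params
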