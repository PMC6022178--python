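"""Acquisition-chain simulator: sampling, divider physics, noise, determinism."""

import numpy as np
import pytest

from piezopose import (AcquisitionError, CircuitConfig, NoiseConfig,
                       SessionPlan, default_plan, default_sensor,
                       generate_dataset, posture_strain, simulate_session)
from piezopose.acquisition import DEFAULT_STRAIN_MAP, _trailing_mean
from piezopose.sensor import critical_strain

QUIET = NoiseConfig(jitter_sd=0.0, meas_sd_counts=0.0, seed=0)


class TestPostureStrain:
    def test_default_mapping(self):
        assert posture_strain("normal") == 0.01
        assert posture_strain("severe_hunchback") == 0.09

    def test_mapping_override(self):
        assert posture_strain("severe_hunchback",
                              {"severe_hunchback": 0.12}) == 0.12

    def test_unknown_label(self):
        with pytest.raises(AcquisitionError):
            posture_strain("slouching")

    def test_default_mapping_monotone_in_severity(self):
        strains = [posture_strain(p) for p in
                   ("normal", "slight_hunchback", "severe_hunchback")]
        assert strains[0] < strains[1] < strains[2]
        assert all(0 < s <= 0.10 for s in strains)  # nominal design range


class TestSessionPlan:
    def test_three_postures_ten_seconds(self):
        assert default_plan().duration_s == 30.0

    def test_rejects_empty_or_bad_segments(self):
        with pytest.raises(AcquisitionError):
            SessionPlan([])
        with pytest.raises(AcquisitionError):
            SessionPlan([("normal", -1.0)])
        with pytest.raises(AcquisitionError):
            SessionPlan([("limbo", 10.0)])


class TestSimulateSession:
    def test_sample_count_three_by_ten_seconds(self):
        trace = simulate_session(default_plan(), noise=NoiseConfig(seed=1))
        assert len(trace) == 1500          # 3 postures x 10 s x 50 Hz
        # 500 samples carry each posture's label
        labels, counts = np.unique(trace.labels, return_counts=True)
        assert set(counts) == {500}

    def test_counts_within_adc_range(self):
        trace = simulate_session(default_plan(),
                                 noise=NoiseConfig(meas_sd_counts=50.0, seed=2))
        assert trace.counts.min() >= 0
        assert trace.counts.max() <= 1023
        assert trace.counts.dtype.kind == "i"

    def test_constant_posture_constant_after_warmup(self):
        plan = SessionPlan([("normal", 10.0)], transition_s=0.0)
        trace = simulate_session(plan, noise=QUIET)
        warm = trace.counts[100:]          # rolling window is 2 s = 100 samples
        assert np.all(warm == warm[0])

    def test_higher_strain_gives_higher_counts(self):
        # postures sit above the critical strain: more strain -> lower sensor
        # resistance -> larger divider fraction on the fixed leg
        sensor = default_sensor()
        assert critical_strain(sensor) < DEFAULT_STRAIN_MAP["normal"]
        means = {}
        for label in ("normal", "severe_hunchback"):
            plan = SessionPlan([(label, 10.0)], transition_s=0.0)
            trace = simulate_session(plan, noise=QUIET)
            means[label] = trace.counts[100:].mean()
        assert means["normal"] < means["severe_hunchback"]

    def test_same_seed_identical_trace(self):
        a = simulate_session(default_plan(), noise=NoiseConfig(seed=11))
        b = simulate_session(default_plan(), noise=NoiseConfig(seed=11))
        np.testing.assert_array_equal(a.counts, b.counts)

    def test_noise_free_chain_ignores_seed(self):
        a = simulate_session(default_plan(),
                             noise=NoiseConfig(0.0, 1.0, 0.0, seed=1))
        b = simulate_session(default_plan(),
                             noise=NoiseConfig(0.0, 1.0, 0.0, seed=999))
        np.testing.assert_array_equal(a.counts, b.counts)

    def test_measurement_noise_autocorrelation_flat_beyond_window(self):
        # white count noise smoothed by a 100-sample trailing mean must be
        # uncorrelated at lags beyond the window
        plan = SessionPlan([("normal", 60.0)], transition_s=0.0)
        trace = simulate_session(
            plan, noise=NoiseConfig(jitter_sd=0.0, meas_sd_counts=20.0, seed=3))
        x = trace.counts[200:].astype(float)
        x -= x.mean()
        lag = 150
        rho = np.dot(x[:-lag], x[lag:]) / np.dot(x, x)
        assert abs(rho) < 0.1

    def test_csv_round_trip(self, tmp_path):
        trace = simulate_session(default_plan(), noise=NoiseConfig(seed=5))
        path = tmp_path / "trace.csv"
        trace.to_csv(path)
        from piezopose.acquisition import RawTrace
        back = RawTrace.from_csv(path)
        np.testing.assert_array_equal(back.counts, trace.counts)
        assert list(back.labels) == list(trace.labels)


class TestTrailingMean:
    def test_constant_is_fixed_point(self):
        x = np.full(300, 7.0)
        np.testing.assert_allclose(_trailing_mean(x, 100), x)

    def test_warmup_uses_available_samples(self):
        x = np.array([2.0, 4.0, 6.0])
        np.testing.assert_allclose(_trailing_mean(x, 100), [2.0, 3.0, 4.0])


class TestGenerateDataset:
    def test_session_count_and_reproducibility(self):
        a = generate_dataset(5, subject_variation=0.1, seed=42)
        b = generate_dataset(5, subject_variation=0.1, seed=42)
        assert len(a) == 5
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.counts, tb.counts)

    def test_zero_variation_sessions_differ_only_by_noise_seed(self):
        quiet = NoiseConfig(jitter_sd=0.0, meas_sd_counts=0.0, seed=0)
        traces = generate_dataset(3, subject_variation=0.0, seed=1, noise=quiet)
        for tr in traces[1:]:
            np.testing.assert_array_equal(tr.counts, traces[0].counts)

    def test_rejects_bad_arguments(self):
        with pytest.raises(AcquisitionError):
            generate_dataset(0)
        with pytest.raises(AcquisitionError):
            generate_dataset(1, subject_variation=-0.1)
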