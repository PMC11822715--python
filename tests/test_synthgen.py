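"""Synthetic-data generator: spectral content, spike ground truth, spectra."""

import numpy as np
import pytest
from scipy.signal import periodogram

import protospike as ps


def periodogram_slope(x):
    """Independent oracle: least-squares slope of log power vs log frequency."""
    f, p = periodogram(x)
    m = (f > 0) & (p > 0)
    return np.polyfit(np.log(f[m]), np.log(p[m]), 1)[0]


class TestPinkNoise:
    def test_rms_is_exact(self):
        x = ps.generate_pink_noise(10_000, beta=1.0, rms=0.37, seed=0)
        assert np.isclose(x.std(), 0.37, rtol=1e-12)

    def test_zero_rms_gives_silence(self):
        assert not np.any(ps.generate_pink_noise(100, 1.0, 0.0, seed=0))

    @pytest.mark.parametrize("beta,tol", [(0.0, 0.05), (1.0, 0.1)])
    def test_spectral_slope(self, beta, tol):
        x = ps.generate_pink_noise(100_000, beta=beta, rms=1.0, seed=3)
        assert abs(periodogram_slope(x) - (-beta)) < tol

    def test_deterministic_per_seed(self):
        a = ps.generate_pink_noise(1000, 1.0, 1.0, seed=9)
        b = ps.generate_pink_noise(1000, 1.0, 1.0, seed=9)
        c = ps.generate_pink_noise(1000, 1.0, 1.0, seed=10)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    @pytest.mark.parametrize("kwargs", [{"n": 1}, {"rms": -0.1}])
    def test_invalid_arguments(self, kwargs):
        args = {"n": 100, "beta": 1.0, "rms": 1.0, "seed": 0, **kwargs}
        with pytest.raises(ValueError):
            ps.generate_pink_noise(**args)


class TestSpikeRecording:
    def test_periodic_constant_amplitude_limit(self):
        cfg = ps.RecordingConfig(duration=1000.0, sample_interval=1.0, isi_mean=100.0,
                                 isi_cv=0.0, amp_mean=1.0, amp_sd=0.0, noise_rms=0.0,
                                 seed=0)
        trace, truth = ps.generate_spike_recording(cfg)
        assert np.allclose(np.diff(truth.spike_times), 100.0)
        assert np.allclose(truth.spike_amplitudes, 1.0)

    def test_sample_mean_isi_close_to_generator_mean(self):
        isi = 7520.47
        cfg = ps.RecordingConfig(duration=502 * isi, isi_mean=isi, isi_cv=0.3,
                                 noise_rms=0.0, seed=11)
        _, truth = ps.generate_spike_recording(cfg)
        assert len(truth) > 400
        assert np.isclose(np.diff(truth.spike_times).mean(), isi, rtol=0.02)

    def test_ground_truth_on_grid_and_amplitudes_exact(self):
        cfg = ps.RecordingConfig(duration=5000.0, sample_interval=2.0, isi_mean=50.0,
                                 isi_cv=0.5, amp_mean=1.0, amp_sd=0.3, noise_rms=0.0,
                                 baseline=0.2, seed=4)
        trace, truth = ps.generate_spike_recording(cfg)
        idx = np.round(truth.spike_times / 2.0).astype(int)
        assert np.allclose(idx * 2.0, truth.spike_times)  # times on the grid
        assert np.allclose(trace.potential[idx] - 0.2, truth.spike_amplitudes)
        # with no noise, the global maximum is an injected spike
        assert trace.time[np.argmax(trace.potential)] in truth.spike_times

    def test_exponential_waveform_decays(self):
        cfg = ps.RecordingConfig(duration=500.0, isi_mean=100.0, isi_cv=0.0,
                                 amp_mean=1.0, amp_sd=0.0, noise_rms=0.0, seed=0)
        trace, truth = ps.generate_spike_recording(cfg, waveform="exp", waveform_tau=5.0)
        i = int(truth.spike_times[0])
        assert trace.potential[i] == pytest.approx(1.0)
        assert trace.potential[i + 1] == pytest.approx(np.exp(-1 / 5.0))

    def test_unresolvable_isi_rejected(self):
        with pytest.raises(ValueError, match="unresolvable"):
            ps.generate_spike_recording(
                ps.RecordingConfig(duration=10.0, sample_interval=1.0, isi_mean=0.5))

    def test_bit_identical_for_same_seed(self):
        cfg = ps.RecordingConfig(duration=2000.0, isi_mean=100.0, seed=13)
        t1, g1 = ps.generate_spike_recording(cfg)
        t2, g2 = ps.generate_spike_recording(cfg)
        assert np.array_equal(t1.potential, t2.potential)
        assert np.array_equal(g1.spike_times, g2.spike_times)


class TestControlTrace:
    @pytest.mark.parametrize("seed", [0, 1, 99])
    def test_fluctuations_below_reported_bound(self, seed):
        trace = ps.generate_control_trace(3600.0, 1.0, seed=seed)
        assert np.abs(trace.potential).max() < 0.05

    def test_detector_finds_nothing(self):
        trace = ps.generate_control_trace(7200.0, 1.0, seed=5)
        train = ps.detect_spikes(trace, ps.DetectorConfig(threshold=0.1))
        assert len(train) == 0

    def test_minimal_two_sample_trace(self):
        assert len(ps.generate_control_trace(1.0, 1.0, seed=0)) >= 2


class TestGeneratedSpectra:
    def test_noise_free_capacitance_matches_model(self):
        lp = ps.LogisticParams(1e-7, 1e-10, 500.0, 1.2)
        f = np.geomspace(1, 1e6, 40)
        spec = ps.generate_capacitance_spectrum(lp, f)
        assert np.array_equal(spec.capacitance, ps.logistic_capacitance(lp, f))

    def test_midpoint_and_low_frequency_plateau(self):
        lp = ps.LogisticParams(6.08961e-7, -6.0766e-10, 485.29332, 1.13381)
        assert ps.logistic_capacitance(lp, lp.x0) == pytest.approx((lp.A1 + lp.A2) / 2)
        # towards the lowest measured frequencies C approaches A1
        assert ps.logistic_capacitance(lp, 1e-3) == pytest.approx(lp.A1, rel=1e-6)

    def test_randles_resistive_limit(self):
        rp = ps.RandlesParams(Rs=10.0, Cdl=0.0, Rct=90.0, Zw=0.0)
        spec = ps.generate_impedance_spectrum(rp, np.geomspace(1, 1e4, 12))
        assert np.allclose(spec.Z, 100.0)

    def test_exp3p2_spectrum_low_frequency_limit(self):
        ep = ps.Exp3P2Params(9.16432, -1.13394e-6, -5.30867e-13)
        spec = ps.generate_impedance_spectrum(ep, np.array([1e-9, 1.0]))
        assert spec.Z[0].real == pytest.approx(np.exp(9.16432), rel=1e-12)
        assert spec.Z[0].imag == 0.0

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError, match="unknown impedance model"):
            ps.generate_impedance_spectrum("randles", np.array([1.0, 2.0]))

    def test_unsorted_grid_rejected(self):
        lp = ps.LogisticParams(1e-7, 0.0, 100.0, 1.0)
        with pytest.raises(ValueError):
            ps.generate_capacitance_spectrum(lp, np.array([10.0, 1.0]))
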