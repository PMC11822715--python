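"""Spike detection and amplitude/period statistics."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import protospike as ps


def impulse_trace(times, amps, dt=1.0, duration=None):
    duration = duration or (max(times) + 10 * dt)
    n = int(round(duration / dt)) + 1
    v = np.zeros(n)
    for t, a in zip(times, amps):
        v[int(round(t / dt))] = a
    return ps.VoltageTrace(np.arange(n) * dt, v)


def naive_stats(x):
    """Brute-force order statistics oracle: sort + linear interpolation."""
    x = np.sort(np.asarray(x, dtype=float))
    n = x.size

    def quantile(q):
        h = (n - 1) * q
        lo, hi = int(np.floor(h)), int(np.ceil(h))
        return x[lo] + (h - lo) * (x[hi] - x[lo])

    mean = x.sum() / n
    sd = np.sqrt(((x - mean) ** 2).sum() / (n - 1)) if n > 1 else float("nan")
    return quantile(0.25), quantile(0.5), quantile(0.75), mean, x[0], x[-1], sd


class TestDetector:
    def test_three_impulses_found_at_injected_times(self):
        trace = impulse_trace([100, 200, 300], [1.0, 1.0, 1.0])
        train = ps.detect_spikes(trace, ps.DetectorConfig(threshold=0.1))
        assert np.array_equal(train.times, [100, 200, 300])
        assert np.allclose(train.amplitudes, 1.0)

    def test_conflicting_peaks_keep_the_larger(self):
        # two peaks 30 ms apart with a 50 ms exclusion window
        dt = 0.01
        trace = impulse_trace([0.10, 0.13], [0.5, 0.8], dt=dt, duration=0.5)
        train = ps.detect_spikes(trace, ps.DetectorConfig(threshold=0.1, min_distance=0.05))
        assert len(train) == 1
        assert train.amplitudes[0] == pytest.approx(0.8)

    def test_subthreshold_events_ignored(self):
        trace = impulse_trace([100, 200], [0.05, 1.0])
        train = ps.detect_spikes(trace, ps.DetectorConfig(threshold=0.1))
        assert len(train) == 1

    def test_fixed_baseline_offset(self):
        trace = impulse_trace([50], [1.0])
        shifted = ps.VoltageTrace(trace.time, trace.potential + 3.0)
        cfg = ps.DetectorConfig(threshold=0.1, baseline=3.0)
        train = ps.detect_spikes(shifted, cfg)
        assert train.amplitudes[0] == pytest.approx(1.0)

    def test_running_median_baseline_tracks_drift(self):
        dt = 1.0
        n = 2001
        t = np.arange(n) * dt
        drift = 0.002 * t  # 4 mV drift across the record
        v = drift.copy()
        v[500] += 1.0
        v[1500] += 1.0
        cfg = ps.DetectorConfig(threshold=0.5, baseline_mode="median", median_window=201)
        train = ps.detect_spikes(ps.VoltageTrace(t, v), cfg)
        assert np.array_equal(train.times, [500.0, 1500.0])

    def test_soundness_on_noisy_trace(self):
        cfg = ps.RecordingConfig(duration=50_000.0, isi_mean=500.0, isi_cv=0.5,
                                 amp_mean=0.5, amp_sd=0.2, noise_rms=0.05, seed=21)
        trace, _ = ps.generate_spike_recording(cfg)
        det = ps.DetectorConfig(threshold=0.1, min_distance=10.0)
        train = ps.detect_spikes(trace, det)
        assert np.all(train.amplitudes >= det.threshold)
        assert np.all(np.diff(train.times) >= det.min_distance)

    def test_clean_train_perfect_precision_and_recall(self):
        cfg = ps.RecordingConfig(duration=100_000.0, isi_mean=200.0, isi_cv=0.4,
                                 amp_mean=1.0, amp_sd=0.2, noise_rms=0.0, seed=8)
        trace, truth = ps.generate_spike_recording(cfg)
        train = ps.detect_spikes(trace, ps.DetectorConfig(threshold=0.1, min_distance=1.0))
        assert np.array_equal(train.times, truth.spike_times)        # recall = 1
        assert len(train) == len(truth)                              # precision = 1
        assert np.allclose(train.amplitudes, truth.spike_amplitudes)

    def test_single_sample_trace_rejected(self):
        with pytest.raises(ValueError):
            ps.detect_spikes(ps.VoltageTrace([0.0], [0.0]))


class TestStatistics:
    def test_small_amplitude_example(self):
        train = ps.SpikeTrain([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        st_ = ps.spike_statistics(train)
        a = st_.amplitude
        assert (a.mean, a.median, a.min, a.max, a.sd) == (2.0, 2.0, 1.0, 3.0, 1.0)

    def test_period_absent_below_two_spikes(self):
        st_ = ps.spike_statistics(ps.SpikeTrain([5.0], [1.0]))
        assert st_.period is None
        assert st_.n_spikes == 1

    @given(st.lists(st.floats(min_value=-100, max_value=100,
                              allow_nan=False, allow_infinity=False),
                    min_size=2, max_size=1000))
    def test_statistics_match_naive_oracle(self, values):
        times = np.arange(1, len(values) + 1, dtype=float)
        st_ = ps.spike_statistics(ps.SpikeTrain(times, values))
        a = st_.amplitude
        q1, med, q3, mean, mn, mx, sd = naive_stats(values)
        assert a.q1 == pytest.approx(q1, abs=1e-9)
        assert a.median == pytest.approx(med, abs=1e-9)
        assert a.q3 == pytest.approx(q3, abs=1e-9)
        assert a.mean == pytest.approx(mean, abs=1e-9)
        assert (a.min, a.max) == (mn, mx)
        assert a.sd == pytest.approx(sd, abs=1e-9)
        assert a.min <= a.q1 <= a.median <= a.q3 <= a.max
        assert a.min <= a.mean <= a.max

    def test_mean_period_recovers_generator_mean(self):
        isi = 7520.47  # highest-dose regime
        cfg = ps.RecordingConfig(duration=502 * isi, isi_mean=isi, isi_cv=0.3,
                                 amp_mean=1.0, amp_sd=0.0, noise_rms=0.0, seed=2)
        trace, _ = ps.generate_spike_recording(cfg)
        train = ps.detect_spikes(trace, ps.DetectorConfig(threshold=0.1))
        st_ = ps.spike_statistics(train)
        assert st_.period.mean == pytest.approx(isi, rel=0.02)


class TestDoseComparison:
    def _stats(self, amp, per, seed):
        cfg = ps.RecordingConfig(duration=300 * per, isi_mean=per, isi_cv=0.3,
                                 amp_mean=amp, amp_sd=0.1, noise_rms=0.0, seed=seed)
        trace, _ = ps.generate_spike_recording(cfg)
        return ps.spike_statistics(ps.detect_spikes(trace, ps.DetectorConfig(0.1)))

    def test_single_dose_echoes_stats(self):
        s = ps.spike_statistics(ps.SpikeTrain([1.0, 2.0], [0.5, 0.7]))
        table = ps.dose_comparison({0.83: s})
        assert len(table) == 1
        assert table.loc[0, "mean_amplitude_mV"] == pytest.approx(0.6)

    def test_reported_dose_orderings_reproduced(self):
        table = ps.dose_comparison({
            c: self._stats(amp, per, seed=i)
            for i, (c, (amp, per)) in enumerate(ps.DOSE_REGIMES.items())
        })
        by_conc = table.set_index("concentration_mg_per_mL")
        periods = by_conc["mean_period_s"]
        assert periods[0.72] < periods[0.83] < periods[1.30]  # period grows with dose
        amps = by_conc["mean_amplitude_mV"]
        assert amps[0.72] > amps[1.30] > amps[0.83]

    def test_duplicate_and_empty_inputs_rejected(self):
        s = ps.spike_statistics(ps.SpikeTrain([1.0, 2.0], [0.5, 0.7]))
        with pytest.raises(ValueError, match="duplicate"):
            ps.dose_comparison([(0.72, s), (0.72, s)])
        with pytest.raises(ValueError):
            ps.dose_comparison({})
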