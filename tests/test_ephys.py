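import numpy as np
import pytest
from scipy import signal as spsig

from optofmri import ephys, simulate
from optofmri.protocol import make_protocol

from conftest import brute_force_rank_sum_p

FS = 1000.0


class TestPreprocess:
    def test_highpass_removes_dc(self):
        rng = np.random.default_rng(0)
        x = 100.0 + rng.normal(size=10000)
        out, fs = ephys.preprocess_lfp(x, FS, mode="slo")
        assert fs == FS
        assert abs(out.mean()) < 0.05

    def test_lowpass_passes_10hz(self):
        """10 Hz is far inside the 200 Hz Bessel pass band."""
        t = np.arange(0, 10, 1 / 40000)
        x = np.sin(2 * np.pi * 10 * t)
        out, fs = ephys.preprocess_lfp(x, 40000.0, mode="acquire")
        assert fs == 1000.0
        steady = out[2000:]  # skip causal-filter transient
        assert steady.max() == pytest.approx(1.0, rel=0.01)

    def test_highpass_attenuates_slow_drift_per_transfer_function(self):
        """0.2 Hz leakage equals the filter's stop-band gain at 0.2 Hz."""
        t = np.arange(0, 60, 1 / FS)
        x = np.sin(2 * np.pi * 0.2 * t)
        out, _ = ephys.preprocess_lfp(x, FS, mode="slo")
        sos = spsig.butter(4, 2.0, btype="high", fs=FS, output="sos")
        _, h = spsig.sosfreqz(sos, worN=[0.2], fs=FS)
        expected_gain = np.abs(h[0]) ** 2  # filtfilt applies the filter twice
        amp = np.abs(out[20000:40000]).max()
        assert amp == pytest.approx(expected_gain, rel=0.5)
        assert amp < 1e-3

    def test_cutoff_beyond_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            ephys.preprocess_lfp(np.zeros(100), 300.0, mode="acquire", lowpass_hz=200.0)


class TestSloDetector:
    def _spindle_trace(self, onsets_s, n_s=60.0, amp=10.0, env_s=0.5, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1.0, size=int(n_s * FS))
        n_env = int(env_s * FS)
        env = np.hanning(n_env)
        tt = np.arange(n_env) / FS
        for t0 in onsets_s:
            i = int(t0 * FS)
            x[i:i + n_env] += amp * env * np.sin(2 * np.pi * 10 * tt)
        return x

    def test_flat_trace_yields_no_events(self):
        assert ephys.detect_slos(np.zeros(10000), FS).size == 0

    def test_single_sample_impulse_fails_occupancy(self):
        """One sample above threshold is 1/500 = 0.2% of the active window: below 2%."""
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1.0, size=30000)
        x[15000] = 100.0
        assert ephys.detect_slos(x, FS).size == 0

    def test_injected_spindles_recovered_at_their_onsets(self):
        onsets = [21.0, 27.0, 33.0, 39.0]
        x = self._spindle_trace(onsets, seed=2)
        found = ephys.detect_slos(x, FS, analysis_window_s=(20.0, 40.0))
        assert found.size == len(onsets)
        # onset detected once the envelope ramps above threshold
        assert np.all(np.abs(found - np.array(onsets)) < 0.3)

    def test_amplitude_scale_invariance(self):
        x = self._spindle_trace([10.0, 20.0], seed=3)
        a = ephys.detect_slos(x, FS)
        b = ephys.detect_slos(1000.0 * x, FS)
        assert np.array_equal(a, b)

    def test_event_count_nonincreasing_in_threshold(self):
        x = self._spindle_trace([10.0, 20.0, 30.0], amp=8.0, seed=4)
        counts = [ephys.detect_slos(x, FS, k=k).size for k in (3, 4.5, 6, 8, 12, 30)]
        assert all(c1 >= c2 for c1, c2 in zip(counts, counts[1:]))

    def test_bursts_inside_quiet_window_merge_into_one_event(self):
        """Two bursts 300 ms apart violate the 500 ms quiet rule: one event."""
        x = self._spindle_trace([10.0, 10.3], seed=5)
        found = ephys.detect_slos(x, FS)
        assert found.size == 1
        x2 = self._spindle_trace([10.0, 11.0], seed=5)
        assert ephys.detect_slos(x2, FS).size == 2

    def test_window_longer_than_trace_rejected(self):
        with pytest.raises(ValueError, match="longer than"):
            ephys.detect_slos(np.zeros(100), FS, quiet_window_s=0.5)

    def test_recording_level_detection_with_ground_truth(self):
        spec = simulate.SloSpec(n_per_train=3, amplitude_sd=10.0, spacing_s=6.0,
                                spacing_jitter_s=0.2)
        rec, truth = simulate.gen_lfp(n_channels=2, n_trials=10, slo_spec=spec, seed=6)
        filt, fs = ephys.preprocess_lfp(rec.traces, rec.fs_hz, mode="slo")
        events = ephys.detect_slos_recording(
            simulate.LfpRecording(fs, filt, rec.stim_window_s)
        )
        assert len(events) == len(truth)


class TestIntervalStats:
    def test_simple_intervals(self):
        events = [simulate.SloEvent(0, 0, t) for t in (1.0, 3.0, 6.0)]
        s = ephys.slo_interval_stats(events)
        assert np.allclose(np.sort(s.intervals_s), [2.0, 3.0])
        assert s.mean_s == pytest.approx(2.5)

    def test_single_event_trials_flagged(self):
        events = [simulate.SloEvent(0, t, 5.0) for t in range(3)]
        with pytest.warns(UserWarning, match="undefined"):
            s = ephys.slo_interval_stats(events)
        assert np.isnan(s.mean_s) and s.n_intervals == 0

    def test_generator_spacing_recovered(self):
        spec = simulate.SloSpec(n_per_train=3, spacing_s=6.6, spacing_jitter_s=0.0,
                                amplitude_sd=10.0)
        rec, _ = simulate.gen_lfp(n_channels=1, n_trials=20, slo_spec=spec, seed=7)
        filt, fs = ephys.preprocess_lfp(rec.traces, rec.fs_hz, mode="slo")
        events = ephys.detect_slos_recording(
            simulate.LfpRecording(fs, filt, rec.stim_window_s)
        )
        s = ephys.slo_interval_stats(events)
        assert s.mean_s == pytest.approx(6.6, abs=0.1)


class TestSloCountComparison:
    def test_matches_enumeration(self):
        a = np.array([[2, 2, 2]])
        b = np.array([[0, 0, 0]])
        res = ephys.compare_slo_counts(a, b)[0]
        assert res.pvalue == pytest.approx(brute_force_rank_sum_p(a[0], b[0], "greater"))
        assert res.pvalue == pytest.approx(0.05)

    def test_identical_counts_not_significant(self):
        a = np.array([[1, 2, 3, 2]])
        res = ephys.compare_slo_counts(a, a)[0]
        assert res.pvalue >= 0.5

    def test_per_channel_results(self):
        a = np.array([[3, 4, 3, 4], [1, 1, 1, 1]])
        b = np.array([[0, 1, 0, 1], [1, 1, 1, 1]])
        results = ephys.compare_slo_counts(a, b)
        assert len(results) == 2
        assert results[0].pvalue < results[1].pvalue


class TestPsth:
    def test_homogeneous_poisson_normalizes_to_unity(self):
        prof = simulate.ConditionProfile("flat", baseline_rate_hz=20.0)
        trains = simulate.gen_spike_trains(prof, n_trials=300, seed=0)
        protocol = make_protocol(10.0, 0.30, train_duration_s=20.0)
        h = ephys.psth(trains, protocol, alignment="pulse", bin_s=0.005,
                       baseline_normalize=True)
        assert h.values.mean() == pytest.approx(1.0, abs=0.05)
        assert np.abs(h.values - 1.0).max() < 0.25

    def test_pulse_locked_peak_latency_bin(self):
        """Spikes at +8 ms after each pulse land in the [5, 10) ms bin."""
        protocol = make_protocol(10.0, 0.30)
        prof = simulate.ConditionProfile(
            "locked", baseline_rate_hz=2.0,
            pulse_locked=simulate.PulseLockedSpec(fidelity=1.0, latency_ms=8.0, jitter_ms=0.0),
        )
        trains = simulate.gen_spike_trains(prof, n_trials=20, protocol=protocol, seed=1)
        h = ephys.psth(trains, protocol, alignment="pulse", bin_s=0.005)
        assert h.peak_latency_bin_s == (0.005, 0.010)

    def test_no_spikes_gives_zero_histogram(self):
        protocol = make_protocol(10.0, 0.30)
        trains = [simulate.SpikeTrain(0, 0, "silent", np.array([]))]
        h = ephys.psth(trains, protocol, alignment="pulse", bin_s=0.005)
        assert np.all(h.values == 0)

    def test_train_alignment_covers_stim_window(self):
        protocol = make_protocol(10.0, 0.30)
        prof = simulate.ConditionProfile("flat", baseline_rate_hz=10.0)
        trains = simulate.gen_spike_trains(prof, n_trials=5, seed=2)
        h = ephys.psth(trains, protocol, alignment="train", bin_s=0.5)
        assert h.bin_edges_s[-1] == pytest.approx(20.0)

    def test_nondividing_bin_rejected(self):
        protocol = make_protocol(10.0, 0.30)
        trains = [simulate.SpikeTrain(0, 0, "x", np.array([1.0]))]
        with pytest.raises(ValueError, match="divide"):
            ephys.psth(trains, protocol, alignment="pulse", bin_s=0.003)


class TestFiringRateChange:
    def test_programmed_suppression_flagged_in_correct_bins(self):
        """Gain 0.3 in bins 2-3 is flagged as a decrease there and nowhere else."""
        hits = np.zeros(4)
        false = np.zeros(4)
        n_rep = 20
        for rep in range(n_rep):
            prof = simulate.ConditionProfile(
                "suppress", baseline_rate_hz=10.0, stim_gains=(1.0, 0.3, 0.3, 1.0)
            )
            trains = simulate.gen_spike_trains(prof, n_trials=17, seed=100 + rep)
            results = ephys.firing_rate_change_test(trains, alternative="two-sided")
            for r in results:
                if r.significant and r.direction == "decrease":
                    hits[r.bin_index] += 1
                elif r.significant:
                    false[r.bin_index] += 1
        assert hits[1] / n_rep >= 0.9 and hits[2] / n_rep >= 0.9
        assert hits[0] / n_rep <= 0.2 and hits[3] / n_rep <= 0.2

    def test_null_false_positive_rate_near_alpha(self):
        rng_seeds = range(300)
        flags = 0
        total = 0
        for s in rng_seeds:
            prof = simulate.ConditionProfile("flat", baseline_rate_hz=10.0)
            trains = simulate.gen_spike_trains(prof, n_trials=17, seed=1000 + s)
            results = ephys.firing_rate_change_test(trains, alternative="two-sided")
            flags += sum(r.significant for r in results)
            total += len(results)
        rate = flags / total
        assert 0.01 <= rate <= 0.10  # nominal alpha = 0.05

    def test_all_zero_differences(self):
        trains = [
            simulate.SpikeTrain(0, t, "empty", np.array([]), (20.0, 20.0, 20.0))
            for t in range(8)
        ]
        results = ephys.firing_rate_change_test(trains)
        assert all(r.pvalue == 1.0 and r.direction == "none" for r in results)


class TestBandPower:
    def test_pure_theta_line(self):
        t = np.arange(0, 10, 1 / FS)
        bp = ephys.eeg_band_power(np.sin(2 * np.pi * 6 * t), FS)
        assert bp["theta"] == pytest.approx(1.0, abs=1e-6)
        assert bp["delta"] + bp["alpha"] + bp["beta"] < 1e-6

    def test_white_noise_fractions_follow_bandwidth(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=200000)
        bp = ephys.eeg_band_power(x, FS)
        for name, (lo, hi) in ephys.DEFAULT_BANDS.items():
            assert bp[name] == pytest.approx((hi - lo) / (FS / 2), rel=0.15)

    def test_partition_fractions_sum_to_one(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=10000)
        bands = {"a": (0.0, 5.0), "b": (5.0, 100.0), "c": (100.0, 500.0)}
        bp = ephys.eeg_band_power(x, FS, bands=bands)
        assert sum(bp.fractions.values()) == pytest.approx(1.0, abs=1e-6)

    def test_band_beyond_nyquist_rejected(self):
        with pytest.raises(ValueError, match="within"):
            ephys.eeg_band_power(np.random.default_rng(2).normal(size=100), FS,
                                 bands={"bad": (100.0, 600.0)})
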