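import numpy as np
import pytest

import bonepore as bp
from bonepore.acoustic import (
    AEEvent,
    AERecord,
    bin_and_accumulate,
    detect_events,
    estimate_baseline_rms,
)

FS = 44000.0


def burst_waveform(onsets_s, duration_s=1.0, amp=1.0, width_s=0.003, fs=FS):
    """Deterministic noiseless bursts (rectangular sinusoid packets)."""
    n = int(duration_s * fs)
    w = np.zeros(n)
    m = int(width_s * fs)
    tt = np.arange(m) / fs
    for t0 in onsets_s:
        i0 = int(t0 * fs)
        w[i0 : i0 + m] += amp * np.sin(2 * np.pi * 5000.0 * tt + 0.3)
    return w


class TestDetection:
    def test_all_zero_waveform_yields_no_events(self):
        rec = AERecord(np.zeros(int(FS)), FS)
        assert detect_events(rec) == []

    def test_noiseless_bursts_counted_and_energies_exact(self):
        w = burst_waveform([0.1, 0.4, 0.8])
        rec = AERecord(w, FS)
        events = detect_events(rec, threshold_factor=5.0)
        assert len(events) == 3
        assert sum(e.energy_au for e in events) == pytest.approx((w**2).sum(), rel=1e-12)

    def test_close_bursts_merge_within_dead_time(self):
        w = burst_waveform([0.100, 0.1045])  # 1.5 ms gap < 2 ms dead time
        events = detect_events(AERecord(w, FS), dead_time_s=0.002)
        assert len(events) == 1
        w2 = burst_waveform([0.100, 0.150])
        assert len(detect_events(AERecord(w2, FS), dead_time_s=0.002)) == 2

    def test_pure_noise_false_positive_rate(self):
        # expected crossings of 5 x RMS are ~0.025/s for Gaussian noise
        total_events, total_time = 0, 0.0
        for seed in range(15):
            rec, truth = bp.generate_ae_waveform(
                bp.SyntheticAESpec(duration_s=2.0, event_rate_hz=0.0, seed=seed)
            )
            assert truth == []
            total_events += len(detect_events(rec, threshold_factor=5.0))
            total_time += rec.duration_s
        assert total_events / total_time * 10.0 < 1.0

    def test_injected_burst_recovery_at_factor_five(self):
        recovered, total = 0, 0
        for seed in range(5):
            spec = bp.SyntheticAESpec(
                duration_s=5.0, event_rate_hz=4.0, baseline_noise_sd=0.002,
                event_energy_scale=0.05, seed=seed,
            )
            rec, truth = bp.generate_ae_waveform(spec)
            events = detect_events(rec, threshold_factor=5.0)
            total += len(truth)
            for t in truth:
                if any(abs(e.onset_s - t.onset_s) < 0.005 for e in events):
                    recovered += 1
        assert total > 50
        assert recovered / total >= 0.95

    def test_threshold_in_noise_floor_warns(self):
        rec, _ = bp.generate_ae_waveform(
            bp.SyntheticAESpec(duration_s=1.0, event_rate_hz=0.0, seed=0)
        )
        with pytest.warns(UserWarning, match="noise floor"):
            detect_events(rec, threshold_factor=2.0, dead_time_s=0.0002)

    def test_baseline_uses_quietest_decile(self):
        # first 90% quiet, last 10% loud: baseline reflects the quiet part
        rng = np.random.default_rng(0)
        w = rng.normal(0, 0.001, int(FS))
        w[-int(0.1 * FS):] = rng.normal(0, 0.1, int(0.1 * FS))
        rms = estimate_baseline_rms(w, FS)
        assert rms == pytest.approx(0.001, rel=0.2)


class TestBinningAndCumulative:
    def make_events(self, onsets, energy=1.0):
        return [AEEvent(t, t + 0.001, 1.0, energy) for t in onsets]

    def test_uniform_events_one_per_bin(self):
        events = self.make_events([0.05 + 0.1 * k for k in range(10)])
        rec = AERecord(np.zeros(int(FS)), FS)
        out = bin_and_accumulate(events, rec, cutoff="none")
        assert [c for _, c, _ in out.bins] == [1] * 10
        assert out.cumulative_events == 10

    def test_strain_cutoff_counts_prefix(self):
        # events at 0.0, 0.1, ..., 0.9 s; strain hits 50% at 0.55 s
        events = self.make_events([0.1 * k for k in range(10)])
        rec = AERecord(
            np.zeros(int(FS)), FS,
            strain_time_s=np.array([0.0, 1.1]), strain=np.array([0.0, 1.0]),
        )
        out = bin_and_accumulate(events, rec, cutoff="strain_50pct")
        assert out.cutoff_time_s == pytest.approx(0.55)
        assert out.cumulative_events == 6

    def test_cumulative_energy_is_exact_sum(self):
        events = self.make_events([0.1, 0.2, 0.3], energy=0.123456789)
        rec = AERecord(np.zeros(int(FS)), FS)
        out = bin_and_accumulate(events, rec, cutoff="none")
        assert out.cumulative_energy_au == 3 * 0.123456789

    def test_pct95_cutoff_bounded_by_full_record(self):
        w = burst_waveform([0.1, 0.3, 0.5, 0.7, 0.9])
        t_force = np.linspace(0.0, 1.0, 200)
        force = np.where(t_force < 0.6, t_force / 0.6 * 50.0, 50.0 * (1 - (t_force - 0.6)))
        rec = AERecord(w, FS, force_time_s=t_force, force_n=force)
        events = detect_events(rec)
        full = bin_and_accumulate(events, rec, cutoff="none")
        cut = bin_and_accumulate(events, rec, cutoff="pct95_max_load")
        assert cut.cumulative_events <= full.cumulative_events
        assert cut.cumulative_energy_au <= full.cumulative_energy_au

    def test_post_peak_energy_excluded_at_pct95(self):
        # half the energy is injected after the force peak at 0.5 s
        w = burst_waveform([0.1, 0.2, 0.7, 0.8])
        t_force = np.linspace(0.0, 1.0, 200)
        force = 50.0 * np.where(t_force < 0.5, t_force / 0.5, 1.0 - (t_force - 0.5))
        rec = AERecord(w, FS, force_time_s=t_force, force_n=force)
        events = detect_events(rec)
        full = bin_and_accumulate(events, rec, cutoff="none")
        cut = bin_and_accumulate(events, rec, cutoff="pct95_max_load")
        assert cut.cumulative_energy_au < 0.55 * full.cumulative_energy_au

    def test_cutoff_beyond_record_warns_and_uses_full(self):
        events = self.make_events([0.1, 0.2])
        rec = AERecord(
            np.zeros(int(FS)), FS,
            strain_time_s=np.array([0.0, 4.0]), strain=np.array([0.0, 1.0]),
        )
        with pytest.warns(UserWarning, match="exceeds record duration"):
            out = bin_and_accumulate(events, rec, cutoff="strain_50pct")
        assert out.cumulative_events == 2

    def test_missing_channel_rejected(self):
        rec = AERecord(np.zeros(100), FS)
        with pytest.raises(ValueError, match="force channel"):
            bin_and_accumulate([], rec, cutoff="pct95_max_load")


class TestGeneratorStatistics:
    def test_zero_rate_gives_pure_noise(self):
        rec, truth = bp.generate_ae_waveform(
            bp.SyntheticAESpec(duration_s=1.0, event_rate_hz=0.0, seed=1)
        )
        assert truth == []

    def test_onsets_strictly_increasing(self):
        _, truth = bp.generate_ae_waveform(
            bp.SyntheticAESpec(duration_s=10.0, event_rate_hz=8.0, seed=3)
        )
        onsets = [t.onset_s for t in truth]
        assert all(a < b for a, b in zip(onsets, onsets[1:]))

    def test_poisson_event_count(self):
        # mean count over 120 seeded 10 s runs at 5 Hz should be 50
        # within 3 standard errors of the Poisson law
        counts = [
            len(
                bp.generate_ae_waveform(
                    bp.SyntheticAESpec(
                        duration_s=10.0, event_rate_hz=5.0,
                        baseline_noise_sd=0.0, seed=seed,
                    )
                )[1]
            )
            for seed in range(120)
        ]
        se = np.sqrt(50.0 / len(counts))
        assert abs(np.mean(counts) - 50.0) < 3 * se

    def test_deterministic_under_seed(self):
        spec = bp.SyntheticAESpec(duration_s=2.0, event_rate_hz=5.0, seed=42)
        r1, t1 = bp.generate_ae_waveform(spec)
        r2, t2 = bp.generate_ae_waveform(spec)
        assert np.array_equal(r1.waveform, r2.waveform)
        assert t1 == t2

    def test_high_energy_events_scaled(self):
        spec = bp.SyntheticAESpec(
            duration_s=20.0, event_rate_hz=10.0, baseline_noise_sd=0.0,
            high_energy_fraction=0.5, seed=6,
        )
        _, truth = bp.generate_ae_waveform(spec)
        lo = [t.energy_au for t in truth if not t.is_high_energy]
        hi = [t.energy_au for t in truth if t.is_high_energy]
        assert lo and hi
        ratios = np.array(hi) / np.mean(lo)
        assert ratios.min() >= 4.5 and ratios.max() <= 15.5
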