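import numpy as np
import pytest

from slopetrack.events import (
    detect_slow_waves,
    event_locked_slope,
    event_rate_by_state,
    trough_slope_by_state,
)
from slopetrack.simulate import gen_powerlaw_signal, gen_slow_waves
from slopetrack.spectral import Recording
from slopetrack.state_tracking import Hypnogram


from conftest import injected_recording, match_events  # noqa: E402


class TestDetection:
    def test_pure_40hz_signal_yields_no_events(self, fs):
        t = np.arange(int(60 * fs)) / fs
        rec = Recording(np.sin(2 * np.pi * 40.0 * t)[None, :], fs)
        with pytest.warns(UserWarning):
            assert detect_slow_waves(rec) == []

    def test_recall_and_precision_on_clean_injections(self, fs):
        rec, truth = injected_recording(fs)
        events = detect_slow_waves(rec)
        recall, precision = match_events(events, truth)
        assert recall >= 0.9
        assert precision >= 0.9

    def test_short_deflections_rejected_by_duration(self, fs):
        n = int(60 * fs)
        bg = 0.1 * gen_powerlaw_signal(n, fs, -2.0, seed=3)
        # 0.3 s biphasic deflections are below the 0.8 s duration floor
        sig, _ = gen_slow_waves(20.0, 8.0, (0.25, 0.35), n, fs, seed=4)
        events = detect_slow_waves(Recording((bg + sig)[None, :], fs))
        # nothing near the injected duration should survive
        assert all(ev.duration >= 0.8 for ev in events)

    def test_invariants_duration_amplitude_nonoverlap(self, fs):
        rec, _ = injected_recording(fs, seed=5)
        events = detect_slow_waves(rec)
        assert events
        for ev in events:
            assert 0.8 <= ev.duration <= 2.0
            assert ev.start_time < ev.trough_time < ev.end_time
        times = sorted((e.start_time, e.end_time) for e in events)
        for (a1, b1), (a2, b2) in zip(times[:-1], times[1:]):
            assert b1 <= a2 + 1e-9

    def test_raising_percentile_never_increases_count(self, fs):
        rec, _ = injected_recording(fs, seed=6)
        n75 = len(detect_slow_waves(rec, amplitude_percentile=75))
        n90 = len(detect_slow_waves(rec, amplitude_percentile=90))
        assert n90 <= n75

    def test_stage_labels_attached(self, fs):
        rec, _ = injected_recording(fs, minutes=2.0, seed=7)
        hyp = Hypnogram(["N3", "W", "N3", "W"])
        events = detect_slow_waves(rec, hypnogram=hyp)
        assert all(e.state_at_event in {"N3", "W"} for e in events)

    def test_too_short_recording_rejected(self, fs):
        with pytest.raises(ValueError):
            detect_slow_waves(Recording(np.zeros((1, int(10 * fs))), fs))


class TestEventLocked:
    def test_flat_course_on_stationary_background(self, fs):
        # epochs centered on arbitrary times in a stationary slope -2 signal;
        # a single 0.5 s / 1-taper window slope scatters with SD ~3.4, so the
        # mean course over ~110 events carries SE ~0.3 per window
        n = int(300 * fs)
        x = gen_powerlaw_signal(n, fs, -2.0, seed=8)
        rec = Recording(x[None, :], fs)
        from slopetrack.events import SlowWaveEvent

        events = [
            SlowWaveEvent("ch0", t, t - 0.5, t + 0.5, 1.0, 10.0)
            for t in np.arange(10.0, 290.0, 2.5)
        ]
        locked = event_locked_slope(rec, events)
        assert locked["per_event"].shape[1] == 19
        assert np.nanmean(locked["mean"]) == pytest.approx(-2.0, abs=0.25)
        assert np.all(np.abs(locked["mean"] - (-2.0)) < 1.0)

    def test_trough_window_steeper_when_constructed(self, fs):
        # steep -4 base plus high-band (25-48 Hz) noise whose amplitude dips
        # at each event center: the 30-45 Hz slope is shallow on the flanks
        # and collapses to the steep base exactly at the trough window
        from scipy import signal as sp

        n = int(480 * fs)
        t = np.arange(n) / fs
        # valid_band floor at 20 Hz keeps the steep base analyzable by a
        # single short taper (otherwise low-frequency leakage floors the band)
        base = gen_powerlaw_signal(n, fs, -4.0, seed=9, valid_band=(20, 100))
        rng = np.random.default_rng(10)
        sos = sp.butter(4, (25.0, 48.0), btype="bandpass", fs=fs, output="sos")
        hf = sp.sosfiltfilt(sos, rng.standard_normal(n))
        hf /= hf.std()
        centers = np.arange(10.0, 470.0, 5.0)
        gate = np.zeros(n)
        for c in centers:
            d = np.abs(t - c)
            gate = np.maximum(
                gate,
                np.where(d < 0.4, 1.0,
                         np.where(d < 0.7,
                                  0.5 * (1 + np.cos(np.pi * (d - 0.4) / 0.3)),
                                  0.0)),
            )
        mix = base + hf * (1.0 - gate)
        rec = Recording(mix[None, :], fs)
        from slopetrack.events import SlowWaveEvent

        events = [
            SlowWaveEvent("ch0", c, c - 0.5, c + 0.5, 1.0, 10.0) for c in centers
        ]
        locked = event_locked_slope(rec, events)
        w0 = np.argmin(np.abs(locked["window_centers"]))
        assert np.argmin(locked["mean"]) in range(w0 - 1, w0 + 2)
        # trough window markedly steeper than the far flanks
        assert locked["mean"][w0] < locked["mean"][0] - 1.0
        assert locked["mean"][w0] < locked["mean"][-1] - 1.0

    def test_event_count_windows(self, fs):
        # 19 sliding windows tile the 5 s epoch (0.5 s windows, 0.25 s step)
        n = int(60 * fs)
        rec = Recording(gen_powerlaw_signal(n, fs, -2.0, seed=20)[None, :], fs)
        from slopetrack.events import SlowWaveEvent

        locked = event_locked_slope(
            rec, [SlowWaveEvent("ch0", 30.0, 29.5, 30.5, 1.0, 5.0)]
        )
        assert locked["per_event"].shape == (1, 19)

    def test_edge_events_dropped(self, fs):
        rec, truth = injected_recording(fs, minutes=1.0, seed=11)
        from slopetrack.events import SlowWaveEvent

        events = [SlowWaveEvent("ch0", 1.0, 0.5, 1.5, 1.0, 10.0),
                  SlowWaveEvent("ch0", 30.0, 29.5, 30.5, 1.0, 10.0)]
        locked = event_locked_slope(rec, events)
        assert len(locked["events"]) == 1

    def test_no_valid_events_rejected(self, fs):
        rec, _ = injected_recording(fs, minutes=1.0, seed=12)
        from slopetrack.events import SlowWaveEvent

        with pytest.raises(ValueError):
            event_locked_slope(rec, [SlowWaveEvent("ch0", 0.5, 0.1, 0.9, 0.8, 1.0)])


class TestRates:
    def _events_at(self, times, state=None):
        from slopetrack.events import SlowWaveEvent

        return [
            SlowWaveEvent("ch0", t, t - 0.4, t + 0.5, 0.9, 5.0, state)
            for t in times
        ]

    def test_thirty_events_in_one_minute_of_n3(self):
        hyp = Hypnogram(["N3", "N3"])  # one minute
        events = self._events_at(np.linspace(1, 59, 30))
        rates = event_rate_by_state(events, hyp)
        assert rates["N3"] == pytest.approx(30.0)

    def test_zero_rate_in_empty_state(self):
        hyp = Hypnogram(["N3", "REM"])
        events = self._events_at([5.0, 10.0])
        rates = event_rate_by_state(events, hyp)
        assert rates["REM"] == pytest.approx(0.0)

    def test_detector_rates_reproduce_state_ordering(self, fs):
        # N3-like half with dense strong waves, REM-like half nearly empty
        n_half = int(120 * fs)
        bg1 = 0.3 * gen_powerlaw_signal(n_half, fs, -2.0, seed=13)
        sw1, _ = gen_slow_waves(29.0, 8.0, (0.8, 2.0), n_half, fs, seed=14)
        bg2 = 0.3 * gen_powerlaw_signal(n_half, fs, -2.0, seed=15)
        sw2, _ = gen_slow_waves(2.0, 8.0, (0.8, 2.0), n_half, fs, seed=16)
        rec = Recording(np.concatenate([bg1 + sw1, bg2 + sw2])[None, :], fs)
        hyp = Hypnogram(["N3"] * 4 + ["REM"] * 4)
        events = detect_slow_waves(rec, hypnogram=hyp)
        rates = event_rate_by_state(events, hyp)
        assert rates["N3"] > 5 * rates["REM"]


class TestTroughSlopeByState:
    def test_group_means_recover_construction(self, fs):
        # two constructed populations of epochs with different 30-45 Hz
        # decay; single-window trough slopes scatter with SD ~3.4, so ~100
        # events per group give group-mean SEs of a few tenths
        n = int(480 * fs)
        shallow = gen_powerlaw_signal(n, fs, -2.3, seed=17, valid_band=(20, 100))
        steep = gen_powerlaw_signal(n, fs, -4.0, seed=18, valid_band=(20, 100))
        half = int(240 * fs)
        mix = shallow.copy()
        mix[half:] = steep[half:]
        rec = Recording(mix[None, :], fs)
        from slopetrack.events import SlowWaveEvent

        centers_a = np.arange(10.0, 230.0, 2.0)
        centers_b = np.arange(250.0, 470.0, 2.0)
        events = [SlowWaveEvent("ch0", c, c - 0.5, c + 0.5, 1.0, 9.0, "W")
                  for c in centers_a]
        events += [SlowWaveEvent("ch0", c, c - 0.5, c + 0.5, 1.0, 9.0, "N3")
                   for c in centers_b]
        hyp = Hypnogram(["W"] * 8 + ["N3"] * 8)
        locked = event_locked_slope(rec, events)
        groups = trough_slope_by_state(locked, hyp)
        assert groups["W"]["mean"] == pytest.approx(-2.3, abs=0.6)
        assert groups["N3"]["mean"] == pytest.approx(-4.0, abs=0.6)
        assert groups["W"]["mean"] > groups["N3"]["mean"] + 1.0

    def test_sem_shrinks_with_event_count(self, fs):
        n = int(300 * fs)
        x = gen_powerlaw_signal(n, fs, -2.0, seed=19)
        rec = Recording(x[None, :], fs)
        from slopetrack.events import SlowWaveEvent

        def groups_for(n_events):
            events = [
                SlowWaveEvent("ch0", t, t - 0.5, t + 0.5, 1.0, 9.0, "N3")
                for t in np.linspace(10, 290, n_events)
            ]
            locked = event_locked_slope(rec, events)
            return trough_slope_by_state(locked, Hypnogram(["N3"] * 10))

        sem_small = groups_for(10)["N3"]["sem"]
        sem_large = groups_for(50)["N3"]["sem"]
        assert sem_large < sem_small
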