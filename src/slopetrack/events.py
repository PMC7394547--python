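"""Slow-wave detection and slow-wave-locked slope dynamics.

Candidate slow oscillations are spans between successive positive-to-negative
zero crossings of the 0.16-1.25 Hz band-passed trace (zero-phase 4th-order
Butterworth, forward-backward).  An event must last 0.8-2.0 s and its
trough-to-peak amplitude must reach the 75th percentile of the duration-valid
candidates on that channel.  The raw signal is then epoched +/-2.5 s around
each trough and the 30-45 Hz slope estimated in sliding 0.5 s windows
(0.25 s step, one dpss taper, +/-2 Hz smoothing), yielding the event-locked
slope time course.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sp_signal

from .slope import DEFAULT_BAND, fit_slope_linear
from .spectral import Recording, event_tfr
from .state_tracking import Hypnogram

__all__ = [
    "SlowWaveEvent",
    "detect_slow_waves",
    "event_locked_slope",
    "event_rate_by_state",
    "trough_slope_by_state",
]


@dataclass
class SlowWaveEvent:
    channel: str
    trough_time: float  # s
    start_time: float  # preceding pos->neg zero crossing, s
    end_time: float  # next pos->neg zero crossing, s
    duration: float  # s
    peak_to_peak_amplitude: float  # microvolts, trough-to-peak of filtered trace
    state_at_event: str | None = None

    def __post_init__(self) -> None:
        if not self.start_time < self.trough_time < self.end_time:
            raise ValueError("trough must lie strictly inside the event")


def _stage_at(hypnogram: Hypnogram | None, t: float) -> str | None:
    if hypnogram is None:
        return None
    i = int(t // hypnogram.epoch_sec)
    if 0 <= i < len(hypnogram):
        return hypnogram.labels[i]
    return None


def detect_slow_waves(
    recording: Recording,
    channel: int = 0,
    hypnogram: Hypnogram | None = None,
    band: tuple[float, float] = (0.16, 1.25),
    duration_range: tuple[float, float] = (0.8, 2.0),
    amplitude_percentile: float = 75.0,
) -> list[SlowWaveEvent]:
    """Detect slow oscillations on one channel.

    Returns events sorted by trough time, each labeled with the hypnogram
    stage at its trough when a hypnogram is given.  With fewer than 4
    duration-valid candidates the percentile threshold is unreliable and an
    empty list is returned with a warning.
    """
    if recording.duration < 30.0:
        raise ValueError("need at least 30 s of signal for slow-wave detection")
    fs = recording.fs
    x = recording.data[channel]
    sos = sp_signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    filt = sp_signal.sosfiltfilt(sos, x)

    sign = np.signbit(filt)
    # positive-to-negative crossings: sample i where filt[i] >= 0 > filt[i+1]
    pn = np.flatnonzero(~sign[:-1] & sign[1:])
    candidates = []
    for a, b in zip(pn[:-1], pn[1:]):
        dur = (b - a) / fs
        if not duration_range[0] <= dur <= duration_range[1]:
            continue
        seg = filt[a : b + 1]
        trough_i = a + int(np.argmin(seg))
        p2p = float(seg.max() - seg.min())
        candidates.append((a, b, trough_i, dur, p2p))
    if len(candidates) < 4:
        warnings.warn("fewer than 4 slow-wave candidates; percentile unreliable")
        return []
    thresh = np.percentile([c[4] for c in candidates], amplitude_percentile)
    events = []
    for a, b, trough_i, dur, p2p in candidates:
        if p2p < thresh:
            continue
        t = trough_i / fs
        events.append(
            SlowWaveEvent(
                channel=recording.channel_labels[channel],
                trough_time=t,
                start_time=a / fs,
                end_time=b / fs,
                duration=dur,
                peak_to_peak_amplitude=p2p,
                state_at_event=_stage_at(hypnogram, t),
            )
        )
    return events


def event_locked_slope(
    recording: Recording,
    events: list[SlowWaveEvent],
    channel: int = 0,
    window_half_sec: float = 2.5,
    band: tuple[float, float] = DEFAULT_BAND,
) -> dict:
    """Slope time course around slow-wave troughs.

    Epochs +/-window_half_sec around each trough (edge events dropped), then
    per 0.5 s sliding window (0.25 s step) fits the 30-45 Hz log-log line.
    Returns window centers (s, trough = 0), per-event slope courses, and the
    across-event mean +/- SEM.
    """
    fs = recording.fs
    half = int(round(window_half_sec * fs))
    x = recording.data[channel]
    epochs, kept = [], []
    for ev in events:
        c = int(round(ev.trough_time * fs))
        if c - half < 0 or c + half > x.size:
            continue
        epochs.append(x[c - half : c + half])
        kept.append(ev)
    if not epochs:
        raise ValueError("no events fully inside the recording after windowing")
    centers, freqs, power = event_tfr(np.asarray(epochs), fs)
    n_ev, n_win, _ = power.shape
    courses = np.full((n_ev, n_win), np.nan)
    for e in range(n_ev):
        for w in range(n_win):
            try:
                courses[e, w] = fit_slope_linear(freqs, power[e, w], band).slope
            except ValueError:
                continue
    mean = np.nanmean(courses, axis=0)
    n_ok = np.sum(np.isfinite(courses), axis=0)
    with np.errstate(invalid="ignore"):
        sem = np.nanstd(courses, axis=0, ddof=1) / np.sqrt(np.maximum(n_ok, 1))
    return {
        "window_centers": centers,
        "per_event": courses,
        "mean": mean,
        "sem": sem,
        "events": kept,
    }


def event_rate_by_state(events: list[SlowWaveEvent],
                        hypnogram: Hypnogram) -> dict[str, float]:
    """Events per minute in each stage (trough-time assignment).

    Stages with zero minutes are reported as NaN.
    """
    minutes = {s: 0.0 for s in hypnogram.stages_present}
    for s in hypnogram.labels:
        minutes[s] += hypnogram.epoch_sec / 60.0
    counts = dict.fromkeys(minutes, 0)
    for ev in events:
        st = ev.state_at_event or _stage_at(hypnogram, ev.trough_time)
        if st in counts:
            counts[st] += 1
    return {s: (counts[s] / m if m > 0 else np.nan) for s, m in minutes.items()}


def trough_slope_by_state(locked: dict, hypnogram: Hypnogram) -> dict[str, dict[str, float]]:
    """Mean +/- SEM of the trough-centered-window slope, grouped by stage."""
    centers = locked["window_centers"]
    w0 = int(np.argmin(np.abs(centers)))
    trough_slopes = locked["per_event"][:, w0]
    groups: dict[str, list[float]] = {}
    for ev, s in zip(locked["events"], trough_slopes):
        st = ev.state_at_event or _stage_at(hypnogram, ev.trough_time)
        if st is not None and np.isfinite(s):
            groups.setdefault(st, []).append(float(s))
    out = {}
    for st, vals in groups.items():
        v = np.asarray(vals)
        sem = float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else 0.0
        out[st] = {"mean": float(v.mean()), "sem": sem, "n": int(v.size)}
    return out
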