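"""Synthetic polysomnography with known ground truth.

Emulates the statistical structure the slope analysis assumes: each arousal
state contributes a scale-free 1/f background with a state-specific log-log
slope, band-limited oscillation bursts (slow oscillations <1.25 Hz, spindles
12-16 Hz, alpha 8-12 Hz), slow-wave events at a state-specific rate, and a
broadband EMG channel (noise high-pass filtered at 40 Hz) whose amplitude
tracks muscle tone.  Stage sequences come from a first-order Markov chain in
30 s epochs.  Everything is reproducible from a single seed.

Default per-state target slopes follow group-mean values reported for human
recordings: wake -1.84, N3 -3.46, REM -4.73, N2 -3.67, anesthesia -3.10;
N1 (-2.5) is an interpolated choice.  Slow-wave rates default to 28.79/min
in N3, 5.05/min in wake and 2.16/min in REM.  Oscillation amplitudes and
EMG levels are free parameters with documented defaults; no attempt is made
at physiological microarchitecture (K-complexes, sawtooth waves, eye
movements).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal

from .spectral import Recording

__all__ = [
    "StateProfile",
    "SyntheticGroundTruth",
    "DEFAULT_PROFILES",
    "gen_powerlaw_signal",
    "gen_oscillation_burst",
    "gen_hypnogram",
    "gen_slow_waves",
    "gen_recording",
]

STATES = ("W", "N1", "N2", "N3", "REM", "ANESTHESIA")
EPOCH_SEC = 30.0


@dataclass
class StateProfile:
    """Generative parameters for one arousal state.

    oscillations: list of (center_hz, bandwidth_hz, relative_amplitude,
    burst duty-cycle fraction).  ``target_slope`` is the log-log PSD slope
    (negative).  ``slow_wave_rate`` in events/min; ``emg_level`` the relative
    amplitude of broadband >40 Hz muscle noise.
    """

    state_label: str
    target_slope: float
    oscillations: list[tuple[float, float, float, float]] = field(default_factory=list)
    slow_wave_rate: float = 0.0
    emg_level: float = 0.0

    def __post_init__(self) -> None:
        if self.state_label not in STATES:
            raise ValueError(f"unknown state label {self.state_label!r}")
        if self.target_slope >= 0:
            raise ValueError("target_slope must be negative")
        for f0, bw, amp, duty in self.oscillations:
            if f0 <= 0:
                raise ValueError("oscillation center frequency must be positive")
            if not 0.0 <= duty <= 1.0:
                raise ValueError("burst duty-cycle must lie in [0, 1]")


# Oscillation tuples: (center Hz, bandwidth Hz, relative amplitude, duty).
# Target slopes are published group means for each state; amplitudes, duty
# cycles and EMG levels are generator choices.
DEFAULT_PROFILES: dict[str, StateProfile] = {
    "W": StateProfile("W", -1.84, [(10.0, 4.0, 0.7, 0.5)], slow_wave_rate=5.05, emg_level=1.0),
    "N1": StateProfile("N1", -2.5, [(7.0, 2.0, 0.3, 0.3)], slow_wave_rate=5.0, emg_level=0.4),
    "N2": StateProfile("N2", -3.67, [(14.0, 4.0, 0.5, 0.3)], slow_wave_rate=12.0, emg_level=0.3),
    "N3": StateProfile("N3", -3.46, [(14.0, 4.0, 0.3, 0.2)], slow_wave_rate=28.79, emg_level=0.25),
    "REM": StateProfile("REM", -4.73, [], slow_wave_rate=2.16, emg_level=0.05),
    "ANESTHESIA": StateProfile("ANESTHESIA", -3.10, [(1.0, 0.8, 0.8, 0.8)],
                               slow_wave_rate=15.0, emg_level=0.1),
}


@dataclass
class SyntheticGroundTruth:
    """Exact per-epoch labels/slopes and injected slow-wave troughs."""

    states: list[str]  # one label per epoch
    slopes: np.ndarray  # true background slope per epoch
    trough_times: dict[str, np.ndarray]  # channel label -> trough times (s)
    seed: int


def gen_powerlaw_signal(n_samples: int, fs: float, slope: float, seed: int,
                        valid_band: tuple[float, float] = (1.0, 100.0)) -> np.ndarray:
    """Zero-mean unit-variance signal with PSD(f) ~ f^slope on a validity band.

    White Gaussian noise is shaped in the Fourier domain by f^(slope/2)
    (amplitude), with the DC component set to zero, then inverse
    transformed.  Exact spectral control at O(n log n).  Below the validity
    band the spectrum is held flat at its low-edge value: physiological
    spectra plateau at the slowest frequencies, and an unbounded power law
    would put essentially all variance into the lowest FFT bins, whose
    leakage through any taper's sidelobes floors the high-frequency
    spectrum for steep slopes.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    if slope > 0:
        raise ValueError("slope must be <= 0")
    if n_samples < 2 * fs:
        raise ValueError("need at least 2 s of samples")
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(n_samples)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    f_lo = valid_band[0]
    shape = np.zeros_like(freqs)
    nz = freqs > 0
    shape[nz] = np.maximum(freqs[nz], f_lo) ** (slope / 2.0)
    x = np.fft.irfft(spec * shape, n=n_samples)
    x -= x.mean()
    sd = x.std()
    return x / sd if sd > 0 else x


def _burst_envelope(n_samples: int, fs: float, duty: float, rng: np.random.Generator,
                    burst_sec: float = 1.0, ramp_sec: float = 0.1) -> np.ndarray:
    """Smooth on/off envelope active for ~duty of the samples."""
    if duty <= 0:
        return np.zeros(n_samples)
    if duty >= 1:
        return np.ones(n_samples)
    env = np.zeros(n_samples)
    n_burst = max(int(burst_sec * fs), 4)
    n_ramp = max(int(ramp_sec * fs), 2)
    ramp = 0.5 * (1 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
    shape = np.ones(n_burst)
    shape[:n_ramp] = ramp
    shape[-n_ramp:] = ramp[::-1]
    target = duty * n_samples
    active = 0.0
    guard = 0
    while active < target and guard < 10_000:
        guard += 1
        start = rng.integers(0, max(n_samples - n_burst, 1))
        seg = env[start : start + n_burst]
        before = seg.sum()
        np.maximum(seg, shape[: seg.size], out=seg)
        active += seg.sum() - before
    return env


def gen_oscillation_burst(freq: float, amplitude: float, duty: float,
                          n_samples: int, fs: float, seed: int) -> np.ndarray:
    """Randomized-phase sinusoid gated by a smoothly windowed burst envelope."""
    if not 0.0 <= duty <= 1.0:
        raise ValueError("duty must lie in [0, 1]")
    if not 0.0 < freq < fs / 2:
        raise ValueError("oscillation frequency must lie in (0, Nyquist)")
    rng = np.random.default_rng(seed)
    phase = rng.uniform(0, 2 * np.pi)
    t = np.arange(n_samples) / fs
    env = _burst_envelope(n_samples, fs, duty, rng)
    return amplitude * env * np.sin(2 * np.pi * freq * t + phase)


def gen_hypnogram(n_epochs: int, transition_matrix: np.ndarray,
                  states: tuple[str, ...], initial_state: str, seed: int):
    """Markov-chain stage sequence, one label per 30 s epoch."""
    from .state_tracking import Hypnogram

    P = np.asarray(transition_matrix, dtype=float)
    if P.shape != (len(states), len(states)):
        raise ValueError("transition matrix shape must match the state list")
    if np.any(np.abs(P.sum(axis=1) - 1.0) > 1e-9) or np.any(P < 0):
        raise ValueError("transition matrix rows must be non-negative and sum to 1")
    rng = np.random.default_rng(seed)
    idx = {s: i for i, s in enumerate(states)}
    cur = idx[initial_state]
    labels = []
    for _ in range(n_epochs):
        labels.append(states[cur])
        cur = rng.choice(len(states), p=P[cur])
    return Hypnogram(labels)


def _slow_wave_shape(n: int, amplitude: float) -> np.ndarray:
    """One biphasic (trough-then-peak) cycle, zero at both ends.

    A Hann envelope keeps value and first derivative continuous at the
    boundaries so the event's spectral sidelobes decay fast enough not to
    leak into the 30-45 Hz fit band.
    """
    t = np.arange(n) / n
    return -amplitude * np.sin(2 * np.pi * t) * np.sin(np.pi * t) ** 2


def gen_slow_waves(rate: float, amplitude: float, duration_range: tuple[float, float],
                   n_samples: int, fs: float, seed: int,
                   min_gap: float = 0.25) -> tuple[np.ndarray, np.ndarray]:
    """Insert non-overlapping biphasic slow-wave cycles; return exact troughs.

    ``rate`` is events per minute; durations are drawn uniformly from
    ``duration_range`` (seconds, within (0, 5]).  Successive events are
    separated by at least ``min_gap`` seconds (slow oscillations have a
    refractory down-state interval).  The returned trough times (s) are the
    exact minima of the injected waveforms.
    """
    lo, hi = duration_range
    if not (0 < lo <= hi <= 5.0):
        raise ValueError("duration_range must lie within (0, 5] s")
    sig = np.zeros(n_samples)
    minutes = n_samples / fs / 60.0
    n_events = int(round(rate * minutes))
    if n_events == 0:
        return sig, np.array([])
    rng = np.random.default_rng(seed)
    n_gap = int(round(min_gap * fs))
    n_durs = np.round(rng.uniform(lo, hi, size=n_events) * fs).astype(int)
    free = n_samples - int(n_durs.sum()) - (n_events - 1) * n_gap
    if free < 0:
        raise ValueError("requested slow-wave rate cannot fit without overlap")
    # stick-breaking placement: spread the free samples as random extra gaps
    offsets = np.sort(rng.integers(0, free + 1, size=n_events))
    starts = offsets + np.concatenate([[0], np.cumsum(n_durs[:-1] + n_gap)])
    troughs = []
    for start, n_dur in zip(starts, n_durs):
        wave = _slow_wave_shape(n_dur, amplitude)
        sig[start : start + n_dur] += wave
        troughs.append((start + int(np.argmin(wave))) / fs)
    return sig, np.sort(np.array(troughs))


def _epoch_signal(profile: StateProfile, n: int, fs: float,
                  rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Background + oscillations + slow waves for one epoch of one channel."""
    x = gen_powerlaw_signal(n, fs, profile.target_slope, int(rng.integers(2**31)))
    for f0, _bw, amp, duty in profile.oscillations:
        x = x + gen_oscillation_burst(f0, amp, duty, n, fs, int(rng.integers(2**31)))
    troughs = np.array([])
    if profile.slow_wave_rate > 0:
        sw, troughs = gen_slow_waves(profile.slow_wave_rate, 3.0, (0.8, 2.0),
                                     n, fs, int(rng.integers(2**31)))
        x = x + sw
    return x, troughs


def gen_recording(hypnogram, n_channels: int = 2, fs: float = 400.0, seed: int = 0,
                  profiles: dict[str, StateProfile] | None = None,
                  crossfade_sec: float = 1.0,
                  amplitude_uv: float = 20.0) -> tuple[Recording, SyntheticGroundTruth]:
    """Multichannel recording following a hypnogram, plus exact ground truth.

    Per-epoch signals are synthesized from each state's profile and joined
    with 1 s cosine cross-fades to avoid spectral edge artifacts.  One
    EMG-like channel (Gaussian noise high-pass filtered at 40 Hz, scaled by
    the state's ``emg_level``) is appended after the EEG channels.
    """
    profiles = profiles or DEFAULT_PROFILES
    missing = sorted(set(hypnogram.labels) - set(profiles))
    if missing:
        raise ValueError(f"no profile for hypnogram states: {missing}")
    rng = np.random.default_rng(seed)
    n_epoch = int(round(hypnogram.epoch_sec * fs))
    n_total = n_epoch * len(hypnogram.labels)
    n_fade = int(crossfade_sec * fs)
    fade_in = 0.5 * (1 - np.cos(np.pi * np.arange(n_fade) / n_fade))

    data = np.zeros((n_channels + 1, n_total))
    trough_times: dict[str, list[float]] = {f"ch{c}": [] for c in range(n_channels)}
    true_slopes = np.array([profiles[s].target_slope for s in hypnogram.labels])

    for c in range(n_channels):
        for e, state in enumerate(hypnogram.labels):
            prof = profiles[state]
            x, troughs = _epoch_signal(prof, n_epoch, fs, rng)
            x = x * amplitude_uv
            s0 = e * n_epoch
            if e > 0:
                # cosine cross-fade into the previous epoch's tail
                x[:n_fade] *= fade_in
                data[c, s0 : s0 + n_fade] *= fade_in[::-1]
            data[c, s0 : s0 + n_epoch] += x
            trough_times[f"ch{c}"].extend(s0 / fs + troughs)

    # EMG surrogate: >40 Hz high-passed noise scaled per epoch by muscle tone
    sos = sp_signal.butter(4, 40.0, btype="highpass", fs=fs, output="sos")
    emg = sp_signal.sosfiltfilt(sos, rng.standard_normal(n_total))
    emg /= emg.std()
    levels = np.repeat([profiles[s].emg_level for s in hypnogram.labels], n_epoch)
    data[n_channels] = emg * levels * amplitude_uv

    labels = [f"ch{c}" for c in range(n_channels)] + ["EMG"]
    roles = ["EEG"] * n_channels + ["EMG"]
    rec = Recording(data, fs, labels, roles)
    gt = SyntheticGroundTruth(
        states=list(hypnogram.labels),
        slopes=true_slopes,
        trough_times={k: np.asarray(v) for k, v in trough_times.items()},
        seed=seed,
    )
    return rec, gt
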