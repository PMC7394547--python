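"""Power spectral density estimation for slope tracking.

Four estimators are provided on a common frequency grid (default 0.5-45 Hz in
0.5 Hz steps): a multitaper estimate using discrete prolate spheroidal (dpss)
tapers, a single Hann taper, a rectangular-window periodogram, and Welch's
method with one Hamming window per segment.  The taper count for the
multitaper estimate follows the rule K = 2*T*W - 1, where T is the segment
length in seconds and W the one-sided frequency-smoothing halfwidth in Hz
(e.g. 29 tapers for 30 s segments at +/-0.5 Hz; 9 tapers for 10 s segments).

Power is returned as density (unit^2/Hz).  Slope estimates downstream are
invariant to the overall scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal
from scipy.signal.windows import dpss as dpss_windows

__all__ = [
    "Recording",
    "PowerSpectrum",
    "dpss_taper_count",
    "compute_psd",
    "compute_snr",
    "band_power",
    "event_tfr",
]

CHANNEL_ROLES = {"EEG", "iEEG", "EMG", "EOG", "ECG"}


@dataclass
class Recording:
    """Multichannel sampled signal.

    data : array, shape (n_channels, n_samples), microvolts
    fs : sampling rate in Hz
    channel_labels : one label per channel
    channel_roles : one of {EEG, iEEG, EMG, EOG, ECG} per channel
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str] = field(default_factory=list)
    channel_roles: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        n_ch = self.data.shape[0]
        if not self.channel_labels:
            self.channel_labels = [f"ch{i}" for i in range(n_ch)]
        if not self.channel_roles:
            self.channel_roles = ["EEG"] * n_ch
        if len(self.channel_labels) != n_ch or len(self.channel_roles) != n_ch:
            raise ValueError("channel metadata length mismatch")
        bad = set(self.channel_roles) - CHANNEL_ROLES
        if bad:
            raise ValueError(f"unknown channel roles: {sorted(bad)}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def pick(self, roles: set[str] | None = None) -> "Recording":
        """Sub-recording containing only channels with the given roles."""
        if roles is None:
            return self
        idx = [i for i, r in enumerate(self.channel_roles) if r in roles]
        return Recording(
            self.data[idx],
            self.fs,
            [self.channel_labels[i] for i in idx],
            [self.channel_roles[i] for i in idx],
        )


@dataclass
class PowerSpectrum:
    """Per-channel power on a frequency grid, with estimator metadata."""

    freqs: np.ndarray
    power: np.ndarray  # channels x freqs (segment average)
    method: str
    segment_sec: float
    n_tapers: int = 1
    per_segment: np.ndarray | None = None  # segments x channels x freqs

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.atleast_2d(np.asarray(self.power, dtype=float))
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequency grid must be strictly increasing")


def dpss_taper_count(segment_sec: float, halfbandwidth: float) -> int:
    """Number of dpss tapers: K = 2*T*W - 1 (floored to an integer).

    T is the segment length in seconds and W the one-sided smoothing
    halfwidth in Hz, so 2*T*W is the (two-sided) time-bandwidth product.
    """
    if segment_sec <= 0 or halfbandwidth <= 0:
        raise ValueError("segment length and halfbandwidth must be positive")
    k = math.floor(2.0 * segment_sec * halfbandwidth - 1.0 + 1e-12)
    if k < 1:
        raise ValueError(
            "time-bandwidth product too small: 2*T*W - 1 < 1 "
            f"(T={segment_sec}, W={halfbandwidth})"
        )
    return k


def _segment(data: np.ndarray, fs: float, segment_sec: float) -> np.ndarray:
    """Cut channels x samples into non-overlapping segments.

    Returns segments x channels x n_per_seg; trailing partial segment dropped.
    """
    n_per_seg = int(round(segment_sec * fs))
    if n_per_seg < 2:
        raise ValueError("segment too short")
    n_seg = data.shape[1] // n_per_seg
    if n_seg == 0:
        raise ValueError("recording shorter than one segment")
    trimmed = data[:, : n_seg * n_per_seg]
    return trimmed.reshape(data.shape[0], n_seg, n_per_seg).swapaxes(0, 1)


def _detrend(seg: np.ndarray) -> np.ndarray:
    return sp_signal.detrend(seg, axis=-1, type="linear")


def _grid(fmin: float, fmax: float, fstep: float) -> np.ndarray:
    n = int(round((fmax - fmin) / fstep))
    return fmin + fstep * np.arange(n + 1)


def _nearest_bins(fft_freqs: np.ndarray, grid: np.ndarray) -> np.ndarray:
    return np.abs(fft_freqs[None, :] - grid[:, None]).argmin(axis=1)


def _taper_psd(
    segs: np.ndarray,
    fs: float,
    tapers: np.ndarray,
    eigenvalues: np.ndarray | None = None,
    adaptive: bool = False,
    n_iter: int = 50,
    rtol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray]:
    """Combine tapered periodograms into a density estimate.

    segs: segments x channels x n; tapers: K x n (unit-energy dpss rows) or
    a single 1-D window.  Returns (fft_freqs, segments x channels x n_freqs).

    With ``adaptive`` the eigenspectra are combined with Thomson's adaptive
    weights d_k(f) = S(f) / (lambda_k S(f) + (1 - lambda_k) sigma^2),
    iterated to a fixed point; this suppresses the broadband leakage of the
    highest-order tapers, which otherwise floors the high-frequency tail of
    steep (high dynamic range) spectra.  Weights are computed on the
    two-sided density so the leakage term (1 - lambda) sigma^2 is on the
    same scale as the eigenspectra.
    """
    n = segs.shape[-1]
    tapers = np.atleast_2d(tapers)
    fft_freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    # two-sided eigenspectra: K x segments x channels x freqs
    eig = np.empty((tapers.shape[0],) + segs.shape[:2] + (fft_freqs.size,))
    for k, taper in enumerate(tapers):
        spec = np.fft.rfft(segs * taper, axis=-1)
        eig[k] = (np.abs(spec) ** 2) / (fs * np.sum(taper**2))
    if adaptive and tapers.shape[0] > 1:
        lam = np.asarray(eigenvalues).reshape(-1, 1, 1, 1)
        # leakage floor: process variance as two-sided density
        sigma2 = segs.var(axis=-1)[None, :, :, None] / fs
        est = eig[:2].mean(axis=0)
        for _ in range(n_iter):
            d = est[None] / (lam * est[None] + (1.0 - lam) * sigma2)
            w = d**2 * lam
            new = np.sum(w * eig, axis=0) / np.sum(w, axis=0)
            if np.allclose(new, est, rtol=rtol, atol=0):
                est = new
                break
            est = new
        combined = est
    else:
        combined = eig.mean(axis=0)
    # convert to one-sided density
    combined = combined.copy()
    combined[..., 1:] *= 2.0
    if n % 2 == 0:
        combined[..., -1] /= 2.0
    return fft_freqs, combined


def compute_psd(
    recording: Recording,
    method: str = "multitaper",
    segment_sec: float = 30.0,
    halfbandwidth: float = 0.5,
    fmin: float = 0.5,
    fmax: float = 45.0,
    fstep: float = 0.5,
    taper_weights: str = "adaptive",
) -> PowerSpectrum:
    """PSD on the requested grid from non-overlapping segments.

    Methods: ``multitaper`` (K dpss tapers, K = 2*T*W - 1), ``hanning``
    (single Hann taper), ``periodogram`` (rectangular window), ``welch``
    (one Hamming window per segment).  Each segment is demeaned and linearly
    detrended before tapering.  Segments containing NaN are excluded from the
    average.  Both the per-segment and the segment-averaged power are
    returned, sampled at the grid points nearest to the requested
    frequencies.

    ``taper_weights`` selects how multitaper eigenspectra are combined:
    ``adaptive`` (Thomson's leakage-suppressing weights, the default) or
    ``unity`` (plain average).
    """
    if fmax > recording.fs / 2:
        raise ValueError("requested grid exceeds the Nyquist frequency")
    if taper_weights not in ("adaptive", "unity"):
        raise ValueError("taper_weights must be 'adaptive' or 'unity'")
    segs = _segment(recording.data, recording.fs, segment_sec)
    n = segs.shape[-1]
    grid = _grid(fmin, fmax, fstep)

    n_tapers = 1
    eigenvalues = None
    if method == "multitaper":
        n_tapers = dpss_taper_count(segment_sec, halfbandwidth)
        nw = segment_sec * halfbandwidth
        tapers, eigenvalues = dpss_windows(n, NW=nw, Kmax=n_tapers, return_ratios=True)
    elif method == "hanning":
        tapers = sp_signal.windows.hann(n, sym=False)[None, :]
    elif method == "periodogram":
        tapers = np.ones((1, n))
    elif method == "welch":
        tapers = sp_signal.windows.hamming(n, sym=False)[None, :]
    else:
        raise ValueError(f"unknown PSD method: {method!r}")

    nan_seg = np.isnan(segs).any(axis=(1, 2))
    clean = _detrend(np.nan_to_num(segs))
    fft_freqs, per_seg_full = _taper_psd(
        clean, recording.fs, tapers, eigenvalues,
        adaptive=(method == "multitaper" and taper_weights == "adaptive"),
    )
    per_seg_full[nan_seg] = np.nan

    bins = _nearest_bins(fft_freqs, grid)
    per_segment = per_seg_full[..., bins]
    with np.errstate(invalid="ignore"):
        avg = np.nanmean(per_segment, axis=0)
    return PowerSpectrum(
        freqs=grid,
        power=avg,
        method=method,
        segment_sec=segment_sec,
        n_tapers=n_tapers,
        per_segment=per_segment,
    )


def compute_snr(per_segment_power: np.ndarray) -> np.ndarray:
    """Spectral signal-to-noise ratio: mean over segments / SD over segments.

    Bins with zero SD across segments are flagged as ``inf`` rather than
    dropped.  Input is segments x channels x freqs.
    """
    per_segment_power = np.asarray(per_segment_power, dtype=float)
    if per_segment_power.shape[0] < 2:
        raise ValueError("SNR requires at least 2 segments")
    mean = np.nanmean(per_segment_power, axis=0)
    sd = np.nanstd(per_segment_power, axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        snr = np.where(sd == 0, np.inf, mean / sd)
    return snr


def band_power(
    psd: PowerSpectrum,
    band: tuple[float, float],
    baseline: PowerSpectrum | None = None,
) -> np.ndarray:
    """Mean power per channel over grid points inside ``band`` (inclusive).

    With a baseline spectrum, returns the relative change
    (power - baseline) / baseline.
    """
    lo, hi = band
    mask = (psd.freqs >= lo - 1e-9) & (psd.freqs <= hi + 1e-9)
    if not mask.any():
        raise ValueError(f"band {band} contains no grid points")
    bp = psd.power[:, mask].mean(axis=1)
    if baseline is not None:
        base = band_power(baseline, band)
        return (bp - base) / base
    return bp


def event_tfr(
    epochs: np.ndarray,
    fs: float,
    window_sec: float = 0.5,
    step_sec: float = 0.25,
    halfbandwidth: float = 2.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sliding-window spectra for event-locked epochs.

    0.5 s windows stepping 0.25 s, one dpss taper with +/-2 Hz smoothing.
    ``epochs`` is events x samples, assumed centered on the event (e.g. a
    slow-wave trough).  Returns (window_centers_s, freqs, power) with power
    events x windows x freqs and window centers relative to the epoch center.
    """
    epochs = np.atleast_2d(np.asarray(epochs, dtype=float))
    n_epoch = epochs.shape[1]
    n_win = int(round(window_sec * fs))
    n_step = int(round(step_sec * fs))
    if n_epoch < n_win:
        raise ValueError("epoch shorter than one analysis window")
    n_windows = (n_epoch - n_win) // n_step + 1

    taper = dpss_windows(n_win, NW=window_sec * halfbandwidth, Kmax=1)[0]
    freqs = np.fft.rfftfreq(n_win, d=1.0 / fs)
    power = np.empty((epochs.shape[0], n_windows, freqs.size))
    starts = np.arange(n_windows) * n_step
    for w, s in enumerate(starts):
        seg = _detrend(epochs[:, s : s + n_win])
        spec = np.fft.rfft(seg * taper, axis=-1)
        p = (np.abs(spec) ** 2) / (fs * np.sum(taper**2))
        p[..., 1:] *= 2.0
        if n_win % 2 == 0:
            p[..., -1] /= 2.0
        power[:, w, :] = p
    centers = (starts + n_win / 2.0) / fs - n_epoch / (2.0 * fs)
    return centers, freqs, power
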