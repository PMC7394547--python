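"""1/f spectral-slope estimators.

The central quantity is the slope of a straight line fitted to the power
spectral density in log-log coordinates over a stated band (default
30-45 Hz).  For a scale-free spectrum PSD(f) ~ 1/f^alpha the fitted slope is
beta = -alpha; steeper (more negative) slopes accompany lower arousal.
Alternative estimators guard against oscillatory contamination: a robust
(bisquare) line fit, an aperiodic model with iterative Gaussian peak removal,
and IRASA, which separates the fractal from the oscillatory spectrum by
irregular resampling.

Slopes are invariant to the log base (log10 used throughout, on both axes)
and to a global multiplicative rescaling of the signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal as sp_signal

from .spectral import PowerSpectrum, Recording, compute_psd

__all__ = [
    "SlopeEstimate",
    "SlopeTrack",
    "fit_slope_linear",
    "fit_slope_robust",
    "fit_aperiodic_model",
    "irasa_fractal_psd",
    "time_resolved_slope",
    "slope_parameter_scan",
]

DEFAULT_BAND = (30.0, 45.0)


@dataclass
class SlopeEstimate:
    """A single log-log line fit: slope, intercept (log10 power at log10 f = 0),
    R^2, the fitted band and the estimator used."""

    slope: float
    intercept: float
    r_squared: float
    band: tuple[float, float]
    method: str


@dataclass
class SlopeTrack:
    """Per-segment, per-channel slope estimates aligned to segment start times."""

    times: np.ndarray  # segment start times, s
    slopes: np.ndarray  # segments x channels
    r_squared: np.ndarray  # segments x channels
    band: tuple[float, float]
    method: str
    segment_sec: float
    channel_labels: list[str]

    @property
    def n_segments(self) -> int:
        return self.slopes.shape[0]


def _band_points(freqs: np.ndarray, power: np.ndarray, band) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = band
    mask = (freqs >= lo - 1e-9) & (freqs <= hi + 1e-9)
    if mask.sum() < 3:
        raise ValueError(f"fewer than 3 grid points in band {band}")
    f = freqs[mask]
    p = power[mask]
    if np.any(p <= 0) or np.any(~np.isfinite(p)):
        raise ValueError("non-positive or non-finite power in fit band")
    return f, p


def _r2(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return 1.0
    return max(0.0, 1.0 - ss_res / ss_tot)


def fit_slope_linear(
    freqs: np.ndarray, power: np.ndarray, band: tuple[float, float] = DEFAULT_BAND
) -> SlopeEstimate:
    """OLS fit of log10 power on log10 frequency over the band (inclusive)."""
    f, p = _band_points(np.asarray(freqs, float), np.asarray(power, float), band)
    x, y = np.log10(f), np.log10(p)
    slope, intercept = np.polyfit(x, y, 1)
    return SlopeEstimate(float(slope), float(intercept), _r2(y, slope * x + intercept),
                         tuple(band), "linear")


def fit_slope_robust(
    freqs: np.ndarray,
    power: np.ndarray,
    band: tuple[float, float] = DEFAULT_BAND,
    tuning: float = 4.685,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> SlopeEstimate:
    """Iteratively reweighted least squares with Tukey bisquare weights.

    Matches the convention of MATLAB's robustfit: residuals are scaled by
    s = MAD/0.6745 with leverage adjustment, default tuning constant 4.685.
    """
    f, p = _band_points(np.asarray(freqs, float), np.asarray(power, float), band)
    x, y = np.log10(f), np.log10(p)
    X = np.column_stack([np.ones_like(x), x])
    h = np.clip(np.diag(X @ np.linalg.pinv(X.T @ X) @ X.T), 0, 0.9999)
    adj = np.sqrt(1.0 - h)
    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    for _ in range(max_iter):
        resid = (y - X @ beta) / adj
        s = np.median(np.abs(resid - np.median(resid))) / 0.6745
        if s <= 1e-10 * max(1.0, float(np.abs(y).mean())):
            break  # essentially exact fit; nothing to reweight
        u = resid / (tuning * s)
        w = np.where(np.abs(u) < 1, (1 - u**2) ** 2, 0.0)
        if w.sum() < 2:
            raise RuntimeError("robust fit degenerated: all points down-weighted")
        Xw = X * np.sqrt(w)[:, None]
        beta_new = np.linalg.lstsq(Xw, y * np.sqrt(w), rcond=None)[0]
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            break
        beta = beta_new
    else:
        raise RuntimeError("robust slope fit did not converge in 50 iterations")
    yhat = X @ beta
    return SlopeEstimate(float(beta[1]), float(beta[0]), _r2(y, yhat), tuple(band), "robust")


def _gauss(f: np.ndarray, center: float, height: float, width: float) -> np.ndarray:
    return height * np.exp(-((f - center) ** 2) / (2.0 * width**2))


def fit_aperiodic_model(
    freqs: np.ndarray,
    power: np.ndarray,
    band: tuple[float, float] = DEFAULT_BAND,
    max_peaks: int = 6,
    peak_threshold_sd: float = 2.0,
    min_peak_width: float = 0.5,
) -> tuple[SlopeEstimate, list[dict]]:
    """Aperiodic slope with iterative Gaussian peak removal.

    Alternates between a line fit to log10 power (aperiodic component, no
    knee) and extraction of Gaussian oscillatory peaks from the residual
    until no residual point exceeds ``peak_threshold_sd`` standard
    deviations (the noise floor).  The aperiodic fit is then refit on the
    peak-subtracted spectrum.  Returns the aperiodic slope plus the list of
    detected peaks as dicts with keys ``center``, ``height``, ``width``.
    """
    if band[1] - band[0] < 5.0:
        raise ValueError("aperiodic model needs a band at least 5 Hz wide")
    f, p = _band_points(np.asarray(freqs, float), np.asarray(power, float), band)
    logf, logp = np.log10(f), np.log10(p)

    def aperiodic_fit(y):
        b = np.polyfit(logf, y, 1)
        return b, b[0] * logf + b[1]

    peaks: list[dict] = []
    flat = logp.copy()
    _, ap = aperiodic_fit(flat)
    resid = logp - ap
    for _ in range(max_peaks + 1):
        sd = resid.std()
        if sd <= 0 or resid.max() <= peak_threshold_sd * sd:
            break
        if len(peaks) >= max_peaks:
            warnings.warn("aperiodic model: peak budget exhausted before noise floor")
            break
        i = int(np.argmax(resid))
        height = float(resid[i])
        center = float(f[i])
        # half-height width from the residual profile
        half = height / 2.0
        left = i
        while left > 0 and resid[left] > half:
            left -= 1
        right = i
        while right < len(f) - 1 and resid[right] > half:
            right += 1
        fwhm = max(f[right] - f[left], min_peak_width)
        width = float(fwhm / 2.355)
        peaks.append({"center": center, "height": height, "width": width})
        resid = resid - _gauss(f, center, height, width)
    # refit the aperiodic component on the peak-subtracted spectrum
    removed = logp - sum((_gauss(f, **pk) for pk in peaks), np.zeros_like(f))
    beta, ap = aperiodic_fit(removed)
    est = SlopeEstimate(float(beta[0]), float(beta[1]), _r2(removed, ap),
                        tuple(band), "aperiodic_model")
    return est, peaks


def _resampled_psd(x: np.ndarray, fs: float, factor: Fraction, nperseg: int) -> tuple[np.ndarray, np.ndarray]:
    y = sp_signal.resample_poly(x, factor.numerator, factor.denominator)
    return sp_signal.welch(y, fs=fs, nperseg=min(nperseg, y.size), window="hann")


def irasa_fractal_psd(
    x: np.ndarray,
    fs: float,
    h_set: tuple[float, ...] = tuple(np.round(np.arange(1.1, 1.95, 0.05), 2)),
    nperseg_sec: float = 4.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Irregular-resampling auto-spectral analysis (IRASA).

    For each resampling factor h the signal is resampled by h and by 1/h and
    the geometric mean of the two PSDs is taken; a fractal (scale-free)
    component is invariant under this pairing while any oscillatory peak is
    displaced to h*f and f/h and suppressed by the median across the h set.

    Returns (freqs, fractal_psd, oscillatory_residual) where the residual is
    original - fractal on the same grid.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 10 * fs:
        raise ValueError("IRASA needs at least 10 s of signal for low-frequency use")
    for h in h_set:
        if h <= 0 or abs(h - 1.0) < 1e-9:
            raise ValueError("resampling factors must be positive and != 1")
    nperseg = int(round(nperseg_sec * fs))
    freqs, pxx = sp_signal.welch(x, fs=fs, nperseg=nperseg, window="hann")
    geo = np.empty((len(h_set), freqs.size))
    for k, h in enumerate(h_set):
        frac = Fraction(h).limit_denominator(100)
        _, up = _resampled_psd(x, fs, frac, nperseg)
        _, down = _resampled_psd(x, fs, 1 / frac, nperseg)
        m = min(up.size, down.size, freqs.size)
        geo[k, :m] = np.sqrt(up[:m] * down[:m])
        geo[k, m:] = np.nan
    fractal = np.nanmedian(geo, axis=0)
    return freqs, fractal, pxx - fractal


def time_resolved_slope(
    recording: Recording,
    segment_sec: float = 30.0,
    band: tuple[float, float] = DEFAULT_BAND,
    method: str = "linear",
    halfbandwidth: float = 0.5,
    fmin: float = 0.5,
    fmax: float = 45.0,
    fstep: float = 0.5,
) -> SlopeTrack:
    """Slope fitted per non-overlapping multitaper segment, per channel.

    A fit failure in one segment yields NaN for that (segment, channel)
    rather than aborting the track.
    """
    psd = compute_psd(recording, "multitaper", segment_sec, halfbandwidth,
                      fmin=fmin, fmax=max(fmax, band[1]), fstep=fstep)
    assert psd.per_segment is not None
    n_seg, n_ch, _ = psd.per_segment.shape
    if n_seg < 2:
        raise ValueError("need at least 2 segments for a slope track")
    fitter = {"linear": fit_slope_linear, "robust": fit_slope_robust}[method]
    slopes = np.full((n_seg, n_ch), np.nan)
    r2 = np.full((n_seg, n_ch), np.nan)
    for s in range(n_seg):
        for c in range(n_ch):
            try:
                est = fitter(psd.freqs, psd.per_segment[s, c], band)
            except (ValueError, RuntimeError):
                continue
            slopes[s, c] = est.slope
            r2[s, c] = est.r_squared
    times = np.arange(n_seg) * segment_sec
    return SlopeTrack(times, slopes, r2, tuple(band), method, segment_sec,
                      list(recording.channel_labels))


def slope_parameter_scan(
    recording: Recording,
    hypnogram,
    bands: list[tuple[float, float]],
    segment_sec: float = 30.0,
    n_bins: int = 5,
) -> list[dict]:
    """Recompute the slope track and its hypnogram MI for each candidate band.

    Returns one dict per band: {band, track, mi} sorted by descending MI.
    Used to rank fit ranges, e.g. +/-10 Hz windows around candidate center
    frequencies.
    """
    from .state_tracking import align_to_hypnogram, discretize_values, mutual_information

    nyquist = recording.fs / 2
    results = []
    for band in bands:
        if band[1] > nyquist:
            raise ValueError(f"band {band} exceeds the Nyquist frequency")
        track = time_resolved_slope(recording, segment_sec, band,
                                    fmax=min(band[1], nyquist * 0.98))
        slopes, labels = align_to_hypnogram(track, hypnogram)
        mi = mutual_information(discretize_values(slopes, n_bins), labels)
        results.append({"band": tuple(band), "track": track, "mi": mi})
    return sorted(results, key=lambda r: -r["mi"])
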