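"""Fronto-parietal connectivity metrics for comparison with slope tracking.

Per 30 s epoch and channel pair: magnitude-squared coherence (4 s Hann
sub-windows, 50% overlap, band-averaged — theta 4-10 Hz by default), phase
locking value and its imaginary part (volume-conduction robust), and log
power-envelope correlations, optionally orthogonalized by removing from one
signal the component parallel to the other before taking its envelope.  A
per-epoch metric track can then be compared to the slope track by Mutual
Information with the hypnogram.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sp_signal

from .state_tracking import Hypnogram, discretize_values, mutual_information

__all__ = [
    "coherence_pair",
    "phase_locking_pair",
    "power_correlation_pair",
    "compare_tracking",
]

THETA_BAND = (4.0, 10.0)


def _epochs(x: np.ndarray, fs: float, epoch_sec: float) -> np.ndarray:
    n = int(round(epoch_sec * fs))
    n_ep = x.size // n
    return x[: n_ep * n].reshape(n_ep, n)


def coherence_pair(x: np.ndarray, y: np.ndarray, fs: float,
                   band: tuple[float, float] = THETA_BAND,
                   epoch_sec: float = 30.0,
                   subwindow_sec: float = 4.0) -> np.ndarray:
    """Band-averaged magnitude-squared coherence per epoch.

    |Sxy|^2 / (Sxx * Syy) from Welch cross-spectra with 4 s Hann
    sub-windows and 50% overlap inside each 30 s epoch.
    """
    ex, ey = _epochs(np.asarray(x, float), fs, epoch_sec), _epochs(np.asarray(y, float), fs, epoch_sec)
    nseg = int(round(subwindow_sec * fs))
    if ex.shape[1] // (nseg // 2) - 1 < 4:
        raise ValueError("need at least 4 sub-windows per epoch")
    out = np.empty(ex.shape[0])
    for i in range(ex.shape[0]):
        f, cxy = sp_signal.coherence(ex[i], ey[i], fs=fs, window="hann",
                                     nperseg=nseg, noverlap=nseg // 2)
        mask = (f >= band[0]) & (f <= band[1])
        out[i] = float(cxy[mask].mean())
    return out


def _analytic(x: np.ndarray, fs: float, band: tuple[float, float]) -> np.ndarray:
    if band[1] >= fs / 2:
        raise ValueError("band exceeds the Nyquist frequency")
    sos = sp_signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    return sp_signal.hilbert(sp_signal.sosfiltfilt(sos, x))


def phase_locking_pair(x: np.ndarray, y: np.ndarray, fs: float,
                       band: tuple[float, float] = THETA_BAND,
                       epoch_sec: float = 30.0) -> tuple[np.ndarray, np.ndarray]:
    """PLV and imaginary PLV per epoch.

    PLV = |mean exp(i dphi)|; iPLV = |mean imag(exp(i dphi))| discounts
    zero-lag (volume-conducted) coupling.
    """
    ax = _analytic(np.asarray(x, float), fs, band)
    ay = _analytic(np.asarray(y, float), fs, band)
    dphi = np.exp(1j * (np.angle(ax) - np.angle(ay)))
    ep = _epochs(dphi, fs, epoch_sec)
    plv = np.abs(ep.mean(axis=1))
    iplv = np.abs(ep.imag.mean(axis=1))
    return plv, iplv


def power_correlation_pair(x: np.ndarray, y: np.ndarray, fs: float,
                           band: tuple[float, float] = THETA_BAND,
                           epoch_sec: float = 30.0,
                           orthogonalize: bool = False) -> np.ndarray:
    """Correlation of log power envelopes per epoch.

    With ``orthogonalize``, the envelope of y's component orthogonal to x,
    imag(Y * conj(X) / |X|), is correlated with |X|; the measure is
    symmetrized by averaging both directions.
    """
    ax = _analytic(np.asarray(x, float), fs, band)
    ay = _analytic(np.asarray(y, float), fs, band)
    ex_a, ey_a = _epochs(ax, fs, epoch_sec), _epochs(ay, fs, epoch_sec)
    out = np.empty(ex_a.shape[0])
    for i in range(ex_a.shape[0]):
        X, Y = ex_a[i], ey_a[i]
        if orthogonalize:
            y_orth = np.abs(np.imag(Y * np.conj(X) / np.abs(X)))
            x_orth = np.abs(np.imag(X * np.conj(Y) / np.abs(Y)))
            # an orthogonal component at roundoff level (collinear signals)
            # carries no power information, only scaled numerical noise
            r1 = (_logpow_corr(np.abs(X), y_orth)
                  if np.mean(y_orth**2) > 1e-12 * np.mean(np.abs(Y) ** 2) else 0.0)
            r2 = (_logpow_corr(np.abs(Y), x_orth)
                  if np.mean(x_orth**2) > 1e-12 * np.mean(np.abs(X) ** 2) else 0.0)
            out[i] = 0.5 * (r1 + r2)
        else:
            out[i] = _logpow_corr(np.abs(X), np.abs(Y))
    return out


def _logpow_corr(a: np.ndarray, b: np.ndarray) -> float:
    la, lb = np.log(a**2 + 1e-30), np.log(b**2 + 1e-30)
    if la.std() == 0 or lb.std() == 0:
        raise ValueError("zero envelope variance")
    return float(np.corrcoef(la, lb)[0, 1])


def compare_tracking(tracks: dict[str, np.ndarray], hypnogram: Hypnogram,
                     n_bins: int = 5) -> list[dict]:
    """MI of each per-epoch metric track with the hypnogram, ranked.

    All tracks must be epoch-aligned to the hypnogram (one value per epoch,
    truncated to the shorter of the two).  Returns [{metric, mi, n_epochs}]
    sorted by descending MI.
    """
    results = []
    for name, vals in tracks.items():
        v = np.asarray(vals, dtype=float)
        n = min(v.size, len(hypnogram))
        if n < 2:
            raise ValueError(f"track {name!r} has no epochs in common with the hypnogram")
        v = v[:n]
        labels = hypnogram.labels[:n]
        keep = np.isfinite(v)
        v = v[keep]
        labels = [labels[i] for i in np.flatnonzero(keep)]
        mi = mutual_information(discretize_values(v, n_bins), labels)
        results.append({"metric": name, "mi": mi, "n_epochs": int(v.size)})
    return sorted(results, key=lambda r: -r["mi"])
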