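"""Relating the time-resolved slope to the hypnogram.

The slope track is epoched to the 30 s hypnogram grid, discretized into five
equal-width bins, and its dependence on the stage sequence quantified with
plug-in Mutual Information (bits).  Significance is calibrated with
block-swap surrogates: the hypnogram is cut into B contiguous blocks
(B = number of distinct stages present, by default) at random interior cut
points and the block order permuted, preserving stage marginals and local
autocorrelation.  The observed MI is z-scored against the surrogate
distribution; z = 1.96 corresponds to an uncorrected two-tailed p of 0.05
and z > 2.8 to a Bonferroni-corrected threshold for 19 channels
(0.05/19 = 0.0026).

Rank (Spearman) correlation against an ordinal sleep-depth coding, with an
optional EMG-slope covariate partialled out, and per-state summaries
(mean +/- SEM) complete the module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sp_stats

__all__ = [
    "Hypnogram",
    "SurrogateResult",
    "align_to_hypnogram",
    "discretize_values",
    "mutual_information",
    "block_swap_surrogates",
    "surrogate_zscore",
    "correlate_with_hypnogram",
    "state_summary",
    "DEPTH_CODING",
]

ALLOWED_STAGES = {"W", "N1", "N2", "N3", "REM", "ANESTHESIA", "UNKNOWN"}

# Ordinal sleep-depth convention (increasing cortical synchronization).
DEPTH_CODING = {"W": 0, "REM": 1, "N1": 2, "N2": 3, "N3": 4}


@dataclass
class Hypnogram:
    """Stage label per fixed-length (30 s) epoch."""

    labels: list[str]
    epoch_sec: float = 30.0

    def __post_init__(self) -> None:
        self.labels = list(self.labels)
        if not self.labels:
            raise ValueError("hypnogram is empty")
        bad = set(self.labels) - ALLOWED_STAGES
        if bad:
            raise ValueError(f"unknown stage labels: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def stages_present(self) -> list[str]:
        return sorted(set(self.labels))

    def as_depth(self, coding: dict[str, int] | None = None) -> np.ndarray:
        coding = coding or DEPTH_CODING
        return np.array([coding[s] for s in self.labels], dtype=float)


@dataclass
class SurrogateResult:
    observed: float
    surrogate_mean: float
    surrogate_sd: float
    z: float
    p_two_tailed: float
    n_surrogates: int
    significant_uncorrected: bool = field(init=False)
    significant_bonferroni_19ch: bool = field(init=False)

    def __post_init__(self) -> None:
        self.significant_uncorrected = abs(self.z) > 1.96
        self.significant_bonferroni_19ch = abs(self.z) > 2.8


def align_to_hypnogram(track, hypnogram: Hypnogram,
                       channel: int = 0) -> tuple[np.ndarray, list[str]]:
    """One slope value per hypnogram epoch, paired with its stage label.

    Track segments must tile the 30 s epochs exactly (spacing equal to the
    epoch length or an integer divisor of it; sub-segments are averaged).
    Epochs whose slope is missing (NaN) are dropped from both sequences.
    """
    seg = track.segment_sec
    ratio = hypnogram.epoch_sec / seg
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError("track segment length must divide the hypnogram epoch")
    k = int(round(ratio))
    vals = track.slopes[:, channel]
    n_ep = min(len(hypnogram), vals.size // k)
    if n_ep == 0:
        raise ValueError("no overlapping epochs between track and hypnogram")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        per_epoch = np.nanmean(vals[: n_ep * k].reshape(n_ep, k), axis=1)
    keep = np.isfinite(per_epoch)
    labels = [hypnogram.labels[i] for i in np.flatnonzero(keep)]
    if not labels:
        raise ValueError("no overlapping epochs after removing missing slopes")
    return per_epoch[keep], labels


def discretize_values(values: np.ndarray, n_bins: int = 5) -> np.ndarray:
    """Equal-width binning over [min, max]; returns integer labels 1..n_bins.

    The maximum is assigned to the top bin.  Labels are invariant to affine
    transforms of the input.
    """
    values = np.asarray(values, dtype=float)
    if np.unique(values).size < n_bins:
        raise ValueError(f"need at least {n_bins} distinct values")
    edges = np.linspace(values.min(), values.max(), n_bins + 1)
    return np.clip(np.digitize(values, edges[1:-1], right=False) + 1, 1, n_bins)


def mutual_information(x_labels, y_labels) -> float:
    """Plug-in Mutual Information in bits between two discrete sequences.

    MI(X;Y) = sum_xy p(x,y) log2[ p(x,y) / (p(x) p(y)) ], probabilities
    normalized by their sum; zero-count cells contribute nothing.
    """
    x = np.asarray(x_labels)
    y = np.asarray(y_labels)
    if x.size != y.size:
        raise ValueError("sequences must have equal length")
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    xi = np.unique(x, return_inverse=True)[1]
    yi = np.unique(y, return_inverse=True)[1]
    joint = np.zeros((xi.max() + 1, yi.max() + 1))
    np.add.at(joint, (xi, yi), 1.0)
    p = joint / joint.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float(np.sum(p[nz] * np.log2(p[nz] / (px @ py)[nz])))


def block_swap_surrogates(hypnogram: Hypnogram, n_surrogates: int, seed: int,
                          n_blocks: int | None = None,
                          repetitions: str = "blocks") -> list[list[str]]:
    """Surrogate hypnograms by random block swapping.

    The label sequence is cut into B contiguous blocks at uniformly random
    interior cut points and the block order permuted.  By default
    B = number of distinct stages present (``repetitions='blocks'``); the
    alternative reading ``repetitions='swaps'`` applies B random pairwise
    block swaps to a fixed 2B-block partition instead.  Label counts are
    preserved exactly; deterministic given the seed.
    """
    labels = np.asarray(hypnogram.labels, dtype=object)
    n = labels.size
    B = n_blocks if n_blocks is not None else len(set(hypnogram.labels))
    if B < 2:
        warnings.warn("fewer than 2 stages present; surrogates equal the original")
        return [list(labels) for _ in range(n_surrogates)]
    if n < 2 * B:
        raise ValueError("hypnogram too short for the requested block count")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_surrogates):
        if repetitions == "blocks":
            cuts = np.sort(rng.choice(np.arange(1, n), size=B - 1, replace=False))
            blocks = np.split(labels, cuts)
            order = rng.permutation(len(blocks))
            out.append(list(np.concatenate([blocks[i] for i in order])))
        elif repetitions == "swaps":
            cuts = np.sort(rng.choice(np.arange(1, n), size=2 * B - 1, replace=False))
            blocks = np.split(labels, cuts)
            order = np.arange(len(blocks))
            for _s in range(B):
                i, j = rng.choice(len(blocks), size=2, replace=False)
                order[i], order[j] = order[j], order[i]
            out.append(list(np.concatenate([blocks[i] for i in order])))
        else:
            raise ValueError("repetitions must be 'blocks' or 'swaps'")
    return out


def surrogate_zscore(observed: float, surrogates) -> SurrogateResult:
    """z-score an observed statistic against its surrogate distribution."""
    surrogates = np.asarray(surrogates, dtype=float)
    if surrogates.size < 20:
        raise ValueError("need at least 20 surrogates")
    mu = float(surrogates.mean())
    sd = float(surrogates.std(ddof=1))
    if sd == 0:
        raise ValueError("zero surrogate standard deviation")
    z = (observed - mu) / sd
    p = 2.0 * sp_stats.norm.sf(abs(z))
    return SurrogateResult(float(observed), mu, sd, float(z), float(p),
                           int(surrogates.size))


def _rank(a: np.ndarray) -> np.ndarray:
    return sp_stats.rankdata(a)


def correlate_with_hypnogram(slope_series: np.ndarray, hypnogram: Hypnogram,
                             covariate: np.ndarray | None = None,
                             coding: dict[str, int] | None = None) -> tuple[float, float]:
    """Spearman correlation of the slope with ordinal sleep depth.

    With a covariate (e.g. the EMG channel's slope series) all three series
    are ranked and a partial correlation is computed by residualizing the
    ranks on the covariate ranks.
    """
    x = np.asarray(slope_series, dtype=float)
    depth = hypnogram.as_depth(coding)[: x.size]
    if np.unique(x).size < 2 or np.unique(depth).size < 2:
        raise ValueError("constant series")
    if covariate is None:
        rho, p = sp_stats.spearmanr(x, depth)
        return float(rho), float(p)
    zc = _rank(np.asarray(covariate, dtype=float))
    rx, rd = _rank(x), _rank(depth)

    def resid(v):
        A = np.column_stack([np.ones_like(zc), zc])
        return v - A @ np.linalg.lstsq(A, v, rcond=None)[0]

    ex, ed = resid(rx), resid(rd)
    if ex.std() == 0 or ed.std() == 0:
        return 0.0, 1.0
    r = float(np.corrcoef(ex, ed)[0, 1])
    n = x.size
    df = n - 3  # one covariate partialled out
    t = r * np.sqrt(df) / np.sqrt(max(1.0 - r**2, 1e-15))
    p = 2.0 * sp_stats.t.sf(abs(t), df)
    return r, float(p)


def state_summary(track, hypnogram: Hypnogram, states=None,
                  channel: int = 0) -> dict[str, dict[str, float]]:
    """Per-state mean +/- SEM of the slope over that state's epochs.

    Absent states are reported with NaN, never as zero.
    """
    slopes, labels = align_to_hypnogram(track, hypnogram, channel)
    states = list(states) if states is not None else sorted(set(labels))
    out = {}
    for st in states:
        vals = slopes[[i for i, s in enumerate(labels) if s == st]]
        if vals.size == 0:
            out[st] = {"mean": np.nan, "sem": np.nan, "n": 0}
        else:
            sem = float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else 0.0
            out[st] = {"mean": float(vals.mean()), "sem": sem, "n": int(vals.size)}
    return out
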