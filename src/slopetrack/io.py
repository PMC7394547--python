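"""Recording and hypnogram I/O plus montage re-referencing.

The native round-trip format is an array container (``.npy``) with a JSON
sidecar carrying the sampling rate, channel labels/roles and the generating
seed.  Hypnograms are plain text, one AASM label per line, 30 s epochs,
with a documented alias table (e.g. "NREM3", "S3", "SWS" -> N3).  EDF/EDF+
files can be read through mne when it is installed.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np

from .spectral import Recording
from .state_tracking import Hypnogram

__all__ = [
    "write_recording",
    "read_recording",
    "write_hypnogram",
    "read_hypnogram",
    "rereference",
    "STAGE_ALIASES",
]

log = logging.getLogger("slopetrack")

STAGE_ALIASES = {
    "W": "W", "WAKE": "W", "WK": "W", "0": "W",
    "N1": "N1", "NREM1": "N1", "S1": "N1", "1": "N1",
    "N2": "N2", "NREM2": "N2", "S2": "N2", "2": "N2",
    "N3": "N3", "NREM3": "N3", "S3": "N3", "S4": "N3", "SWS": "N3", "3": "N3", "4": "N3",
    "REM": "REM", "R": "REM", "5": "REM",
    "ANESTHESIA": "ANESTHESIA", "ANAESTHESIA": "ANESTHESIA",
    "UNKNOWN": "UNKNOWN", "?": "UNKNOWN", "A": "UNKNOWN",
}


def write_recording(rec: Recording, path: str | Path, seed: int | None = None) -> None:
    """Save samples to ``path``.npy and metadata to ``path``.json."""
    path = Path(path)
    np.save(path.with_suffix(".npy"), rec.data)
    meta = {
        "fs": rec.fs,
        "channel_labels": rec.channel_labels,
        "channel_roles": rec.channel_roles,
        "seed": seed,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def read_recording(path: str | Path, format: str = "array_container") -> Recording:
    """Load a recording from the array container or an EDF file."""
    path = Path(path)
    if format == "array_container":
        npy = path.with_suffix(".npy")
        if not npy.exists():
            raise FileNotFoundError(f"recording array not found: {npy}")
        meta = json.loads(path.with_suffix(".json").read_text())
        return Recording(np.load(npy), meta["fs"], meta["channel_labels"],
                         meta["channel_roles"])
    if format == "edf":
        return _read_edf(path)
    raise ValueError(f"unsupported recording format: {format!r}")


def _read_edf(path: Path) -> Recording:
    if not path.exists():
        raise FileNotFoundError(f"EDF file not found: {path}")
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("EDF reading requires mne (pip install mne)") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    sfreqs = {info["sfreq"] for info in [raw.info]}
    if len(sfreqs) > 1:  # pragma: no cover - mne resamples on load
        log.warning("EDF signals at mixed rates; resampled to %s Hz", max(sfreqs))
    data = raw.get_data() * 1e6  # volts -> microvolts
    labels = list(raw.ch_names)
    roles = ["EMG" if "EMG" in lb.upper() else
             "EOG" if "EOG" in lb.upper() else
             "ECG" if "ECG" in lb.upper() or "EKG" in lb.upper() else "EEG"
             for lb in labels]
    return Recording(data, float(raw.info["sfreq"]), labels, roles)


def write_hypnogram(hyp: Hypnogram, path: str | Path) -> None:
    Path(path).write_text("\n".join(hyp.labels) + "\n")


def read_hypnogram(path: str | Path) -> Hypnogram:
    """Read a plain-text hypnogram: one stage label per line (30 s epochs).

    Lines of the form ``onset<TAB>duration<TAB>stage`` are also accepted;
    the duration is split into 30 s epochs.  Unknown tokens are listed
    verbatim in the error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"hypnogram not found: {path}")
    labels: list[str] = []
    unknown: list[str] = []
    lines = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"empty hypnogram file: {path}")
    for ln in lines:
        parts = ln.replace(",", "\t").split()
        if len(parts) == 3:
            _onset, dur, token = parts
            reps = max(int(round(float(dur) / 30.0)), 1)
        else:
            token, reps = parts[0], 1
        canon = STAGE_ALIASES.get(token.upper())
        if canon is None:
            unknown.append(token)
        else:
            labels.extend([canon] * reps)
    if unknown:
        raise ValueError(f"unknown stage tokens: {unknown}")
    return Hypnogram(labels)


def rereference(rec: Recording, scheme: str = "common_average",
                adjacency: dict[int, set[int]] | None = None,
                mastoids: tuple[str, str] = ("M1", "M2")) -> Recording:
    """Re-reference the EEG channels of a recording.

    Schemes: ``common_average`` (subtract the mean of all EEG channels),
    ``linked_mastoids`` (subtract the average of the two mastoid channels),
    ``bipolar`` (successive channel differences), ``laplacian``
    (subtract the mean of the graph neighbors given by ``adjacency``).
    Non-EEG channels pass through unchanged except under ``bipolar``, where
    only the EEG subset is re-expressed.
    """
    eeg_idx = [i for i, r in enumerate(rec.channel_roles) if r in ("EEG", "iEEG")]
    data = rec.data.copy()
    if scheme == "common_average":
        data[eeg_idx] -= data[eeg_idx].mean(axis=0, keepdims=True)
        return Recording(data, rec.fs, rec.channel_labels, rec.channel_roles)
    if scheme == "linked_mastoids":
        mi = [rec.channel_labels.index(m) for m in mastoids if m in rec.channel_labels]
        if len(mi) != 2:
            raise ValueError(f"mastoid channels {mastoids} not found")
        ref = data[mi].mean(axis=0)
        data[eeg_idx] -= ref
        return Recording(data, rec.fs, rec.channel_labels, rec.channel_roles)
    if scheme == "bipolar":
        if len(eeg_idx) < 2:
            raise ValueError("bipolar montage needs at least 2 EEG channels")
        pairs = list(zip(eeg_idx[:-1], eeg_idx[1:]))
        bip = np.array([data[a] - data[b] for a, b in pairs])
        labels = [f"{rec.channel_labels[a]}-{rec.channel_labels[b]}" for a, b in pairs]
        other = [i for i in range(rec.n_channels) if i not in eeg_idx]
        full = np.vstack([bip, data[other]]) if other else bip
        return Recording(full, rec.fs,
                         labels + [rec.channel_labels[i] for i in other],
                         ["EEG"] * len(pairs) + [rec.channel_roles[i] for i in other])
    if scheme == "laplacian":
        if not adjacency:
            raise ValueError("laplacian montage needs an adjacency graph")
        out = data.copy()
        for i in eeg_idx:
            nbs = [n for n in adjacency.get(i, ()) if n in eeg_idx]
            if nbs:
                out[i] = data[i] - data[nbs].mean(axis=0)
        return Recording(out, rec.fs, rec.channel_labels, rec.channel_roles)
    raise ValueError(f"unknown reference scheme: {scheme!r}")
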