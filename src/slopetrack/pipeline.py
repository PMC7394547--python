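"""End-to-end pipeline: simulate (or load) -> PSD -> slope track -> MI ->
events -> classification -> stats, with every artifact written to disk.

A single master seed drives every stochastic stage (per-stage seeds are
derived from it with a SeedSequence), so an identical configuration yields
byte-identical numeric outputs.  Every output file records the package
version, the configuration hash and the seeds used.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import lda_balanced_cv, logit_transform
from .events import detect_slow_waves, event_locked_slope, event_rate_by_state
from .io import write_hypnogram, write_recording
from .simulate import DEFAULT_PROFILES, gen_hypnogram, gen_recording
from .slope import time_resolved_slope
from .state_tracking import (
    align_to_hypnogram,
    block_swap_surrogates,
    discretize_values,
    mutual_information,
    state_summary,
    surrogate_zscore,
)

__all__ = ["PipelineConfig", "run_pipeline"]

# Markov transition matrix over (W, N1, N2, N3, REM): sticky stages with
# physiologically ordered transitions (W->N1->N2->N3, REM entered from N2).
SLEEP_STATES = ("W", "N1", "N2", "N3", "REM")
SLEEP_TRANSITIONS = np.array([
    [0.90, 0.08, 0.02, 0.00, 0.00],  # W
    [0.05, 0.70, 0.23, 0.00, 0.02],  # N1
    [0.02, 0.03, 0.85, 0.07, 0.03],  # N2
    [0.01, 0.00, 0.09, 0.88, 0.02],  # N3
    [0.04, 0.02, 0.04, 0.00, 0.90],  # REM
])


@dataclass
class PipelineConfig:
    seed: int = 0
    n_epochs: int = 120
    n_channels: int = 2
    fs: float = 200.0
    segment_sec: float = 30.0
    halfbandwidth: float = 0.5
    band: tuple[float, float] = (30.0, 45.0)
    psd_method: str = "multitaper"
    n_surrogates: int = 100
    n_permutations: int = 1000
    lda_repeats: int = 20
    out_dir: str = "slopetrack_out"

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        d = json.loads(text)
        d["band"] = tuple(d["band"])
        return cls(**d)

    @property
    def config_hash(self) -> str:
        # out_dir does not influence any computed number
        d = dataclasses.asdict(self)
        d.pop("out_dir")
        return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:12]


def _provenance(cfg: PipelineConfig) -> dict:
    return {"version": __version__, "config_hash": cfg.config_hash, "seed": cfg.seed}


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the full synthetic analysis and write its report bundle.

    Returns the summary dict (also written to ``summary.json``).  Any stage
    failure raises with the stage name; artifacts written before the
    failure are left in place.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(cfg.seed)
    seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(6)]
    summary: dict = {"provenance": _provenance(cfg), "stage_seeds": seeds}

    stage = "simulate"
    try:
        hyp = gen_hypnogram(cfg.n_epochs, SLEEP_TRANSITIONS, SLEEP_STATES, "W", seeds[0])
        rec, gt = gen_recording(hyp, cfg.n_channels, cfg.fs, seeds[1])
        write_recording(rec, out / "recording", seed=seeds[1])
        write_hypnogram(hyp, out / "hypnogram.txt")

        stage = "slope_track"
        eeg = rec.pick({"EEG"})
        track = time_resolved_slope(eeg, cfg.segment_sec, cfg.band,
                                    halfbandwidth=cfg.halfbandwidth)
        rows = []
        for s in range(track.n_segments):
            for c, lb in enumerate(track.channel_labels):
                rows.append((track.times[s], lb, track.slopes[s, c],
                             track.r_squared[s, c], cfg.band[0], cfg.band[1], "linear"))
        pd.DataFrame(rows, columns=["segment_start_s", "channel", "slope",
                                    "r_squared", "band_lo", "band_hi", "method"]
                     ).to_csv(out / "slope_track.csv", index=False)

        stage = "state_tracking"
        slopes, labels = align_to_hypnogram(track, hyp)
        disc = discretize_values(slopes, 5)
        mi_obs = mutual_information(disc, labels)
        surr_hyps = block_swap_surrogates(hyp, cfg.n_surrogates, seeds[2])
        mi_surr = [mutual_information(disc, sh[: len(labels)]) for sh in surr_hyps]
        sres = surrogate_zscore(mi_obs, mi_surr)
        summ = state_summary(track, hyp)
        summary["mi"] = {"observed": sres.observed, "z": sres.z, "p": sres.p_two_tailed,
                         "surrogate_mean": sres.surrogate_mean,
                         "surrogate_sd": sres.surrogate_sd}
        summary["state_summary"] = summ
        pd.DataFrame([
            {"channel": "ch0", "statistic": "mi", "observed": sres.observed,
             "surrogate_mean": sres.surrogate_mean, "surrogate_sd": sres.surrogate_sd,
             "z": sres.z, "p": sres.p_two_tailed}
        ]).to_csv(out / "mi_results.csv", index=False)

        stage = "events"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sw = detect_slow_waves(rec, channel=0, hypnogram=hyp)
        rates = event_rate_by_state(sw, hyp)
        summary["slow_wave_rates_per_min"] = rates
        pd.DataFrame([
            {"channel": e.channel, "trough_time_s": e.trough_time,
             "start_s": e.start_time, "end_s": e.end_time, "duration_s": e.duration,
             "p2p_uv": e.peak_to_peak_amplitude, "state": e.state_at_event}
            for e in sw
        ]).to_csv(out / "slow_waves.csv", index=False)
        if sw:
            locked = event_locked_slope(rec, sw, channel=0)
            summary["event_locked_mean_trough_slope"] = float(
                locked["mean"][np.argmin(np.abs(locked["window_centers"]))]
            )

        stage = "classify"
        cls_rows = []
        lab_arr = np.asarray(labels)
        for a, b in (("W", "REM"), ("W", "N3")):
            mask = np.isin(lab_arr, [a, b])
            if np.unique(lab_arr[mask]).size == 2 and min(
                np.sum(lab_arr[mask] == a), np.sum(lab_arr[mask] == b)) >= 2:
                res = lda_balanced_cv(slopes[mask], lab_arr[mask],
                                      n_repeats=cfg.lda_repeats, seed=seeds[3])
                cls_rows.append({"comparison": f"{a}_vs_{b}", "feature_set": "slope",
                                 "accuracy_pct": res.accuracy,
                                 "logit_mean": logit_transform(res.accuracy / 100),
                                 "n_repeats": res.n_repeats, "seed": seeds[3]})
        if cls_rows:
            pd.DataFrame(cls_rows).to_csv(out / "classification.csv", index=False)
            summary["classification"] = cls_rows

        summary["ground_truth_states"] = gt.states[:10]
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (out / "summary.json").write_text(json.dumps(summary, indent=1, default=float))
    return summary
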