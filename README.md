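# slopetrack

Estimation of the aperiodic **1/f spectral slope** of EEG/iEEG power spectra
and its use as an electrophysiological marker of arousal — separating
wakefulness from NREM sleep, REM sleep, and propofol anesthesia.

Spectra of neural field recordings follow a scale-free background
PSD(f) ∝ 1/f^α; the log-log slope β = −α of a straight line fitted over
**30–45 Hz** tracks arousal level: it is shallowest in wakefulness
(group means near −1.8), intermediate in NREM (≈ −3.5), and steepest in
REM sleep (≈ −4.7) and under anesthesia (≈ −3.1). `slopetrack` implements
the full analysis chain around that statistic:

- **spectral** — multitaper PSD with dpss tapers (K = 2·T·W − 1, e.g.
  29 tapers for 30 s segments at ±0.5 Hz smoothing), plus Hann, rectangular
  periodogram and Welch estimators for SNR comparison; event-locked
  short-window time-frequency decomposition.
- **slope** — log-log linear fits, bisquare robust fits, an aperiodic model
  with iterative Gaussian peak removal, IRASA fractal/oscillatory
  separation, time-resolved slope tracks, and fit-band parameter scans.
- **state_tracking** — Mutual Information between the discretized slope
  track and the hypnogram, calibrated with block-swap surrogates
  (z = 1.96 ↔ two-tailed p = 0.05), Spearman/partial rank correlations,
  and per-state summaries.
- **events** — slow-oscillation detection (0.16–1.25 Hz bandpass, zero
  crossings, 0.8–2 s duration, 75th-percentile amplitude criterion) and
  slow-wave-locked slope time courses (±2.5 s, 0.5 s windows, 0.25 s step).
- **stats** — sign-flip permutation t-tests, permutation repeated-measures
  ANOVA with Greenhouse–Geisser correction, channel-level cluster
  permutation tests (maxsize criterion), Cohen's d, Yates-corrected 2×2
  chi-squared, and the r→t transform.
- **classify** — balanced leave-one-out LDA (logit-averaged accuracies) and
  a two-predictor GLM (slope + slow-oscillation power + interaction) with
  eta-squared variance decomposition.
- **connectivity** — coherence, PLV/iPLV and (orthogonalized) power-envelope
  correlations as control comparisons for state tracking.
- **simulate** — a synthetic polysomnography generator with exact ground
  truth (per-state 1/f exponents, oscillation bursts, slow-wave events,
  Markov stage sequences, EMG contamination), so the whole pipeline is
  testable without clinical recordings.

## Worked example

```python
from slopetrack.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(seed=7, n_epochs=80, fs=200.0, out_dir="demo_out")
summary = run_pipeline(cfg)
```

This simulates 40 minutes of two-channel sleep EEG plus an EMG channel,
computes the 30 s multitaper slope track, relates it to the simulated
hypnogram, detects slow waves and classifies states. The summary prints:

```
MI(slope, hypnogram)  = 1.098 bits
surrogate z           = 3.46  p = 5.3e-04
slope[  W] = -1.83 +/- 0.06  (n=47)
slope[ N1] = -2.62 +/- 0.22  (n=2)
slope[ N2] = -3.68 +/- 0.07  (n=20)
slope[ N3] = -3.58 +/- 0.17  (n=7)
slope[REM] = -5.25 +/- 0.25  (n=4)
LDA W_vs_REM: 100.0% correct
LDA W_vs_N3: 98.6% correct
slow waves/min: {'N1': 7.0, 'N2': 12.1, 'N3': 16.6, 'REM': 7.0, 'W': 5.7}
```

The slope track recovers each state's generating exponent (wake −1.84,
N2 −3.67, REM −4.73 targets), the Mutual Information with the hypnogram is
significant against block-swap surrogates (z > 2.8 would survive a
19-channel Bonferroni correction; here z = 3.46 on one channel), the
wake-vs-REM discrimination from the slope alone is essentially perfect at
this effect size, and detected slow-wave rates are highest in N3 — the
expected ordering across arousal states.

A thin CLI wraps the same functions:

```bash
slopetrack simulate --seed 7 --n-epochs 80 --out syn
slopetrack track syn --out track.csv
slopetrack events syn --hypnogram syn.hypnogram.txt --out sw.csv
slopetrack report --seed 7 --out-dir demo_out
```

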