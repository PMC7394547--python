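# Methods

## The statistic

All analyses revolve around the aperiodic exponent of the power spectrum.
For a scale-free background PSD(f) ∝ 1/f^α, an ordinary least-squares line
fitted to log₁₀ power against log₁₀ frequency over a stated band has slope
β = −α. The working band is **30–45 Hz**: below ~30 Hz strong oscillations
(slow waves, spindles, alpha) distort the fit, and above ~50 Hz line noise
and broadband EMG dominate. Band endpoints are inclusive on the 0.5 Hz
analysis grid (30.0 … 45.0 → 31 points). Fits use log₁₀ on both axes; the
slope is invariant to the log base and to any global rescaling of the
signal (both properties are under test).

## Spectral estimation

PSDs are computed on non-overlapping segments (30 s for sleep, 10 s for
anesthesia), each demeaned and linearly detrended, on a 0.5–45 Hz grid in
0.5 Hz steps (nearest FFT bins). The multitaper estimator uses discrete
prolate spheroidal (dpss) tapers with the count rule

    K = 2·T·W − 1

where T is the segment length (s) and W the one-sided smoothing halfwidth
(Hz): 29 tapers for 30 s and 9 tapers for 10 s at W = 0.5 Hz. Hann,
rectangular-periodogram and Welch (one Hamming window per segment)
estimators are provided for the SNR comparison (mean/SD across segments
per bin); the multitaper estimate wins that comparison by a wide margin.

**Taper weighting.** Eigenspectra are combined with Thomson's adaptive
weights d_k(f) = S(f) / (λ_k S(f) + (1 − λ_k)σ²), iterated to a fixed
point, rather than a plain average. The last taper retained by the
K = 2TW − 1 rule has eigenvalue ≈ 0.89, and its broadband leakage floors
the high-frequency tail of any spectrum whose dynamic range exceeds
~40 dB; steep (β ≤ −3.5) spectra are unrecoverable under unity weights but
recovered to within 0.1 adaptively (cross-checked against an independent
adaptive multitaper implementation). `taper_weights="unity"` restores the
plain average. Power is returned as one-sided density (unit²/Hz); segments
containing NaN are excluded from averages rather than interpolated.

**Estimator variance.** With ±0.5 Hz smoothing the 31 grid points in
30–45 Hz are strongly correlated, so a *single-segment* slope estimate
scatters with SD ≈ 0.4 even though it is unbiased; claims about recovery
accuracy therefore refer to the mean over segments (20 min of signal gives
a standard error well under 0.1). Event-locked windows (0.5 s, one taper,
±2 Hz) are far noisier still (per-window slope SD ≈ 3.4); event-locked
conclusions always average over ≥ 100 events.

## Slope estimators

- **linear** — OLS in log-log space; requires positive power at ≥ 3 band
  points; reports slope, intercept and R².
- **robust** — iteratively reweighted least squares with Tukey bisquare
  weights (tuning 4.685, residual scale MAD/0.6745 with leverage
  adjustment, ≤ 50 iterations). Identical to OLS on outlier-free spectra.
- **aperiodic model** — alternating line fit / Gaussian peak removal: the
  largest residual above 2 SD of the residuals seeds a Gaussian (center at
  the peak bin, width from the half-height span, floor 0.5 Hz), which is
  subtracted; iteration stops at the noise floor or at `max_peaks`
  (warning). No knee term by default; the knee-free model is equivalent to
  a log-log line.
- **IRASA** — for each resampling factor h ∈ {1.1, 1.15, …, 1.9} the
  signal is resampled by h and 1/h and the geometric mean of the two Welch
  PSDs taken; the median across h is the fractal component, the remainder
  the oscillatory residual. Default 4 s Hann sub-windows; low-frequency
  work (tones near 2–3 Hz) needs 8 s windows so that displaced peaks leave
  the main lobe.

The time-resolved track applies the multitaper + linear fit per segment,
with per-segment failures recorded as NaN rather than aborting. The
parameter-scan utility re-derives the track and its hypnogram MI for each
candidate band and ranks bands by MI.

## State tracking

The track is epoched to the 30 s hypnogram grid (sub-segments averaged;
missing epochs dropped pairwise), discretized into five equal-width bins,
and compared to the stage sequence with plug-in Mutual Information in bits.
Significance uses block-swap surrogates: the stage sequence is cut into B
contiguous blocks at uniformly random interior cut points and block order
permuted, preserving stage counts exactly and most local autocorrelation;
B defaults to the number of distinct stages present (an alternative
"B pairwise swaps of a 2B-block partition" reading is available behind a
flag). The observed MI is z-scored against ≥ 20 surrogates; z = 1.96
corresponds to an uncorrected two-tailed p of 0.05 and z > 2.8 to a
19-channel Bonferroni threshold (0.05/19 ≈ 0.0026). Under a
state-independent null the |z| > 1.96 rejection rate calibrates to ≈ 3–5%
(the MI null is right-skewed, so the normal transform is slightly
conservative). Rank correlations code sleep depth ordinally as
W=0 < REM=1 < N1=2 < N2=3 < N3=4 (configurable); the partial variant ranks
all three series and residualizes on the covariate's ranks.

## Slow waves

Detection: zero-phase 4th-order Butterworth bandpass 0.16–1.25 Hz;
candidates span successive positive-to-negative zero crossings; events must
last 0.8–2.0 s and their trough-to-peak amplitude must reach the 75th
percentile of the duration-valid candidates on that channel (per-channel,
stage-agnostic; the percentile reference set is configurable). The trough
is the filtered-trace minimum. Fewer than 4 candidates make the percentile
meaningless → empty result with a warning. Because the threshold keeps the
top quarter of candidates by construction, detector benchmarks must supply
roughly three background candidates per injected event; with that pool the
detector achieves recall and precision ≥ 0.9 against injected ground truth.

Event-locked analysis epochs the raw trace ±2.5 s around troughs (edge
events dropped), computes sliding-window spectra (0.5 s windows, 0.25 s
step, one dpss taper, ±2 Hz smoothing → 19 windows, centers −2.25 … +2.25 s)
and fits the 30–45 Hz slope per window, reporting per-event courses and
the across-event mean ± SEM, plus per-state trough-window summaries and
per-state event rates (events per minute spent in the stage).

## Statistics

Permutation conventions: Monte-Carlo p = (#{|stat*| ≥ |stat|} + 1)/(n+1);
exhaustive sign-flip enumerations (2ⁿ ≤ budget) report the exact
p = #/2ⁿ, the identity flip guaranteeing p > 0. The paired t-test flips
difference signs; the one-way repeated-measures ANOVA permutes condition
labels within subject and attaches Greenhouse–Geisser-corrected degrees of
freedom (ε = 1 exactly under compound symmetry) to the observed F. The
channel-level cluster test thresholds per-channel paired t-tests at
p < 0.05 two-tailed, joins suprathreshold channels through an adjacency
graph (a 19-channel 10-20 template graph ships with the package), uses
cluster *size* as the statistic and the permutation maximum cluster size as
the null. Note that with saturating effects the size statistic plateaus at
the channel count, so corrected p is monotone in effect size only below
saturation. Cohen's d ships in pooled-SD and paired-difference variants,
with the variant always recorded: published d values cannot be reproduced
from printed t statistics under either convention alone, so no single
convention is privileged. The 2×2 chi-squared applies the Yates continuity
correction by default — only the corrected statistic reproduces the
reference values 33.56 and 33.12 — and always reports the uncorrected value
alongside.

## Classification and GLM

LDA uses balanced leave-one-out cross-validation: each of (default) 50
repeats subsamples every class to the minority count, then holds out each
trial once; accuracy is percent correct averaged over repeats, and
accuracies are logit-transformed (p clipped to [1e-4, 1−1e-4]) before any
cross-channel averaging. Pooled-covariance LDA comes from scikit-learn;
singular covariances fall back to a small recorded shrinkage. Features are
used per channel (1-D slope or slow-oscillation power), then aggregated.

The GLM z-scores both predictors and fits state ~ slope + SO + slope×SO by
OLS; eta squared per term is that term's sum of squares over the total sum
of squares, Type II by default (Types I/III available, the type always
recorded; for orthogonal designs all types coincide, which is under test).

## Connectivity controls

Per 30 s epoch and channel pair: magnitude-squared coherence (4 s Hann
sub-windows, 50% overlap, averaged over the band — theta 4–10 Hz default);
PLV = |mean e^{iΔφ}| and iPLV = |mean Im e^{iΔφ}| from band-passed analytic
signals; log power-envelope correlation, optionally orthogonalized
(Im(Y·conj(X)/|X|), symmetrized over both directions; an orthogonal
component at roundoff level is treated as zero coupling rather than
correlated numerical noise). The `compare_tracking` utility ranks any set
of epoch-aligned tracks by MI with the hypnogram.

## Synthetic data

The generator emulates the statistical structure the analysis assumes, not
sleep physiology. Each state contributes:

- a **1/f background** with the state's target slope, synthesized by
  shaping white-noise Fourier amplitudes by f^(slope/2) (DC zeroed, unit
  variance). The power law holds over a validity band (default 1–100 Hz);
  below its low edge the spectrum is held flat, since physiological spectra
  plateau at the slowest frequencies and an unbounded power law would both
  be unrealistic and put essentially all variance into the lowest FFT bins.
- **oscillation bursts** — randomized-phase sinusoids gated by smoothly
  ramped on/off envelopes covering a duty-cycle fraction of the epoch
  (wake: alpha 10 Hz; N2/N3: spindles 14 Hz; anesthesia: ~1 Hz).
- **slow waves** — Hann-enveloped biphasic (trough-then-peak) cycles with
  durations drawn from 0.8–2.0 s, placed by stick-breaking (durations
  drawn, remaining time distributed as random gaps, ≥ 0.25 s refractory
  gap), which stays feasible at the N3 rate of 28.79/min; exact trough
  times are returned as ground truth. The Hann envelope keeps the event's
  spectral sidelobes out of the 30–45 Hz fit band.
- an **EMG channel** — Gaussian noise high-pass filtered at 40 Hz, scaled
  per epoch by the state's muscle tone (wake 1.0, REM 0.05 — atonia).

Stage sequences come from a first-order Markov chain (one label per 30 s
epoch) with sticky, physiologically ordered default transitions. Epoch
boundaries are joined with 1 s cosine cross-fades to avoid spectral edge
artifacts. Everything derives from a single seed.

Default target slopes are published group means — wake −1.84, N2 −3.67,
N3 −3.46, REM −4.73, anesthesia −3.10; N1, for which no group mean is
printed, uses −2.5 as an interpolation between wake and N2. Slow-wave rates
default to 28.79/min (N3), 5.05/min (wake), 2.16/min (REM). Oscillation
amplitudes, duty cycles and EMG levels are generator choices with
documented defaults. The generator deliberately omits K-complexes, sawtooth
waves, eye movements, artifacts and inter-subject variability — so passing
tests demonstrate correctness of the estimators under the assumed
statistical structure, not performance on clinical recordings.

## Numerical choices and degenerate inputs

- Equal-width slope bins for MI (affine-invariant); constant series are
  rejected rather than silently binned.
- SNR at zero cross-segment SD is flagged as +inf, never dropped.
- Zero-variance differences, degenerate contingency margins, |r| ≥ 1,
  constant predictors and rank-deficient designs all raise explicit errors.
- Per-segment fit failures propagate as NaN through tracks and are dropped
  pairwise in alignment.
- Reference schemes (common average, linked mastoids, bipolar, Laplacian
  from an adjacency graph) are preprocessing options on recordings.

## Problem sizes

Simulation-backed tests use 20–40 minutes of synthetic signal at
fs = 200 Hz (400 Hz where the claim refers to that rate), 500-run
calibrations for type-I error, 100+ events for event-locked claims and
60-event injection benchmarks for the detector — sizes at which the
measured standard errors sit comfortably inside the asserted tolerances.

## Known limitations

- Unity-weight multitaper averaging (the classical estimator) cannot
  recover slopes steeper than ≈ −3.5 from a full-range synthetic power law;
  adaptive weighting is the package default for this reason.
- Short-window event-locked slopes are extremely noisy at the published
  window parameters; single-event courses should never be interpreted.
- The block-swap surrogate with B = number of stages preserves substantial
  slope-hypnogram alignment (its purpose); its mean MI sits between the
  full-shuffle floor and the observed value and approaches the floor only
  as B grows.
- EDF support is a thin optional wrapper; the array-container + JSON
  sidecar is the native format.
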