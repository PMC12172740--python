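# Methods

This note documents the models, conventions and numerical choices behind
erpbench, in the spirit of a methods appendix: what is simulated, what the
pipeline does, where the design was genuinely open, and what the tests do
and do not demonstrate.

## Time and amplitude conventions

Voltages are microvolts throughout; channel × sample matrices with time on
the last axis. Epoch windows are half-open `[start, end)` with sample 0 at
the event onset, so a −200..1000 ms window at 500 Hz is exactly 600
samples and window lengths add exactly
(`n(a,b) + n(b,c) = n(a,c)`). Windows must land on the sample grid;
misaligned endpoints raise rather than round silently.

## The synthetic cohort

The generator emulates a feedback-gambling EEG study: per subject, six
blocks of twenty feedback events (each independently *gain* with
probability 0.5 — reward contingency affects behavior, not the signal
path, so a symmetric Bernoulli is used), inter-onset spacing of at least
the 1.8 s epoch span plus 0.2–0.6 s, at 500 Hz on a 32-channel extended
10–20 montage.

**Evoked model.** Each trial adds Gaussian temporal components under a
spatial topography `exp(−d²/2σ²)` (angular distance `d` to FCz, σ =
0.7 rad). The default template has conditional components at 212 ms
(6.5 μV) and 370 ms (14 μV) in both conditions and a gain-only
(difference) component at 310 ms, 4.8 μV, SD 20 ms — latencies and the
difference amplitude match the reward-positivity morphology the bench is
calibrated to; conditional amplitudes are set so the gain waveform
dominates the loss waveform through 0–450 ms. Gaussians were chosen
because their peak location and any windowed mean have closed forms,
giving the tests analytic oracles. Per-trial amplitudes get multiplicative
Gaussian jitter (SD 20% of the peak).

**Mastoid-silent topography.** The topography is forced to zero at
TP9/TP10. The ground truth is thereby *defined in linked-mastoid reference
space*: re-referencing is exactly transparent to the injected components,
and recovered ERPs can be compared to the template directly. Without this,
every recovered amplitude would carry a constant ≈1.8% deflation (the
template leakage into the mastoids), which is a property of referencing,
not of any pipeline difference.

**Noise.** Per-channel independent Gaussian noise, spectrally shaped to
power ∝ 1/f (pink) above a 0.5 Hz corner and flat below, scaled to 10 μV
RMS. The low-frequency content exercises the 0.1 Hz high-pass; channel
independence is a simplification (real EEG noise is spatially correlated),
so whole-scalp similarity values on synthetic cohorts are not calibrated
to values observed on real data.

**Artifacts.** Blinks: biphasic 300 ms transients, 80 μV, weighted toward
frontal sites, ~2/min. Transients: 100 ms broadband bursts, 150 μV peak,
on a random single channel, ~0.5/min. Flat channels: a constant stretch
(default 6 s when enabled). Line noise: a common 60 Hz sinusoid (2 μV).
Every injection is logged with channel, onset and duration, so rejection
stages can be tested against a closed loop (e.g. a logged 150 μV transient
must trip the 100 μV min-max rule for exactly the epochs it touches).

**Determinism.** All randomness flows from explicit seeds; per-subject
seeds derive from the cohort master seed. Identical (config, seed) is
bit-identical, which the reproducibility tests check at file-byte level.

**What passing tests do not show.** The generator has no spatially
correlated noise, no head model (idealized unit-sphere geometry), no
ocular ground truth for ICA-style correction (out of scope), and no
behavioral structure. Recovery results therefore validate the pipeline
mechanics and statistics, not claims about real-data effect sizes.

## Preprocessing pipeline

Two passes, matching common ERP practice for automated bad-channel
handling:

1. **First pass** (throwaway): linked-mastoid re-reference → zero-phase
   band-pass (variant's filter) → optional 60 Hz notch → epochs
   −500..1500 ms → baseline −200..0 ms → trial flagging. A channel whose
   per-channel violation rate strictly exceeds 40% of trials is bad. The
   alternative `flat_detection` policy instead flags channels with a flat
   run (|Δ| < 10⁻⁸ μV between samples) strictly longer than 5 s.
2. **Second pass** (from the raw recording): re-reference → filter (+
   notch where the variant uses one) → interpolate bad channels → epochs
   −500..1300 ms → baseline −200..0 ms → trial rejection → per-condition
   averages and the gain − loss difference → trim to −200..1000 ms.

Rejection statistics are computed per channel over the full epoch after
baseline correction: gradient `max |x[i+1] − x[i]|·fs/1000` (μV/ms),
min-max `max − min`, absolute `max |x|`. All thresholds are strict
(`>`, "exceeds"); an epoch is rejected if any channel violates any enabled
rule. The order — baseline before flagging — matters and is fixed: a large
DC offset with small fluctuations passes an absolute rule only after
baseline correction (there is a test demonstrating the disagreement).
Subjects keep ERPs only with ≥ 15 accepted trials per condition (a
configurable default; the threshold is an assumption, not an established
constant).

## Filters

All filters are applied forward–backward (zero phase): peak latencies are
what the analysis is about, and zero-phase application preserves them
exactly in the noise-free limit (verified to the sample). The effective
magnitude is |H|²; `magnitude_response` reports single-pass dB and can
double them for the zero-phase case.

* **Butterworth band-pass**, design order 4 *per pass* (the band-pass
  transform doubles the pole count; the stated order is the design order,
  a choice documented here because tools describe it both ways).
* **Hamming-window FIR**, order `round(3.3/(df/fs))` with `df` the lowest
  pass-band edge — 16500 for 0.1–30 Hz at 500 Hz. Taps are forced odd
  (type I) so the pass-band is symmetric.
* **Kaiser-window FIR**, order `ceil((A − 7.95)/(2.285·2π·Δf/fs))`
  rounded up to even — 18128 at A = 60 dB, Δf = 0.1 Hz. The (60 dB,
  0.1 Hz) design point is an inference that reproduces the order the
  emulated tool reports for this band; β follows the standard attenuation
  formula.
* **IIR notch**, second order, Q = 35 (only the center frequency is ever
  specified by the emulated tools; Q is this package's default).

Note that `firwin` places band edges at half amplitude (−6 dB), while the
Butterworth edge sits at −3 dB: the families genuinely differ at the band
edge even before orders differ, which the filter-swap experiment surfaces
as pairwise correlations < 1 on broadband signals.

**Numerics.** IIR filtering uses second-order sections with odd-reflection
padding of 3× the effective order (capped at signal length − 1). FIR
zero-phase filtering is implemented as forward–backward FFT convolution
with odd-reflection edge padding of one kernel length — for linear-phase
taps this equals direct filtfilt to rounding, and it is the only practical
option at 16k–18k taps on minutes-long recordings. Signals shorter than
one kernel are rejected with the required minimum in the error.

## Channel repair

* **Spherical spline** (Perrin-type): basis
  `g(cosθ) = (1/4π) Σₙ (2n+1)/(nᵐ(n+1)ᵐ) Pₙ(cosθ)` truncated at 50 terms,
  stiffness m = 4 (truncation error < 10⁻⁶ at this stiffness), solved over
  good channels with a constant term and ridge 10⁻⁵ on the Gram matrix.
  Validated against analytic fields: constants are reproduced to 10⁻⁶ and
  a first-order spherical harmonic is interpolated within 2%.
* **Inverse-distance weighting**: weighted mean of good neighbors within
  0.6 rad, weight 1/angular distance. This is the mapped default for tools
  whose repair method is a weighted-neighbor scheme.

Both are linear operators in the data (tested), so interpolating averages
equals averaging interpolated trials.

## Features at FCz

Peak time: argmax of the difference waveform within 200–400 ms (tie →
earliest sample; the window equals the published max-peak window since no
separate peak-time window is specified anywhere). Mean peak: average over
±46 ms around the peak (47 samples at 500 Hz when interior; clipped at the
axis edges). Max peak: signed maximum in 200–400 ms. Base-to-peak: max
peak minus the trough immediately prior — implemented as the bottom of the
descent nearest the peak when walking back from it, falling back to the
global minimum of [0, peak] for monotone rises; the trough search starts
at stimulus onset. For the conditional (gain/loss) mean peaks the anchor
latency is the subject's own difference-ERP peak, so all scopes share one
latency per subject.

## Comparison battery

* **Cohen's d** (one sample): d = mean/SD (SD with n−1), CI
  d ± 1.96·√(1/n + d²/2n).
* **Rank-sum tests**: unpaired Wilcoxon rank-sum per metric per pipeline
  pair via the tie-corrected, continuity-corrected normal approximation;
  significance at α/m, m = C(k,2) pairs (6 for four pipelines, α = 0.01).
  The unpaired form is kept deliberately even though the design is paired,
  for fidelity to the emulated analysis. Against exact enumeration at
  n ≤ 8 the approximation stays within 0.05 in p.
* **Similarity**: per subject, Pearson r per channel, averaged over
  channels; zero-variance channels are excluded with a count. A one-sample
  Kolmogorov–Smirnov check (against a normal with the sample moments) is
  provided to precede Pearson use.
* **Cluster permutation test**: paired t per (channel, sample);
  supra-threshold samples (two-tailed at 0.05) clustered by temporal
  adjacency within channels plus montage adjacency (< 0.6 rad) across
  channels, positive and negative clusters separately; cluster mass =
  summed t. The null sign-flips whole subjects (the exchangeable unit when
  the same subjects pass through both pipelines — trial-level relabeling
  is *not* exchangeable across pipelines, which is why subject-level flips
  were chosen); p = (1 + #{perm max |mass| ≥ |observed|})/(n_perm + 1), so
  p > 0 always. Calibration: over 200 seeded null experiments the
  family-wise error rate lies inside the binomial 95% band around 0.05,
  and Monte-Carlo p agrees with full enumeration of the 2⁶ sign patterns
  at n = 6.
* **SME**: per subject × condition, resample accepted trials with
  replacement (same n), average, score (mean peak at FCz), 1000 times; SME
  = SD of the scores. On constant-waveform trials with iid amplitudes this
  reproduces σ/√n within 10%. A one-way fixed-effects ANOVA compares SME
  across pipelines (two groups reduce to the squared pooled t, tested).

## Variant registry

| variant | band-pass | notch | repair | rejection | bad channels |
|---|---|---|---|---|---|
| reference | Butterworth 4 | 60 Hz | spherical spline | gradient 10 μV/ms + min-max 100 μV | two-pass 40% |
| eeglab_like | Hamming FIR 16500 | — | spherical spline | absolute ±50 μV | two-pass 40% |
| brainstorm_like | Kaiser FIR 18128 | 60 Hz | inverse distance | peak-to-peak 100 μV | two-pass 40% |
| fieldtrip_like | Butterworth 4 | — | inverse distance | min-max 100 μV | two-pass 40% |

The notch appears only where the emulated tool's documented step list
includes one. `with_flat_policy()` derives the modified pipelines that use
flat-channel detection (optionally raising min-max to 200 μV); raising the
threshold never loses trials (tested monotonicity). Variant configs load
from YAML with unknown keys rejected.

## Problem sizes and degenerate inputs

The shipped study scale is 20 subjects × 120 trials, which keeps a full
cohort generation plus reference run under a minute on one CPU while
leaving the grand-average difference peak within a few milliseconds of the
injected 310 ms (estimator jitter at this scale is ≈2 ms SD; the noise-free
limit is exact to the sample). Comparison tests use smaller cohorts (6
subjects × 40 trials) and reduced channel × time maps for the permutation
calibration. Degenerate inputs fail loudly: empty epoch sets, windows off
the grid or off the axis, zero-variance samples in effect sizes and
normality checks, fewer than 4 good channels for splines, no neighbor in
range for IDW, fewer than 3 paired subjects for the cluster test.

## Known limitations

Idealized spherical geometry (no digitized positions); channel-independent
noise; no ICA/ocular correction path (deliberately excluded); the
BrainVision writer emits a single fixed dialect (float32 multiplexed,
μV); SME is computed for the mean-peak score only; cluster inference uses
one fixed cluster-forming threshold rather than TFCE.
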