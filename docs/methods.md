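# Methods

This note documents the models, conventions and numerical choices
behind `avfsound`, in the order of the processing chain.

## Signal model and scope

The unit of analysis is a single-channel vascular-sound recording taken
over an arteriovenous fistula, nominally 22 050 Hz for 60 s at one of
five positions along the outflow vein. Classification happens at the
**cardiac-cycle** level (10 cycles per recording); recording-level
labels can be formed afterwards by majority vote over cycles
(`doe_eval.aggregate_recording_votes`, ties to stenosis). Hardware,
capture and any clinical interpretation are out of scope.

## Pre-processing

**Normalization.** Global min–max to [0, 1]. A constant signal has no
information and is rejected rather than mapped arbitrarily.

**EMD filtering.** Classical empirical mode decomposition by sifting:
local extrema located by slope sign changes (plateaus collapsed),
upper/lower envelopes as cubic splines through the maxima/minima with a
two-extremum mirror extension at each boundary, and the sift iterated
until the Cauchy-type criterion Σ(h_prev − h)²/Σh_prev² < 0.2, capped
at 10 sifts per IMF and 10 IMFs. These are the standard defaults of
the classical algorithm; no ensemble variants (EEMD/CEEMDAN) are
provided. The filter output is s − c(1): the first IMF carries the
highest-frequency, sensor-noise-dominated content. Only c(1) is
actually sifted out (`max_imfs=1`), which is algebraically identical to
summing residual + IMFs 2..J at a tenth of the cost on 60 s signals.
The decomposition conserves the input exactly by construction
(residual = input − ΣIMFs); the test suite verifies reconstruction to
1e−8 relative error and the IMF zero-crossing/extrema balance.

**Cycle segmentation.** The amplitude envelope is the 4th-order
Butterworth low-pass (20 Hz cutoff, zero-phase) of the rectified,
mean-removed signal. The cycle period is the lag in [0.3 s, 2.0 s]
(30–200 bpm) maximizing the envelope autocorrelation; onsets are
envelope peaks at least 0.7 × period apart; cycles run onset-to-onset
and the first 10 complete ones are kept (a deterministic choice —
nothing distinguishes later cycles). Cycles whose span falls outside
the physiological band are discarded. Synthetic burst trains at 45–100
bpm are recovered with <5% period error.

**Augmentation.** Circular time-shift up to 10% of the cycle length
plus amplitude scaling by Uniform[0.9, 1.1] — label-preserving
transformations that mimic trigger jitter and contact-pressure
variation. Augmentation is meant for training folds only; applying it
before a split would leak near-duplicates across folds.

## Features

**Spectrogram images.** Left-aligned framing (frame f covers
[f·hop, f·hop + width)), Hann window of 1024 samples (~46 ms) and 50%
hop by default, one-sided magnitudes. For the CNN the magnitude matrix
is optionally mapped to dB (20 log₁₀(mag + 1e−10)), min–max scaled,
bilinearly resampled to a square (224 px for the full model, 32 px in
the desk-scale protocol) and replicated to three channels. A
constant-magnitude spectrogram maps to the all-zero image. Rectangular
non-overlapping framing satisfies Parseval to 1e−6, which pins the
normalization.

**Sample entropy.** SampEn(z, m, r) = −ln(A/B) with the following
conventions, each pinned by the worked examples and a brute-force
enumeration oracle in the tests:

* templates of length m and m+1 both start at indices 1..N−m (equal
  counts);
* unordered pairs i < j, self-pairs excluded;
* Chebyshev distance, **strict** inequality d < r·sd(z);
* sd is the population (divide-by-N) standard deviation;
* B counts m-length matches, A counts (m+1)-length matches, so the
  statistic is ≥ 0 (−ln of a conditional probability). Descriptions
  that swap the A/B labels would make it ≤ 0 and are inconsistent with
  the demonstration values 0 and ln 4 ≈ 1.386294, which this
  orientation reproduces.

A = 0 or B = 0 leaves −ln(A/B) undefined; that is reported as an error
(and as a flagged missing value in batch feature extraction), never
as 0. Because the tolerance scales with sd, the statistic is invariant
under affine transforms of z; for the integer demonstration series any
r with r·sd < 1 gives the same counts, and r = 0.2 is used.

**Band-limited variant.** z is obtained by an ideal FFT band-pass:
every bin with frequency outside the open interval (F_L, F_H) is
zeroed (DC is outside any band with F_L ≥ 0). The filter is idempotent
and exactly band-limits the signal, so the series may afterwards be
decimated by any integer factor that keeps the new Nyquist frequency
above F_H without aliasing. Batch feature extraction decimates to
~2205 Hz (the grid's largest F_H is 1000 Hz), cutting the O(N²)
entropy cost two orders of magnitude; the entropy of the decimated
series is a well-defined feature in its own right and is used
consistently on both classes. The default feature vector evaluates the
five top-ranked quadruples, (10, 700, 4, 0.2) first; a single-quadruple
vector is supported. The O(N²) pair count is a numba-compiled kernel
with early abort.

## Classifier

Both branches and the head are built on a small in-package numpy layer
engine (im2col convolution, batch normalization, max/global-average
pooling, dense layers, bottleneck residual blocks, Adam). Every
backward pass is verified against numerical differentiation in the
test suite. Float64 parameters and a single seeded generator make
training bitwise-reproducible on CPU.

* **Image branch**: stem 7×7/2 convolution → BN/ReLU → 3×3/2 max-pool →
  four bottleneck stages (1×1, 3×3, 1×1 with 4× expansion; identity or
  1×1-projection shortcut; strides 1, 2, 2, 2) → global average pool.
  The standard schedule (3, 4, 6, 3) at base width 64 gives 2048-d
  features and the familiar layer accounting
  50 = 1 + 1 + [3+3·2] + [3+3·3] + [3+3·5] + [3+3·2], counting the
  stem, the max-pool stage, and 3 convolutions per block. The `reduced`
  variant (1, 1, 1, 1) at quarter width (512-d features) exists for
  CPU-scale experiments; by the same accounting it has 14 layers.
* **Entropy branch**: n_layers dense ReLU layers of n_nodes units; the
  last hidden activation is the branch output.
* **Head**: the concatenated feature vector (e.g. 2048 + 4 = 2052 wide)
  passes through head_layers ReLU layers of head_nodes units and a
  single output unit; training minimizes binary cross-entropy on the
  logit, prediction applies a sigmoid and a 0.5 threshold with ties to
  stenosis.

**Training protocol.** Adam (lr 1e−4, β = 0.9/0.999), batch 32, 30
epochs by default, no pretrained weights (reproducibility first; the
desk-scale protocol uses 10 epochs, under which the reduced model
already fits the separable synthetic cohorts; this was settled on the
training-accuracy sanity check during development). Entropy features
are z-scored with training-fold statistics stored in the trained
model. Splits are stratified at the **patient** level: all cycles of a
patient land on the same side, so no recording leaks across the split.

## Designed experiments

**Entropy quadruple.** Full factorial over F_L ∈ {10, 50, 100},
F_H ∈ {200, …, 1000}, m ∈ {2, …, 10}, r ∈ {0.1, …, 0.5} — 1215 runs.
Since a single entropy value needs a decision rule to yield
sensitivity/specificity/accuracy, each quadruple is scored by a
threshold classifier whose cut point (and direction) maximizes accuracy
on a training fold and is applied to a held-out fold — the minimal
faithful reading. Results are ranked by test accuracy.

**Model factors.** The 2⁵⁻¹ half fraction is generated as a full
factorial on A–D with E = ABCD (defining relation I = ABCDE,
resolution V): 16 balanced runs in which every main effect aliases only
a four-factor interaction. Factor C selects which filtered cycle
dataset (traditional band-pass vs EMD) feeds a run. "Traditional
filtering" is realized as a 4th-order Butterworth band-pass over
20–1000 Hz, a conventional auscultation band. Effects come from OLS on
the coded columns (plus the B·D interaction by default):
effect = mean(y | +1) − mean(y | −1) and coef = effect/2 — an identity
the code enforces — with t/p from the replicate residual degrees of
freedom; a saturated model without replicates is an error, and an
exactly-fit response reports t/p as undefined rather than inventing
significance. The replicate count feeding the t-tests is configurable
(`n_repeats`).

**Metrics.** sensitivity = TP/(TP+FN), specificity = TN/(TN+FP),
accuracy, precision = TP/(TP+FP), F1 = 2PR/(P+R); any ratio with a zero
denominator is reported as missing, never as 0. Point estimates are
means over n independent stratified patient-level splits (default 10;
split seeds seed..seed+n−1) and SE = sample sd/√n.

## Synthetic data generator

Each recording is a sum over cardiac cycles (period 60/HR with ±2%
jitter) of:

* a **murmur**: fixed 25/40/60/75 Hz tones with per-recording random
  phases, gated by a continuous envelope — diastolic floor 0.4 plus a
  Gaussian systolic burst (center 0.15·period, width 0.08·period).
  A continuous hum with systolic accentuation is the classical
  auscultation picture of a patent fistula, and a nonzero diastolic
  floor is also what keeps sample entropy responsive (an all-or-nothing
  envelope would let near-silent samples dominate the template
  matches);
* for stenotic recordings, a **bruit**: band-limited Gaussian noise in
  (100, 600) Hz, re-randomized every cycle, RMS = 0.9 · severity ·
  murmur RMS, gated by the same envelope. Irregular high-frequency
  turbulence is exactly what the entropy feature and the spectrogram
  band energy are designed to detect;
* white background noise at `snr_db` (default 15 dB) **relative to the
  murmur power only** — the noise floor models the recording chain, so
  it must not scale with the bruit, or the label would leak into
  out-of-band noise levels;
* cohorts: the stenosis label is drawn per patient (probability
  `prevalence`, default 0.48 matching a roughly balanced clinical
  cohort), and a stenotic patient's severity (uniform within ±0.1 of
  the configured severity) is shared across that patient's positions,
  which is what makes patient-level splits meaningful.

Severity 0 makes a stenosis-labeled recording statistically identical
to a normal one, giving a null configuration for calibration tests.
The generator reproduces none of the real data's hemodynamics,
inter-patient spectral variability, probe-contact artifacts or
position-dependent intensity; passing tests on it demonstrates that
the pipeline detects the statistical signature it encodes
(severity-scaled band-limited irregularity), not clinical performance.
Clinical-grade numbers require real recordings supplied through the
manifest interface.

## Problem sizes and tolerances

The test suite and examples run CPU-only at desk scale: cohorts of
20 patients × 2 positions × 10 s recordings, 32 px images, the reduced
ResNet variant, 10 epochs and 4 evaluation repeats — sizes chosen so
the full suite completes in a few minutes while exercising every code
path; the full-scale configuration (60 s, 224 px, full ResNet50) is
the default in the API. Key tolerances: EMD reconstruction 1e−8
(relative), entropy vs brute force 1e−12, effect recovery on noiseless
responses 1e−12, STFT Parseval 1e−6, band-pass idempotence 1e−9,
cycle-period recovery 5%. Degenerate inputs fail loudly by design:
zero-range normalization, zero-variance entropy input, matchless
entropy (A or B = 0), empty confusion matrices, single-class training
sets and sub-minimum image sizes all raise errors rather than return
sentinel values.

## Known limitations

* EMD sifting on heavily noise-dominated signals is sensitive to the
  extrema/boundary conventions; different EMD implementations will not
  produce identical IMFs (the reconstruction identity, however, always
  holds).
* The envelope-autocorrelation segmenter assumes quasi-periodic
  amplitude modulation; strongly arrhythmic recordings would need an
  ECG-gated approach, which is out of scope.
* The entropy-threshold classifier inside the quadruple search is
  intentionally minimal; it measures the information in one entropy
  value, not the ceiling of the full model.
* The numpy engine favors exactness and reproducibility over speed;
  training the full 50-layer model on 224 px images is possible but
  slow on one CPU, which is what the reduced variant is for.
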