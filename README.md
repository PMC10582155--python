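# avfsound

Automatic detection of **arteriovenous-fistula (AVF) stenosis** from
vascular-sound recordings.

Hemodialysis patients depend on a functioning AVF — a surgical
artery–vein connection — for vascular access, and stenosis (a >50%
narrowing of the lumen) is its most common failure mode. Gold-standard
diagnostics (angiography, duplex ultrasound) need hospital equipment;
but a narrowed vessel also *sounds* different: turbulent flow produces a
harsh, high-pitched bruit. `avfsound` implements a complete
phonoangiography pipeline that classifies cheap electronic-stethoscope
recordings (22 050 Hz, 60 s, five auscultation positions along the
outflow vein) as **stenotic (S)** or **normal (N)**. It is aimed at
researchers in biomedical signal processing who want a tested, fully
reproducible CPU-only reference implementation.

## Method

1. **Pre-processing** (`preprocess`): min–max normalization
   s⁽ᴺ⁾ᵢ = (s⁽ᴼ⁾ᵢ − a)/(b − a) to [0, 1]; empirical mode decomposition
   (classical sifting, cubic-spline envelopes) and removal of the first,
   noise-dominated intrinsic mode function, s⁽ᴱᴹᴰ⁾ = s⁽ᴺ⁾ − c(1);
   segmentation into 10 cardiac cycles via the autocorrelation of the
   20 Hz amplitude envelope; optional label-preserving augmentation.
2. **Features** (`features`):
   * **STFT spectrogram images** — windowed one-sided magnitude spectra
     (Hann, 1024 samples, 50% hop by default), rendered as square
     3-channel images in [0, 1] for the CNN branch;
   * **band-limited sample entropy** — SampEn(z, m, r) = −ln(A/B), with
     z the cycle restricted to the band (F_L, F_H), B the number of
     m-point template pairs within Chebyshev distance r·sd(z), and A the
     same for (m+1)-point templates. The default feature vector uses the
     five top-ranked quadruples headed by (F_L, F_H, m, r) =
     (10, 700, 4, 0.2).
3. **Classifier** (`classifier`): a concatenated model — ResNet50
   (bottleneck residual stages 3-4-6-3; layer accounting
   50 = 1 + 1 + 9 + 12 + 18 + 9) on the images, a small dense ANN on the
   entropy vector, both feature vectors concatenated into a sigmoid
   head. Implemented on an in-package numpy layer engine with
   hand-written backpropagation (gradient-checked), so seeded training
   is bitwise-reproducible on CPU. A `reduced` variant (one block per
   stage, quarter width) supports desk-scale experiments.
4. **Designed experiments** (`doe_eval`): a 3×9×9×5 = 1215-run full
   factorial tunes the entropy quadruple; a 2⁵⁻¹ resolution-V fractional
   factorial (I = ABCDE, 16 runs) screens the five model factors
   A (ANN layers), B (ANN nodes), C (filtering: traditional band-pass vs
   EMD), D (head layers), E (head nodes). Effects are estimated on coded
   ±1 columns (coef = effect/2) with t/p from the replicate-based
   regression. Performance is reported as sensitivity, specificity,
   accuracy, precision and F1, each with a standard error over repeated
   stratified patient-level splits.
5. **Synthetic data** (`synthetic`): labeled cohorts with the structure
   the method assumes — a continuous low-frequency murmur with systolic
   accentuation, plus, for stenotic patients, a severity-scaled
   band-limited (100–600 Hz) turbulent bruit randomized cycle-to-cycle —
   so the entire pipeline is testable without any clinical download.

## Worked example

```bash
python examples/01_sample_entropy.py
```

```
SampEn(alternating series) = 0.000000
SampEn(irregular series)   = 1.386294
-> 0 means perfectly repeating; ln 4 ~ 1.386 means 3 of 4 pattern
   continuations are unpredictable.
```

Two series with identical mean and variance: the perfectly alternating
1,2,1,2,… has every m-template continuation determined (A = B, entropy
0), while in 1,1,2,1,2,2,2,1,1,2 only one of the four matching 2-point
template pairs continues identically, giving −ln(1/4) = ln 4.

End to end on a synthetic cohort (`python examples/05_train_and_evaluate.py`):

```
cohort: 24 recordings, {'normal': 14, 'stenosis': 10}
cycle dataset: 240 cycles, images (32, 32, 3), entropy vectors of length 5

metrics over 3 patient-level splits (cycle-level scoring, stenosis = positive):
   sensitivity: 1.000 (SE 0.000)
   specificity: 1.000 (SE 0.000)
      accuracy: 1.000 (SE 0.000)
     precision: 1.000 (SE 0.000)
            f1: 1.000 (SE 0.000)
```

The synthetic cohort at severity 0.8 and 15 dB SNR is deliberately easy;
see `docs/methods.md` for what that does and does not demonstrate.

The other examples cover the spectrogram (`02`), the pre-processing
chain (`03`), cohort simulation (`04`) and both designed experiments
(`06`). A thin CLI mirrors the main workflows:
`avfsound simulate|train|evaluate|doe`.

## Data formats

Recordings are mono WAV (or plain-text amplitude files); datasets are
described by a manifest CSV with columns
`patient_id,position,phase,label,path`. Real clinical recordings in
those formats can be analysed through the identical interfaces — the
synthetic generator is a statistical stand-in, not a requirement.
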