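"""Pre-processing a vascular-sound recording.

Generates one synthetic stenotic recording, then walks the four
pre-processing steps: normalization, EMD filtering (drop the first
intrinsic mode function), cardiac-cycle segmentation, and augmentation.
"""
import numpy as np

import avfsound as av

cfg = av.SimConfig(duration_s=15.0, severity=0.8, heart_rate_bpm=75, seed=1)
rec = av.generate_recording(cfg, "stenosis")
print(f"recording: {rec.n_samples} samples at {rec.fs:.0f} Hz "
      f"({rec.duration_s:.0f} s), label={rec.label}")

x = av.normalize(rec.samples)
print(f"normalized range: [{x.min():.1f}, {x.max():.1f}]")

decomp = av.emd(x, max_imfs=4)
print(f"EMD: {decomp.n_imfs} IMFs extracted "
      f"(sifts per IMF: {decomp.n_sifts}); reconstruction error "
      f"{np.max(np.abs(decomp.reconstruct() - x)):.2e}")

filtered = av.emd_filter(x)
hf = lambda s: np.abs(np.fft.rfft(s - s.mean()))[
    np.fft.rfftfreq(len(s), 1 / rec.fs) > 2000].sum()
print(f"energy above 2 kHz after removing IMF-1: "
      f"{hf(filtered) / hf(x):.2%} of before")

filtered_rec = av.Recording(samples=filtered, fs=rec.fs, label=rec.label)
cycles = av.segment_cycles(filtered_rec, n_cycles=10)
periods = [c.cycle_period_s for c in cycles]
print(f"segmented {len(cycles)} cardiac cycles, period "
      f"{np.mean(periods):.3f} +/- {np.std(periods):.3f} s "
      f"(~{60 / np.mean(periods):.0f} bpm)")

augmented = av.augment(cycles, factor=3, seed=0)
print(f"augmentation x3: {len(cycles)} -> {len(augmented)} cycles "
      f"(time-shift + amplitude jitter, labels preserved)")
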