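"""STFT of a piecewise three-tone signal.

The signal switches from 150 to 100 to 50 Hz every half second; the
spectrogram localizes each tone in time, which a single Fourier
transform of the whole signal cannot do.
"""
import numpy as np

import avfsound as av

fs = 22050.0
t = np.arange(1, int(1.5 * fs) + 1) / fs
x = np.where(t <= 0.5, np.cos(2 * np.pi * 150 * t),
             np.where(t <= 1.0, np.cos(2 * np.pi * 100 * t),
                      np.cos(2 * np.pi * 50 * t)))

spec = av.stft(x, fs, window="hann", width_samples=1024, hop_samples=512)
print(f"spectrogram: {spec.magnitudes.shape[0]} frequency bins x "
      f"{spec.n_frames} frames, bin width {fs / 1024:.2f} Hz")

starts = spec.times_s - 1024 / fs / 2
ends = starts + 1024 / fs
for lo, hi, true_hz in [(0.0, 0.5, 150), (0.5, 1.0, 100), (1.0, 1.5, 50)]:
    sel = (starts >= lo) & (ends <= hi)
    peak = spec.freqs_hz[np.argmax(spec.magnitudes[:, sel].mean(axis=1))]
    print(f"  t in ({lo}, {hi}] s: dominant frequency {peak:6.1f} Hz "
          f"(true tone {true_hz} Hz)")

img = av.spectrogram_to_image(spec, size_px=224)
print(f"\nas CNN input: image tensor {img.shape}, values in "
      f"[{img.min():.1f}, {img.max():.1f}]")
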