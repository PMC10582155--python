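"""Sample entropy as a regularity meter.

Computes SampEn(m=2, r=0.2) for two 10-element demonstration series
with identical mean and variance, then shows the band-limited variant
separating a pure tone from broadband noise.
"""
import numpy as np

import avfsound as av

series_a = np.array([1, 2, 1, 2, 1, 2, 1, 2, 1, 2], float)
series_b = np.array([1, 1, 2, 1, 2, 2, 2, 1, 1, 2], float)
print(f"SampEn(alternating series) = {av.sample_entropy(series_a, m=2, r=0.2):.6f}")
print(f"SampEn(irregular series)   = {av.sample_entropy(series_b, m=2, r=0.2):.6f}")
print("-> 0 means perfectly repeating; ln 4 ~ 1.386 means 3 of 4 pattern")
print("   continuations are unpredictable.")

fs = 22050.0
t = np.arange(2048) / fs
tone = np.sin(2 * np.pi * 300 * t)
noise = np.random.default_rng(0).standard_normal(2048)
p = av.SampEnParams(F_L=10, F_H=700, m=4, r=0.2)  # the top-ranked quadruple
print(f"\nband-limited SampEn(10-700 Hz, m=4, r=0.2):")
print(f"  300 Hz tone     : {av.banded_sample_entropy(tone, fs, p):.4f}")
print(f"  broadband noise : {av.banded_sample_entropy(noise, fs, p):.4f}")
print("-> turbulent, noise-like bruits score high; laminar-flow murmurs low.")
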