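"""Simulating a labeled patient cohort.

Generates a small cohort of synthetic recordings (stenosis label drawn
per patient, severity shared across that patient's positions) and
shows that the top-ranked entropy quadruple separates the classes.
"""
import numpy as np

import avfsound as av
from avfsound import pipeline

cfg = av.SimConfig(duration_s=10.0, n_patients=8, positions_per_patient=2,
                   severity=0.8, snr_db=15.0, prevalence=0.5, seed=0)
ds = av.generate_dataset(cfg)
print(f"{len(ds.recordings)} recordings from {cfg.n_patients} patients; "
      f"class counts: {ds.class_counts}")

p = av.SampEnParams(10, 700, 4, 0.2)
by_class = {"stenosis": [], "normal": []}
for rec in ds.recordings:
    for cyc in pipeline.preprocess_recording(rec, filtering="EMD"):
        by_class[rec.label].append(
            av.banded_sample_entropy(cyc.samples, cyc.fs, p, analysis_fs=2205.0))

for label, vals in by_class.items():
    print(f"  {label:>8s}: banded SampEn {np.mean(vals):.3f} +/- {np.std(vals):.3f} "
          f"(n = {len(vals)} cycles)")
print("-> stenotic cycles carry the turbulent high-frequency bruit and are")
print("   markedly more irregular in the 10-700 Hz band.")
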