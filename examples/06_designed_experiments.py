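"""The two designed experiments that tune the method.

1. Full factorial over the entropy quadruple (F_L, F_H, m, r) — the
   study grid enumerates 3 x 9 x 9 x 5 = 1215 combinations; here a
   two-band slice shows bands covering the bruit range winning.
2. The 2^(5-1) fractional factorial over model factors A-E, with
   effect estimation demonstrated on a planted noiseless response.
"""
import numpy as np

import avfsound as av
from avfsound import pipeline
from avfsound.doe_eval import fractional_factorial_2k1, full_factorial, run_sampen_doe

print(f"entropy grid size: {full_factorial(av.SAMPEN_GRID).n_runs} runs")

cycles = []
for i, (label, seed) in enumerate([("stenosis", 11), ("normal", 31),
                                   ("stenosis", 12), ("normal", 32)]):
    rec = av.generate_recording(
        av.SimConfig(duration_s=10.0, severity=0.8, seed=seed), label)
    rec.label = label
    cycles += pipeline.preprocess_recording(rec, filtering="EMD")
table = run_sampen_doe(cycles, grid={"F_L": [10], "F_H": [90, 700], "m": [4], "r": [0.2]})
print("\nentropy-threshold classification, 40 cycles (band slice):")
print(table[["rank", "F_L", "F_H", "m", "r", "accuracy"]].to_string(index=False))
print("-> the band covering the 100-600 Hz bruit outranks the one below it.")

design = fractional_factorial_2k1(5)
print(f"\n2^(5-1) design: {design.n_runs} runs, {design.defining_relation}, "
      f"every column balanced")
runs = design.runs
planted = (0.85 + 0.09 * runs["C"] - 0.0275 * runs["A"]
           + 0.015 * runs["B"] * runs["D"]).to_numpy(float)
effects = av.estimate_effects(design, planted)
print("effects recovered from a planted noiseless accuracy response:")
print(effects.table[["term", "effect", "coef"]].round(4).to_string(index=False))
print("-> coef = effect/2 exactly; C (the filtering choice) dominates.")
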