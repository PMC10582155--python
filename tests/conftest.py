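import numpy as np
import pytest

import avfsound as av
from avfsound import pipeline


@pytest.fixture(scope="session")
def desk_sim_config() -> av.SimConfig:
    """The desk-scale study conditions: 20 patients x 2 positions,
    10 s recordings, severity 0.8, 15 dB SNR, seed 0."""
    return av.SimConfig(
        duration_s=10.0, n_patients=20, positions_per_patient=2,
        severity=0.8, snr_db=15.0, prevalence=0.48, seed=0,
    )


@pytest.fixture(scope="session")
def desk_dataset(desk_sim_config) -> pipeline.CycleDataset:
    """Cycle-level model inputs for the desk-scale synthetic cohort
    (EMD filtering, 32 px spectrogram images, top-5 entropy vector).
    Session-scoped: building it costs ~20 s."""
    syn = av.generate_dataset(desk_sim_config)
    return pipeline.build_cycle_dataset(
        syn.recordings, filtering="EMD", image_size_px=32
    )


@pytest.fixture(scope="session")
def burst_train():
    """Factory for synthetic cardiac-like burst trains with a known
    period — the segmentation oracle."""

    def make(period_s: float, duration_s: float = 30.0, fs: float = 22050.0):
        n = int(duration_s * fs)
        t = np.arange(n) / fs
        sig = np.zeros(n)
        onset = 0.0
        while onset < duration_s:
            sig += np.exp(-0.5 * ((t - onset - 0.15) / 0.05) ** 2) * np.sin(
                2 * np.pi * 40 * (t - onset)
            )
            onset += period_s
        return av.Recording(samples=sig, fs=fs, label="normal")

    return make


def sampen_bruteforce(z, m, r):
    """Independent sample-entropy oracle: explicit enumeration of all
    unordered template pairs at both lengths, Chebyshev distance,
    strict inequality, N-m templates each."""
    z = [float(v) for v in z]
    n_tot = len(z)
    mean = sum(z) / n_tot
    sd = (sum((v - mean) ** 2 for v in z) / n_tot) ** 0.5
    tol = r * sd
    n = n_tot - m
    B = 0
    A = 0
    for i in range(n):
        for j in range(i + 1, n):
            d_m = max(abs(z[i + t] - z[j + t]) for t in range(m))
            if d_m < tol:
                B += 1
                d_m1 = max(d_m, abs(z[i + m] - z[j + m]))
                if d_m1 < tol:
                    A += 1
    if A == 0 or B == 0:
        return None
    import math

    return -math.log(A / B)
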