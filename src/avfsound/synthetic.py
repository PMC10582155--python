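"""Synthetic vascular-sound generator.

Emulates the statistical structure the detection method relies on,
without any physical hemodynamics: each cardiac cycle is a continuous
low-frequency (20-80 Hz) murmur with a systolic accentuation burst —
the machine-like hum every fistula produces — and stenotic recordings
add a band-limited
(default 100-600 Hz) turbulent bruit whose amplitude grows with the
stenosis severity and whose realization changes from cycle to cycle
(phase-randomized), which is exactly the irregularity that band-limited
sample entropy and spectrogram band energy are meant to pick up.
White background noise is added at a configurable SNR.

Datasets mirror the clinical protocol: several auscultation positions
per patient, one 22 050 Hz recording per position, with the stenosis
label and a severity draw shared by all of a patient's positions so
that patient-level train/test splits are meaningful.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .signal_io import MANIFEST_COLUMNS, Recording, write_manifest, write_wav


@dataclass
class SimConfig:
    fs: float = 22050.0
    duration_s: float = 60.0
    heart_rate_bpm: float = 75.0
    severity: float = 0.8
    bruit_band_hz: tuple[float, float] = (100.0, 600.0)
    snr_db: float = 15.0
    n_patients: int = 40
    positions_per_patient: int = 5
    prevalence: float = 0.48
    diastolic_floor: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.severity <= 1.0):
            raise ValueError("severity must be in [0, 1]")
        if not (30.0 <= self.heart_rate_bpm <= 200.0):
            raise ValueError("heart rate must be in [30, 200] bpm")
        if not (0.0 <= self.prevalence <= 1.0):
            raise ValueError("prevalence must be in [0, 1]")


# fixed low-frequency murmur tones (Hz) and their relative amplitudes
_BASE_TONES = ((25.0, 1.0), (40.0, 0.8), (60.0, 0.6), (75.0, 0.4))
_BRUIT_GAIN = 0.9  # stenotic bruit RMS at severity 1, relative to murmur RMS


def _band_noise(n: int, fs: float, band: tuple[float, float],
                rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS Gaussian noise restricted to a frequency band."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    spec[(f <= band[0]) | (f >= band[1])] = 0.0
    x = np.fft.irfft(spec, n)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def generate_recording(cfg: SimConfig, label: str,
                       rng: np.random.Generator | None = None) -> Recording:
    """One synthetic recording with the given label.

    Deterministic under ``cfg.seed`` when no generator is supplied. A
    ``severity`` of 0 makes a stenosis-labeled recording statistically
    identical to a normal one (the label then carries no signal).
    """
    if label not in ("stenosis", "normal"):
        raise ValueError("label must be 'stenosis' or 'normal'")
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    n = int(round(cfg.fs * cfg.duration_s))
    murmur = np.zeros(n)
    bruit_total = np.zeros(n)

    period = 60.0 / cfg.heart_rate_bpm
    phases = rng.uniform(0, 2 * np.pi, size=len(_BASE_TONES))
    severity = cfg.severity if label == "stenosis" else 0.0

    t0 = 0.05 * period
    while t0 < cfg.duration_s:
        this_period = period * (1.0 + rng.uniform(-0.02, 0.02))
        start = int(round(t0 * cfg.fs))
        seg_len = min(int(round(this_period * cfg.fs)), n - start)
        if seg_len <= 1:
            break
        t = np.arange(seg_len) / cfg.fs
        # continuous machine-like murmur with systolic accentuation:
        # Gaussian burst early in the cycle over a diastolic floor
        fl = cfg.diastolic_floor
        env = fl + (1.0 - fl) * np.exp(
            -0.5 * ((t - 0.15 * this_period) / (0.08 * this_period)) ** 2
        )
        burst = np.zeros(seg_len)
        for (f_hz, amp), ph in zip(_BASE_TONES, phases):
            burst += amp * np.sin(2 * np.pi * f_hz * t + ph)
        burst *= env
        murmur[start : start + seg_len] += burst
        if severity > 0:
            base_rms = np.sqrt(np.mean(burst**2)) or 1.0
            bruit = _band_noise(seg_len, cfg.fs, cfg.bruit_band_hz, rng)
            bruit_total[start : start + seg_len] += (
                severity * _BRUIT_GAIN * base_rms * bruit * env
            )
        t0 += this_period

    # the noise floor models the recording chain, so it scales with the
    # benign murmur, never with the bruit — the label must not leak into
    # out-of-band noise levels
    murmur_power = np.mean(murmur**2)
    noise_power = murmur_power / (10.0 ** (cfg.snr_db / 10.0))
    signal = murmur + bruit_total + rng.standard_normal(n) * np.sqrt(noise_power)
    return Recording(samples=signal, fs=cfg.fs, label=label)


@dataclass
class SyntheticDataset:
    recordings: list[Recording]
    manifest: pd.DataFrame
    severities: dict[str, float] = field(default_factory=dict)

    @property
    def class_counts(self) -> dict[str, int]:
        return self.manifest["label"].value_counts().to_dict()


def generate_dataset(cfg: SimConfig, out_dir: str | Path | None = None) -> SyntheticDataset:
    """A labeled cohort of n_patients x positions_per_patient recordings.

    Each patient is stenotic with probability ``prevalence``; stenotic
    patients get one severity draw (uniform within +/-0.1 of
    ``cfg.severity``, clipped to [0.05, 1]) shared across positions.
    When ``out_dir`` is given, WAV files and a ``manifest.csv`` are
    written there; recordings are always returned in memory.
    """
    rng = np.random.default_rng(cfg.seed)
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    recordings: list[Recording] = []
    rows: list[dict] = []
    severities: dict[str, float] = {}
    for p in range(cfg.n_patients):
        pid = f"P{p:03d}"
        stenotic = bool(rng.uniform() < cfg.prevalence)
        sev = float(np.clip(rng.uniform(cfg.severity - 0.1, cfg.severity + 0.1),
                            0.05, 1.0)) if stenotic else 0.0
        severities[pid] = sev
        label = "stenosis" if stenotic else "normal"
        for pos in range(1, cfg.positions_per_patient + 1):
            rec_cfg = SimConfig(**{**cfg.__dict__, "severity": sev})
            rec = generate_recording(rec_cfg, label, rng)
            rec.patient_id = pid
            rec.position = pos if pos <= 5 else None
            rec.phase = "pre_pta"
            recordings.append(rec)
            fname = f"{pid}_{pos}_pre_{'s' if stenotic else 'n'}.wav"
            rows.append({
                "patient_id": pid, "position": pos, "phase": "pre_pta",
                "label": label, "path": fname,
            })
            if out is not None:
                write_wav(rec, out / fname)
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    if out is not None:
        write_manifest(manifest, out / "manifest.csv")
    return SyntheticDataset(recordings=recordings, manifest=manifest, severities=severities)
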