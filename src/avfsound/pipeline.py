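"""End-to-end glue: recordings -> preprocessed cycles -> model inputs.

The canonical order of operations is normalize -> filter (EMD or
traditional band-pass, screening factor C) -> segment into cardiac
cycles -> per-cycle features (spectrogram image for the ResNet branch,
band-limited sample-entropy vector for the ANN branch).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt

from .features import SampEnParams, TOP5_PARAMS, extract_features, spectrogram_to_image, stft
from .preprocess import CardiacCycle, emd_filter, normalize, segment_cycles
from .signal_io import Recording

logger = logging.getLogger(__name__)

# the conventional auscultation band used for "traditional filtering"
TF_BAND_HZ = (20.0, 1000.0)


def apply_filtering(samples: np.ndarray, fs: float, method: str) -> np.ndarray:
    """Factor C: 'EMD' removes the first intrinsic mode function;
    'TF' is a 4th-order Butterworth band-pass over 20-1000 Hz."""
    if method == "EMD":
        return emd_filter(samples)
    if method == "TF":
        b, a = butter(4, [TF_BAND_HZ[0] / (fs / 2), TF_BAND_HZ[1] / (fs / 2)], btype="band")
        return filtfilt(b, a, samples)
    raise ValueError(f"unknown filtering method {method!r}")


def preprocess_recording(rec: Recording, filtering: str = "EMD",
                         n_cycles: int = 10) -> list[CardiacCycle]:
    """normalize -> filter -> segment one recording into cycles."""
    filtered = apply_filtering(normalize(rec.samples), rec.fs, filtering)
    filtered_rec = Recording(samples=filtered, fs=rec.fs, patient_id=rec.patient_id,
                             position=rec.position, label=rec.label, phase=rec.phase,
                             source=rec.source)
    return segment_cycles(filtered_rec, n_cycles=n_cycles)


@dataclass
class CycleDataset:
    """Aligned model inputs, one row per cardiac cycle."""

    images: np.ndarray        # (n, size_px, size_px, 3)
    features: np.ndarray      # (n, n_quadruples)
    labels: np.ndarray        # (n,) 1 = stenosis
    patient_ids: np.ndarray   # (n,) grouping key for leakage-safe splits

    def __len__(self) -> int:
        return len(self.labels)


def build_cycle_dataset(
    recordings: list[Recording],
    filtering: str = "EMD",
    n_cycles: int = 10,
    image_size_px: int = 224,
    params_list: tuple[SampEnParams, ...] = TOP5_PARAMS,
    stft_width: int = 1024,
    stft_hop: int = 512,
    analysis_fs: float | None = 2205.0,
) -> CycleDataset:
    """Preprocess every recording and compute both feature families.

    Recordings whose label is unknown or where too few cycles are found
    are skipped with a warning; entropy values recorded as missing are
    imputed with the per-column mean so the ANN branch sees a complete
    matrix.
    """
    images, feats, labels, pids = [], [], [], []
    for rec in recordings:
        if rec.label not in ("stenosis", "normal"):
            logger.warning("skipping recording %s with unknown label", rec.source)
            continue
        try:
            cycles = preprocess_recording(rec, filtering=filtering, n_cycles=n_cycles)
        except ValueError as exc:
            logger.warning("skipping recording %s: %s", rec.source, exc)
            continue
        for cyc in cycles:
            spec = stft(cyc.samples, cyc.fs, width_samples=min(stft_width, len(cyc.samples)),
                        hop_samples=stft_hop)
            images.append(spectrogram_to_image(spec, size_px=image_size_px))
            fv = extract_features(cyc, params_list, analysis_fs=analysis_fs)
            feats.append(fv.values)
            labels.append(1 if cyc.label == "stenosis" else 0)
            pids.append(rec.patient_id)
    if not labels:
        raise ValueError("no usable cycles were produced from the recordings")
    F = np.array(feats)
    # mean-impute flagged (NaN) entropy entries, per column
    for col in range(F.shape[1]):
        bad = np.isnan(F[:, col])
        if bad.any():
            fill = np.nanmean(F[:, col]) if not bad.all() else 0.0
            F[bad, col] = fill
    return CycleDataset(images=np.array(images), features=F,
                        labels=np.array(labels), patient_ids=np.array(pids))


def stratified_patient_split(
    ds: CycleDataset, test_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Cycle-index masks for a patient-level stratified train/test split.

    Patients (not cycles) are shuffled and split within each class
    stratum, so every cycle of a patient lands on the same side — no
    leakage of a recording's cycles across the split.
    """
    patients: dict[str, int] = {}
    for pid, lab in zip(ds.patient_ids, ds.labels):
        patients[pid] = int(lab)
    test_patients: list[str] = []
    for cls in (0, 1):
        group = sorted(p for p, l in patients.items() if l == cls)
        if not group:
            raise ValueError(f"cannot stratify: no patients of class {cls}")
        rng.shuffle(group)
        n_test = max(1, int(round(test_fraction * len(group))))
        if n_test >= len(group):
            raise ValueError("dataset too small to stratify at the patient level")
        test_patients += group[:n_test]
    test_mask = np.isin(ds.patient_ids, test_patients)
    return ~test_mask, test_mask
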