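"""Reading and writing vascular-sound recordings.

Recordings are single-channel audio of the bruit heard over an
arteriovenous fistula (AVF), conventionally captured at 22 050 Hz for
60 s at one of five auscultation positions along the outflow vein.
Files come either as RIFF WAV or as plain-text amplitude listings (one
value per line); a dataset is described by a manifest CSV with columns
``patient_id,position,phase,label,path``.
"""
from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

DEFAULT_FS = 22050.0

LABELS = ("stenosis", "normal", "unknown")
PHASES = ("pre_pta", "post_pta", "unknown")

MANIFEST_COLUMNS = ["patient_id", "position", "phase", "label", "path"]

_LABEL_ALIASES = {
    "stenosis": "stenosis", "s": "stenosis", "abnormal": "stenosis",
    "normal": "normal", "n": "normal", "h": "normal",
}
_PHASE_ALIASES = {
    "pre_pta": "pre_pta", "pre": "pre_pta", "before": "pre_pta",
    "post_pta": "post_pta", "post": "post_pta", "after": "post_pta",
}


@dataclass
class Recording:
    """A single-channel vascular-sound recording plus its metadata."""

    samples: np.ndarray
    fs: float
    patient_id: str = ""
    position: int | None = None
    label: str = "unknown"
    phase: str = "unknown"
    source: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.position is not None and self.position not in range(1, 6):
            raise ValueError(f"position must be in 1..5, got {self.position}")
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")
        if self.phase not in PHASES:
            raise ValueError(f"phase must be one of {PHASES}, got {self.phase!r}")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs

    @property
    def n_samples(self) -> int:
        return len(self.samples)


def _parse_filename_metadata(path: Path) -> dict:
    """Parse ``<patient>_<position>_<phase>_<label>`` from a file stem.

    Unknown or missing fields are tolerated and default to unknown.
    """
    meta = {"patient_id": "", "position": None, "phase": "unknown", "label": "unknown"}
    tokens = path.stem.split("_")
    if not tokens:
        return meta
    meta["patient_id"] = tokens[0]
    for tok in tokens[1:]:
        low = tok.lower()
        if re.fullmatch(r"[1-5]", low) and meta["position"] is None:
            meta["position"] = int(low)
        elif low in _PHASE_ALIASES and meta["phase"] == "unknown":
            meta["phase"] = _PHASE_ALIASES[low]
        elif low in _LABEL_ALIASES and meta["label"] == "unknown":
            meta["label"] = _LABEL_ALIASES[low]
    return meta


def read_wav(path: str | Path) -> Recording:
    """Read a mono WAV file into a :class:`Recording`.

    Integer PCM samples are rescaled to [-1, 1); the sampling rate is
    taken from the header and metadata from the filename pattern
    ``<patient>_<position>_<phase>_<label>.wav`` where present.
    """
    path = Path(path)
    try:
        fs, data = wavfile.read(path)
    except ValueError as exc:
        raise ValueError(f"unreadable WAV header in {path}: {exc}") from exc
    if data.ndim != 1:
        raise ValueError(f"expected 1 channel, got {data.shape[1]}")
    if np.issubdtype(data.dtype, np.integer):
        info = np.iinfo(data.dtype)
        # symmetric scaling for signed PCM; unsigned 8-bit is offset binary
        if info.min < 0:
            samples = data.astype(np.float64) / float(-info.min)
        else:
            samples = (data.astype(np.float64) - (info.max + 1) / 2) / ((info.max + 1) / 2)
    else:
        samples = data.astype(np.float64)
    meta = _parse_filename_metadata(path)
    return Recording(samples=samples, fs=float(fs), source=str(path), **meta)


def read_text_signal(path: str | Path, fs: float = DEFAULT_FS) -> Recording:
    """Read a plain-text amplitude file (one value per line, or
    whitespace-separated) at a caller-supplied sampling rate."""
    path = Path(path)
    values: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            for tok in line.split():
                try:
                    values.append(float(tok))
                except ValueError:
                    raise ValueError(
                        f"{path}: non-numeric token {tok!r} on line {lineno}"
                    ) from None
    if not values:
        raise ValueError(f"{path}: no samples")
    meta = _parse_filename_metadata(path)
    return Recording(samples=np.array(values), fs=float(fs), source=str(path), **meta)


def write_wav(rec: Recording, path: str | Path) -> None:
    """Write a recording as 16-bit PCM mono WAV.

    Samples are rescaled to full range only when they exceed [-1, 1].
    """
    samples = np.asarray(rec.samples, dtype=np.float64)
    if not np.all(np.isfinite(samples)):
        raise ValueError("samples contain NaN or Inf")
    peak = np.max(np.abs(samples)) if len(samples) else 0.0
    if peak > 1.0:
        samples = samples / peak
    pcm = np.round(samples * 32767.0).astype(np.int16)
    wavfile.write(Path(path), int(round(rec.fs)), pcm)


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a dataset manifest CSV and validate its columns."""
    df = pd.read_csv(path, dtype={"patient_id": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} missing columns {missing}")
    return df


def write_manifest(df: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest frame missing columns {missing}")
    df.to_csv(path, index=False)


def load_from_manifest(df: pd.DataFrame, root: str | Path | None = None) -> list[Recording]:
    """Load every recording listed in a manifest frame.

    Relative paths are resolved against ``root`` when given. Manifest
    metadata overrides whatever the filename encodes.
    """
    recs = []
    for row in df.itertuples(index=False):
        p = Path(row.path)
        if root is not None and not p.is_absolute():
            p = Path(root) / p
        rec = read_wav(p) if p.suffix.lower() == ".wav" else read_text_signal(p)
        rec.patient_id = str(row.patient_id)
        rec.position = int(row.position) if not pd.isna(row.position) else None
        rec.phase = row.phase if isinstance(row.phase, str) else "unknown"
        rec.label = row.label if isinstance(row.label, str) else "unknown"
        recs.append(rec)
    return recs
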