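"""Pre-processing of vascular-sound recordings.

Four steps, applied in order: min–max normalization to [0, 1],
empirical-mode-decomposition (EMD) filtering that removes the first
intrinsic mode function (the highest-frequency, noise-dominated mode),
segmentation of the 60 s recording into individual cardiac cycles, and
label-preserving data augmentation of the segmented cycles.

The EMD here is the classical sifting algorithm: cubic-spline envelopes
through the local maxima and minima (with a two-extremum mirror
extension at each boundary), iterated until a Cauchy-type normalized
squared-difference criterion falls below ``sd_stop``.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import butter, filtfilt, find_peaks

from .signal_io import Recording

logger = logging.getLogger(__name__)

# physiological heart-rate band: 30-200 bpm
MIN_CYCLE_S = 0.3
MAX_CYCLE_S = 2.0


@dataclass
class IMFSet:
    """Ordered intrinsic mode functions c(1..J) plus the residual."""

    imfs: list[np.ndarray]
    residual: np.ndarray
    n_sifts: list[int]

    @property
    def n_imfs(self) -> int:
        return len(self.imfs)

    def reconstruct(self) -> np.ndarray:
        out = self.residual.copy()
        for imf in self.imfs:
            out += imf
        return out


@dataclass
class CardiacCycle:
    """One heartbeat's worth of signal, the unit of classification."""

    samples: np.ndarray
    fs: float
    start_index: int
    cycle_period_s: float
    source_id: str = ""
    label: str = "unknown"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if not (MIN_CYCLE_S <= self.cycle_period_s <= MAX_CYCLE_S):
            raise ValueError(
                f"cycle period {self.cycle_period_s:.3f}s outside physiological "
                f"band [{MIN_CYCLE_S}, {MAX_CYCLE_S}]s"
            )


def normalize(samples: np.ndarray) -> np.ndarray:
    """Min–max rescale a signal to [0, 1]: (s - min) / (max - min)."""
    x = np.asarray(samples, dtype=np.float64)
    if x.size < 2:
        raise ValueError("need at least 2 samples to normalize")
    a, b = float(np.min(x)), float(np.max(x))
    if b == a:
        raise ValueError("degenerate signal: zero range")
    return (x - a) / (b - a)


def _local_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of interior local maxima and minima.

    Plateaus are collapsed to a single extremum at their midpoint.
    """
    d = np.sign(np.diff(x))
    # propagate the previous nonzero slope across flat runs
    nz = d != 0
    if not nz.any():
        return np.array([], dtype=int), np.array([], dtype=int)
    idx = np.where(nz, np.arange(len(d)), -1)
    np.maximum.accumulate(idx, out=idx)
    filled = np.where(idx >= 0, d[np.clip(idx, 0, None)], 0)
    turns = np.diff(filled)
    maxima = np.where(turns < 0)[0] + 1
    minima = np.where(turns > 0)[0] + 1
    return maxima, minima


def _mirrored_envelope(x: np.ndarray, ext_idx: np.ndarray) -> np.ndarray:
    """Cubic-spline envelope through extrema, mirror-extending up to two
    extrema beyond each boundary to tame end swings."""
    n = len(x)
    idx = ext_idx.astype(np.int64)
    vals = x[idx]
    n_mirror = min(2, len(idx))
    left_i = (-idx[:n_mirror])[::-1]
    left_v = vals[:n_mirror][::-1]
    right_i = (2 * (n - 1) - idx[-n_mirror:])[::-1]
    right_v = vals[-n_mirror:][::-1]
    full_i = np.concatenate([left_i, idx, right_i])
    full_v = np.concatenate([left_v, vals, right_v])
    full_i, keep = np.unique(full_i, return_index=True)
    full_v = full_v[keep]
    if len(full_i) < 2:
        return np.full(n, full_v[0] if len(full_v) else 0.0)
    if len(full_i) < 4:  # cubic needs >= 4 knots; fall back to linear
        return np.interp(np.arange(n), full_i, full_v)
    return CubicSpline(full_i, full_v)(np.arange(n))


def emd(
    samples: np.ndarray,
    max_imfs: int = 10,
    sd_stop: float = 0.2,
    max_sifts: int = 10,
) -> IMFSet:
    """Empirical mode decomposition by classical sifting.

    Decomposition stops when the residual is monotone (or has fewer
    than two interior extrema) or when ``max_imfs`` is reached. The
    identity  input = sum(IMFs) + residual  holds by construction.

    Parameters
    ----------
    max_imfs : maximum number of IMFs to extract.
    sd_stop : Cauchy-type sifting stop: sifting ends when
        sum((h_prev - h)^2) / sum(h_prev^2) < sd_stop.
    max_sifts : hard cap on sifting iterations per IMF.
    """
    x = np.asarray(samples, dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise ValueError("samples contain NaN or Inf")
    if x.size < 16:
        raise ValueError("need at least 16 samples for EMD")

    imfs: list[np.ndarray] = []
    n_sifts: list[int] = []
    residual = x.copy()
    for _ in range(max_imfs):
        maxima, minima = _local_extrema(residual)
        if len(maxima) + len(minima) < 2 or len(maxima) < 2 or len(minima) < 2:
            break  # residual is monotone or trend-like
        h = residual.copy()
        sifts = 0
        for _ in range(max_sifts):
            maxima, minima = _local_extrema(h)
            if len(maxima) < 2 or len(minima) < 2:
                break
            upper = _mirrored_envelope(h, maxima)
            lower = _mirrored_envelope(h, minima)
            mean_env = 0.5 * (upper + lower)
            h_new = h - mean_env
            sifts += 1
            denom = float(np.sum(h * h))
            sd = float(np.sum((h - h_new) ** 2)) / denom if denom > 0 else 0.0
            h = h_new
            if sd < sd_stop:
                break
        imfs.append(h)
        n_sifts.append(sifts)
        residual = residual - h
    return IMFSet(imfs=imfs, residual=residual, n_sifts=n_sifts)


def emd_filter(samples: np.ndarray, sd_stop: float = 0.2, max_sifts: int = 10) -> np.ndarray:
    """Remove the first IMF: s_filtered = s - c(1).

    The first IMF carries the highest-frequency content, dominated by
    sensor/ambient noise in vascular-sound recordings; only c(1) is
    sifted out, which is algebraically identical to (residual + IMFs
    2..J) of a full decomposition.
    """
    decomp = emd(samples, max_imfs=1, sd_stop=sd_stop, max_sifts=max_sifts)
    if decomp.n_imfs == 0:
        logger.warning("EMD produced no IMFs (signal has no oscillation); returning input unchanged")
        return np.asarray(samples, dtype=np.float64).copy()
    return np.asarray(samples, dtype=np.float64) - decomp.imfs[0]


def amplitude_envelope(samples: np.ndarray, fs: float, cutoff_hz: float = 20.0) -> np.ndarray:
    """Low-pass-filtered magnitude of the mean-removed signal."""
    x = np.asarray(samples, dtype=np.float64)
    rectified = np.abs(x - np.mean(x))
    b, a = butter(4, cutoff_hz / (fs / 2), btype="low")
    return filtfilt(b, a, rectified)


def estimate_cycle_period(
    samples: np.ndarray, fs: float, min_s: float = MIN_CYCLE_S, max_s: float = MAX_CYCLE_S
) -> float:
    """Cardiac-cycle period as the autocorrelation-maximizing lag of the
    amplitude envelope, searched over the physiological band."""
    env = amplitude_envelope(samples, fs)
    env = env - np.mean(env)
    n = len(env)
    # FFT autocorrelation
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    spec = np.fft.rfft(env, nfft)
    acf = np.fft.irfft(spec * np.conj(spec), nfft)[:n]
    lo = max(1, int(round(min_s * fs)))
    hi = min(n - 1, int(round(max_s * fs)))
    if hi <= lo:
        raise ValueError("signal too short to estimate a cycle period")
    lag = lo + int(np.argmax(acf[lo : hi + 1]))
    return lag / fs


def segment_cycles(rec: Recording, n_cycles: int = 10) -> list[CardiacCycle]:
    """Slice a recording into its first ``n_cycles`` complete cardiac cycles.

    Cycle onsets are envelope peaks at least 0.7 x the estimated period
    apart; each cycle runs onset-to-onset.
    """
    if rec.duration_s < n_cycles * MIN_CYCLE_S:
        raise ValueError(
            f"recording of {rec.duration_s:.2f}s cannot hold {n_cycles} cycles"
        )
    period = estimate_cycle_period(rec.samples, rec.fs)
    env = amplitude_envelope(rec.samples, rec.fs)
    min_dist = max(1, int(round(0.7 * period * rec.fs)))
    peaks, _ = find_peaks(env, distance=min_dist)
    cycles: list[CardiacCycle] = []
    for start, stop in zip(peaks[:-1], peaks[1:]):
        period_s = (stop - start) / rec.fs
        if not (MIN_CYCLE_S <= period_s <= MAX_CYCLE_S):
            continue
        cycles.append(
            CardiacCycle(
                samples=rec.samples[start:stop],
                fs=rec.fs,
                start_index=int(start),
                cycle_period_s=period_s,
                source_id=rec.patient_id + (f"_p{rec.position}" if rec.position else ""),
                label=rec.label,
            )
        )
        if len(cycles) == n_cycles:
            break
    if len(cycles) < n_cycles:
        raise ValueError(
            f"found only {len(cycles)} complete cycles, needed {n_cycles}"
        )
    return cycles


def augment(cycles: list[CardiacCycle], factor: int, seed: int) -> list[CardiacCycle]:
    """Originals plus (factor - 1) jittered copies of each cycle.

    Jitter = circular time-shift by up to 10% of the cycle length plus
    amplitude scaling by Uniform[0.9, 1.1]; labels are inherited.
    Intended for training folds only (label-preserving, leakage-safe
    when applied after the train/test split).
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    rng = np.random.default_rng(seed)
    out: list[CardiacCycle] = []
    for cyc in cycles:
        out.append(cyc)
        n = len(cyc.samples)
        max_shift = max(1, n // 10)
        for _ in range(factor - 1):
            shift = int(rng.integers(-max_shift, max_shift + 1))
            scale = float(rng.uniform(0.9, 1.1))
            out.append(
                CardiacCycle(
                    samples=np.roll(cyc.samples, shift) * scale,
                    fs=cyc.fs,
                    start_index=cyc.start_index,
                    cycle_period_s=cyc.cycle_period_s,
                    source_id=cyc.source_id,
                    label=cyc.label,
                )
            )
    return out
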