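"""Input features for stenosis classification.

Two feature families feed the concatenated classifier:

* **STFT spectrogram images** — the short-time Fourier transform of a
  cardiac cycle rendered as a fixed-size 3-channel image (the "visual"
  feature, consumed by the ResNet branch).
* **Band-limited sample entropy** — SampEn(z, m, r) = -ln(A/B), where z
  is the cycle restricted to a frequency band (F_L, F_H), A counts
  matching (m+1)-point template pairs and B matching m-point pairs
  under a tolerance of r times the standard deviation of z (the
  "texture" feature, consumed by the ANN branch). Regular signals score
  near 0; turbulent, bruit-like signals score high.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.fft import irfft, rfft, rfftfreq
from scipy.interpolate import RegularGridInterpolator
from scipy.signal import get_window

from .preprocess import CardiacCycle


class UndefinedEntropyError(ValueError):
    """Raised when no template pairs match and -ln(A/B) is undefined."""


@dataclass
class Spectrogram:
    """Time-frequency magnitude matrix (frequency bins x frames)."""

    magnitudes: np.ndarray
    freqs_hz: np.ndarray
    times_s: np.ndarray
    window: str
    width_samples: int
    hop_samples: int

    @property
    def n_frames(self) -> int:
        return self.magnitudes.shape[1]


@dataclass(frozen=True)
class SampEnParams:
    """A (F_L, F_H, m, r) quadruple for band-limited sample entropy."""

    F_L: float
    F_H: float
    m: int
    r: float

    def __post_init__(self) -> None:
        if not (0 <= self.F_L < self.F_H):
            raise ValueError(f"need 0 <= F_L < F_H, got ({self.F_L}, {self.F_H})")
        if self.m < 1:
            raise ValueError("embedding dimension m must be >= 1")
        if self.r <= 0:
            raise ValueError("tolerance factor r must be > 0")


#: The five best-performing quadruples from the 1215-point full-factorial
#: search over (F_L, F_H, m, r), in rank order. Rank 1 is (10, 700, 4, 0.2).
TOP5_PARAMS: tuple[SampEnParams, ...] = (
    SampEnParams(10, 700, 4, 0.2),
    SampEnParams(10, 500, 7, 0.3),
    SampEnParams(10, 1000, 5, 0.2),
    SampEnParams(10, 1000, 4, 0.3),
    SampEnParams(10, 600, 4, 0.3),
)


@dataclass
class SampEnFeature:
    """Entropy values for one cycle, one per configured quadruple."""

    values: np.ndarray
    params_list: tuple[SampEnParams, ...]
    cycle_ref: CardiacCycle | None = None
    missing: np.ndarray | None = None  # boolean mask of undefined entries


_WINDOWS = {"hann", "hamming", "rectangular"}


def stft(
    samples: np.ndarray,
    fs: float,
    window: str = "hann",
    width_samples: int = 1024,
    hop_samples: int = 512,
) -> Spectrogram:
    """Magnitude STFT with explicit left-aligned framing.

    Frame ``f`` covers samples ``[f*hop, f*hop + width)``; the one-sided
    spectrum of each windowed frame is returned, so ``freqs_hz`` runs
    from 0 to fs/2 and ``times_s`` marks frame centers.
    """
    x = np.asarray(samples, dtype=np.float64)
    if window not in _WINDOWS:
        raise ValueError(f"window must be one of {sorted(_WINDOWS)}")
    if width_samples > x.size:
        raise ValueError(
            f"window width {width_samples} exceeds signal length {x.size}"
        )
    if hop_samples < 1:
        raise ValueError("hop must be >= 1")
    w = (
        np.ones(width_samples)
        if window == "rectangular"
        else get_window(window, width_samples, fftbins=True)
    )
    n_frames = 1 + (x.size - width_samples) // hop_samples
    starts = np.arange(n_frames) * hop_samples
    frames = np.lib.stride_tricks.sliding_window_view(x, width_samples)[starts]
    mags = np.abs(rfft(frames * w, axis=1)).T
    return Spectrogram(
        magnitudes=mags,
        freqs_hz=rfftfreq(width_samples, 1.0 / fs),
        times_s=(starts + width_samples / 2) / fs,
        window=window,
        width_samples=width_samples,
        hop_samples=hop_samples,
    )


def spectrogram_to_image(
    spec: Spectrogram, size_px: int = 224, log_scale: bool = True
) -> np.ndarray:
    """Render a spectrogram as a (size_px, size_px, 3) image in [0, 1].

    Magnitudes are optionally mapped to dB (20 log10(mag + 1e-10)),
    min-max scaled, bilinearly resampled to a square, and replicated to
    three identical channels for the CNN branch. A constant-magnitude
    spectrogram (zero dynamic range) maps to the all-zero image.
    """
    M = spec.magnitudes
    if M.size == 0:
        raise ValueError("empty spectrogram")
    if log_scale:
        M = 20.0 * np.log10(M + 1e-10)
    mn, mx = float(M.min()), float(M.max())
    M = (M - mn) / (mx - mn) if mx > mn else np.zeros_like(M)
    h, w = M.shape
    interp = RegularGridInterpolator(
        (np.linspace(0.0, 1.0, h), np.linspace(0.0, 1.0, w)),
        M,
        method="linear" if min(h, w) > 1 else "nearest",
    )
    g = np.linspace(0.0, 1.0, size_px)
    gy, gx = np.meshgrid(g, g, indexing="ij")
    img = interp(np.stack([gy.ravel(), gx.ravel()], axis=1)).reshape(size_px, size_px)
    img = np.clip(img, 0.0, 1.0)
    return np.repeat(img[:, :, None], 3, axis=2)


def bandpass(samples: np.ndarray, fs: float, F_L: float, F_H: float) -> np.ndarray:
    """Ideal (FFT) band-pass: zero every bin with frequency outside the
    open interval (F_L, F_H), then invert. Idempotent by construction."""
    if F_L >= F_H:
        raise ValueError(f"need F_L < F_H, got ({F_L}, {F_H})")
    if F_L < 0 or F_H > fs / 2:
        raise ValueError(f"band ({F_L}, {F_H}) outside [0, fs/2] = [0, {fs / 2}]")
    x = np.asarray(samples, dtype=np.float64)
    X = rfft(x)
    f = rfftfreq(x.size, 1.0 / fs)
    X[(f <= F_L) | (f >= F_H)] = 0.0
    return irfft(X, n=x.size)


@njit(cache=False)
def _sampen_counts(z: np.ndarray, m: int, tol: float) -> tuple[int, int]:
    """Matched template-pair counts (A for length m+1, B for length m).

    Both template sets start at indices 0..N-m-1 (N-m templates each),
    pairs are unordered with i < j, and a match is a strict Chebyshev
    inequality d < tol.
    """
    n = z.shape[0] - m
    A = 0
    B = 0
    for i in range(n - 1):
        for j in range(i + 1, n):
            d = 0.0
            for t in range(m):
                diff = abs(z[i + t] - z[j + t])
                if diff > d:
                    d = diff
                if d >= tol:
                    break
            if d < tol:
                B += 1
                if abs(z[i + m] - z[j + m]) < tol:
                    A += 1
    return A, B


def sample_entropy(z: np.ndarray, m: int = 2, r: float = 0.2) -> float:
    """SampEn(z, m, r) = -ln(A/B).

    B counts unordered pairs of m-point templates whose Chebyshev
    distance is strictly below r*sd(z); A counts the same for
    (m+1)-point templates. sd is the population (divide-by-N) standard
    deviation. Scale- and shift-invariant since the tolerance tracks sd.
    """
    z = np.ascontiguousarray(z, dtype=np.float64)
    if m < 1:
        raise ValueError("m must be >= 1")
    if r <= 0:
        raise ValueError("r must be > 0")
    if z.size < m + 2:
        raise ValueError(f"need at least m+2={m + 2} samples, got {z.size}")
    sd = float(np.std(z))
    if sd == 0.0:
        raise ValueError("zero variance")
    A, B = _sampen_counts(z, m, r * sd)
    if A == 0 or B == 0:
        raise UndefinedEntropyError("undefined entropy: no template matches")
    return float(-np.log(A / B)) + 0.0  # +0.0 normalizes -0.0


def banded_sample_entropy(
    samples: np.ndarray,
    fs: float,
    p: SampEnParams,
    analysis_fs: float | None = None,
) -> float:
    """Sample entropy of the signal restricted to the band (F_L, F_H).

    When ``analysis_fs`` is given, the band-passed signal is decimated
    by the largest integer factor that keeps the new Nyquist frequency
    above F_H — exact (alias-free) for the band-limited signal, and it
    cuts the O(N^2) entropy cost accordingly.
    """
    z = bandpass(samples, fs, p.F_L, p.F_H)
    if analysis_fs is not None:
        q = max(1, int(fs // analysis_fs))
        while q > 1 and fs / q <= 2.0 * p.F_H:
            q -= 1
        z = z[::q]
    return sample_entropy(z, p.m, p.r)


def extract_features(
    cycle: CardiacCycle,
    params_list: tuple[SampEnParams, ...] | list[SampEnParams] | None = None,
    analysis_fs: float | None = 2205.0,
) -> SampEnFeature:
    """Entropy feature vector for one cycle, one value per quadruple.

    Defaults to the five top-ranked quadruples (:data:`TOP5_PARAMS`).
    Quadruples with undefined entropy are recorded as NaN and flagged;
    an all-missing vector is an error.
    """
    plist = tuple(params_list) if params_list is not None else TOP5_PARAMS
    if not plist:
        raise ValueError("params_list is empty")
    values = np.empty(len(plist))
    missing = np.zeros(len(plist), dtype=bool)
    for k, p in enumerate(plist):
        try:
            values[k] = banded_sample_entropy(cycle.samples, cycle.fs, p, analysis_fs)
        except UndefinedEntropyError:
            values[k] = np.nan
            missing[k] = True
    if missing.all():
        raise UndefinedEntropyError("entropy undefined for every configured quadruple")
    return SampEnFeature(values=values, params_list=plist, cycle_ref=cycle, missing=missing)
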