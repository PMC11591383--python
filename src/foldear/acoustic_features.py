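"""Hand-crafted 68-dimensional acoustic descriptor of a segment.

Per short-term frame (default 50 ms with 25 ms hop), 34 base features are
computed: three time-domain (zero-crossing rate, energy, energy entropy),
five spectral-shape (centroid, spread, entropy, flux, roll-off), 13 MFCCs
and 13 chroma features (12 semitone-class energy fractions, A440 reference,
plus their standard deviation).  First-order frame differences (deltas) of
all 34 double the set, and the per-column mean across frames yields the
fixed 68-dimensional segment vector.  A train-fitted standardizer brings
columns to zero mean / unit (population) standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.fft import dct

from .audio_io import AudioSegment, frame_signal
from .spectrograms import mel_filterbank

_EPS = 1e-10
N_BASE = 34
N_FEATURES = 68
_N_MEL_FILTERS = 40
_N_MFCC = 13
_ENTROPY_BLOCKS = 10
_ROLLOFF = 0.90

BASE_FEATURE_NAMES: tuple[str, ...] = (
    "zcr",
    "energy",
    "energy_entropy",
    "spectral_centroid",
    "spectral_spread",
    "spectral_entropy",
    "spectral_flux",
    "spectral_rolloff",
    *[f"mfcc_{i}" for i in range(1, 14)],
    *[f"chroma_{i}" for i in range(1, 13)],
    "chroma_std",
)
FEATURE_NAMES: tuple[str, ...] = BASE_FEATURE_NAMES + tuple(
    f"delta_{n}" for n in BASE_FEATURE_NAMES
)
assert len(BASE_FEATURE_NAMES) == N_BASE and len(FEATURE_NAMES) == N_FEATURES

DEFAULT_FRAME_SEC = 0.050
DEFAULT_HOP_SEC = 0.025


@dataclass
class FeatureFrameMatrix:
    values: np.ndarray  # (num_frames, 34)
    names: tuple[str, ...] = BASE_FEATURE_NAMES

    def __post_init__(self) -> None:
        if self.values.ndim != 2 or self.values.shape[1] != N_BASE:
            raise ValueError(f"expected (frames, {N_BASE}) matrix, got {self.values.shape}")


@dataclass
class AcousticFeatureVector:
    values: np.ndarray  # (68,)
    names: tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (N_FEATURES,):
            raise ValueError(f"expected {N_FEATURES} values, got {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite feature values")


def _entropy(p: np.ndarray) -> float:
    """Shannon entropy (bits) of a non-negative vector normalized to sum 1."""
    total = p.sum()
    if total <= 0:
        return 0.0
    q = p / total
    q = q[q > 0]
    return float(-np.sum(q * np.log2(q)))


def _zcr(frame: np.ndarray) -> float:
    s = frame >= 0.0
    return float(np.count_nonzero(s[1:] != s[:-1])) / (frame.size - 1)


def _energy_entropy(frame: np.ndarray) -> float:
    block = frame.size // _ENTROPY_BLOCKS
    if block == 0:
        return 0.0
    sub = frame[: block * _ENTROPY_BLOCKS].reshape(_ENTROPY_BLOCKS, block)
    return _entropy(np.sum(sub**2, axis=1))


def _chroma_map(n_fft: int, sample_rate: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-rfft-bin semitone class (A440 reference); bin 0 (DC) excluded."""
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / sample_rate)
    classes = np.full(freqs.size, -1, dtype=np.int64)
    pos = freqs > 0
    classes[pos] = np.mod(np.round(12.0 * np.log2(freqs[pos] / 440.0)).astype(np.int64), 12)
    return classes, freqs


def short_term_features(
    segment: AudioSegment,
    frame_length: int | None = None,
    hop: int | None = None,
) -> FeatureFrameMatrix:
    """Compute the 34 base short-term features for every frame.

    Spectral features use the magnitude of the un-windowed real FFT of the
    frame; centroid/spread/roll-off are expressed in normalized frequency
    (1 = Nyquist).  Flux is the squared distance between successive
    L2-normalized magnitude spectra (first frame 0).  MFCCs come from a
    40-filter mel bank on the frame's power spectrum, log-compressed with a
    1e-10 floor, followed by an orthonormal DCT-II keeping the first 13
    coefficients.  Chroma folds power-spectrum bins onto the 12 semitone
    classes and reports energy fractions of total power.
    """
    sr = segment.sample_rate
    if frame_length is None:
        frame_length = int(round(DEFAULT_FRAME_SEC * sr))
    if hop is None:
        hop = int(round(DEFAULT_HOP_SEC * sr))
    if frame_length < 2:
        raise ValueError("frame_length must be >= 2 samples")
    fs = frame_signal(segment, frame_length, hop)
    if fs.num_frames == 0:
        raise ValueError("segment shorter than one analysis frame")

    frames = fs.frames
    n_fr = fs.num_frames
    mag = np.abs(np.fft.rfft(frames, axis=1))  # (T, n_bins)
    power = mag**2
    n_bins = mag.shape[1]
    f_norm = np.arange(n_bins) / (n_bins - 1)

    fb = mel_filterbank(_N_MEL_FILTERS, frame_length, sr)
    chroma_classes, _ = _chroma_map(frame_length, sr)

    out = np.zeros((n_fr, N_BASE))
    # time domain
    out[:, 0] = [_zcr(fr) for fr in frames]
    out[:, 1] = np.mean(frames**2, axis=1)
    out[:, 2] = [_energy_entropy(fr) for fr in frames]
    # spectral shape
    mag_sum = mag.sum(axis=1)
    safe = np.where(mag_sum > 0, mag_sum, 1.0)
    centroid = (mag @ f_norm) / safe
    centroid[mag_sum == 0] = 0.0
    out[:, 3] = centroid
    spread = np.sqrt(np.maximum((mag @ f_norm**2) / safe - centroid**2, 0.0))
    spread[mag_sum == 0] = 0.0
    out[:, 4] = spread
    out[:, 5] = [_entropy(p) for p in power]
    norms = np.linalg.norm(mag, axis=1)
    unit = mag / np.where(norms > 0, norms, 1.0)[:, None]
    flux = np.zeros(n_fr)
    if n_fr > 1:
        flux[1:] = np.sum((unit[1:] - unit[:-1]) ** 2, axis=1)
    out[:, 6] = flux
    p_tot = power.sum(axis=1)
    cum = np.cumsum(power, axis=1)
    for t in range(n_fr):
        if p_tot[t] <= 0:
            out[t, 7] = 0.0
        else:
            out[t, 7] = f_norm[int(np.searchsorted(cum[t], _ROLLOFF * p_tot[t]))]
    # cepstral domain: MFCC 1..13
    mel_energy = power @ fb.T
    log_mel = np.log(np.maximum(mel_energy, _EPS))
    out[:, 8:21] = dct(log_mel, type=2, norm="ortho", axis=1)[:, :_N_MFCC]
    # chroma: 12 class-energy fractions + their std
    chroma = np.zeros((n_fr, 12))
    for c in range(12):
        chroma[:, c] = power[:, chroma_classes == c].sum(axis=1)
    tot = chroma.sum(axis=1)
    chroma = chroma / np.where(tot > 0, tot, 1.0)[:, None]
    out[:, 21:33] = chroma
    out[:, 33] = chroma.std(axis=1)
    return FeatureFrameMatrix(values=out)


def delta_features(base: np.ndarray) -> np.ndarray:
    """First-order frame differences; the first frame's delta is 0."""
    d = np.zeros_like(base)
    if base.shape[0] > 1:
        d[1:] = base[1:] - base[:-1]
    return d


def segment_features(
    segment: AudioSegment,
    frame_length: int | None = None,
    hop: int | None = None,
) -> AcousticFeatureVector:
    """The 68-dimensional segment descriptor: mean of [base || delta] frames."""
    base = short_term_features(segment, frame_length, hop).values
    stacked = np.hstack([base, delta_features(base)])
    return AcousticFeatureVector(values=stacked.mean(axis=0))


def feature_matrix(segments: list[AudioSegment], **kw) -> np.ndarray:
    """Stack segment descriptors into an (n, 68) matrix in list order."""
    return np.vstack([segment_features(s, **kw).values for s in segments])


@dataclass
class Standardizer:
    """Column-wise (x - mean)/sd scaler fitted on training rows only.

    Uses the population (divide-by-n) standard deviation; zero-variance
    columns get scale 1 so they standardize to exactly zero.
    """

    means: np.ndarray | None = None
    scales: np.ndarray | None = None
    fitted: bool = False

    def fit(self, X: np.ndarray) -> "Standardizer":
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("fit requires a 2-D matrix with at least 2 rows")
        self.means = X.mean(axis=0)
        sd = X.std(axis=0)
        self.scales = np.where(sd > 0, sd, 1.0)
        self.fitted = True
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if not self.fitted:
            raise RuntimeError("standardizer not fitted; call fit on training rows first")
        return (np.asarray(X, dtype=np.float64) - self.means) / self.scales


def fit_standardizer(X: np.ndarray) -> Standardizer:
    return Standardizer().fit(X)


def apply_standardizer(s: Standardizer, X: np.ndarray) -> np.ndarray:
    return s.transform(X)
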