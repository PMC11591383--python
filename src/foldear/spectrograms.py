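"""Time-frequency transforms and fixed-size image rendering.

Three magnitude spectrograms feed the CNN: the short-time Fourier transform

    X(tau, k) = sum_n x(n) w(n - tau) exp(-j 2 pi k n / N),

the constant-Q transform with geometrically spaced bins f_k = f_min 2^(k/B)
and quality factor Q = 1/(2^(1/B) - 1),

    X_cqt(k) = (1/N_k) sum_{n<N_k} x(n) w_{N_k}(n) exp(-j 2 pi Q n / N_k),
    N_k = ceil(fs Q / f_k),

and the mel spectrogram, STFT magnitudes pooled through triangular filters
spaced uniformly on the perceptual mel scale Mel(f) = 2595 log10(1 + f/700).

Defaults follow the study configuration: N = 2048 for the STFT, 200 CQT
bins at 32 bins/octave (6.25 octaves) from 22.05 Hz.  The CQT is evaluated
directly from its definition, one kernel per bin — segments are 1-3 s, so
no fast multi-rate algorithm is needed.  Rendering maps magnitude to dB,
clips to an 80 dB floor below the peak, min-max normalizes, applies a fixed
256-entry RGB lookup table shipped as package data, and bilinearly resizes
to the 100x100x3 CNN input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import numpy as np

from .audio_io import AudioSegment, frame_signal

IMAGE_SIZE = 100
_DB_RANGE = 80.0
_DB_FLOOR = 1e-10


def hann(n: int) -> np.ndarray:
    """Periodic Hann window of length n."""
    return 0.5 - 0.5 * np.cos(2.0 * np.pi * np.arange(n) / n)


@dataclass
class STFTConfig:
    N: int = 2048
    hop: int = 512
    window: str = "hann"

    def __post_init__(self) -> None:
        if self.N < 2 or self.hop < 1:
            raise ValueError("require N >= 2 and hop >= 1")
        if self.window != "hann":
            raise ValueError("only the Hann window is supported")


@dataclass
class CQTConfig:
    total_bins: int = 200
    bins_per_octave: int = 32
    f_min: float = 22.05
    hop: int = 512
    quality_factor: Optional[float] = None  # default 1/(2^(1/B) - 1)
    window: str = "hann"

    def __post_init__(self) -> None:
        if self.total_bins < 1 or self.bins_per_octave < 1 or self.f_min <= 0 or self.hop < 1:
            raise ValueError("invalid CQT configuration")
        if self.quality_factor is None:
            self.quality_factor = 1.0 / (2.0 ** (1.0 / self.bins_per_octave) - 1.0)

    @property
    def octave_span(self) -> float:
        return self.total_bins / self.bins_per_octave

    def bin_frequencies(self) -> np.ndarray:
        k = np.arange(self.total_bins)
        return self.f_min * 2.0 ** (k / self.bins_per_octave)

    def kernel_lengths(self, sample_rate: int) -> np.ndarray:
        """N_k = ceil(fs * Q / f_k), the constant-Q window length per bin."""
        return np.ceil(sample_rate * self.quality_factor / self.bin_frequencies()).astype(np.int64)


@dataclass
class MelConfig:
    n_mels: int = 128
    N: int = 2048
    hop: int = 512
    f_min: float = 0.0
    f_max: Optional[float] = None  # defaults to Nyquist at transform time

    def __post_init__(self) -> None:
        if self.n_mels < 1:
            raise ValueError("n_mels must be >= 1")


@dataclass
class Spectrogram:
    """Non-negative magnitude matrix (frequency_bins x time_frames)."""

    values: np.ndarray
    bin_frequencies: np.ndarray
    frame_times: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.size and (np.any(self.values < 0) or not np.all(np.isfinite(self.values))):
            raise ValueError("spectrogram values must be finite and non-negative")


@dataclass
class SpectrogramImage:
    """100x100x3 image in [0, 1] as fed to the CNN."""

    pixels: np.ndarray
    kind: str
    source_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.shape != (IMAGE_SIZE, IMAGE_SIZE, 3):
            raise ValueError(f"image must be {IMAGE_SIZE}x{IMAGE_SIZE}x3, got {self.pixels.shape}")
        if self.pixels.size and (self.pixels.min() < 0 or self.pixels.max() > 1):
            raise ValueError("pixel values must lie in [0, 1]")


def stft(segment: AudioSegment, config: STFTConfig = STFTConfig()) -> Spectrogram:
    """One-sided magnitude STFT; rows = N/2 + 1, column tau starts at tau*hop."""
    x = segment.samples
    if x.size < config.N:
        raise ValueError(
            f"signal has {x.size} samples but the window needs {config.N}; "
            "zero-pad upstream before calling stft"
        )
    fs = frame_signal(segment, config.N, config.hop)
    w = hann(config.N)
    mag = np.abs(np.fft.rfft(fs.frames * w, axis=1)).T  # (N/2+1, T)
    freqs = np.fft.rfftfreq(config.N, d=1.0 / segment.sample_rate)
    times = fs.origin_offsets / segment.sample_rate
    return Spectrogram(values=mag, bin_frequencies=freqs, frame_times=times, kind="stft")


def cqt(segment: AudioSegment, config: CQTConfig = CQTConfig()) -> Spectrogram:
    """Constant-Q magnitude transform evaluated directly from its definition.

    Kernel lengths N_k at low bins can exceed the segment (N_k ~ 1e5 samples
    at 22.05 Hz / 48 kHz versus 1-3 s clips); such kernels are truncated to
    the available signal and renormalized by the actual kernel length.  The
    complex exponential keeps the nominal N_k so the analyzed frequency
    Q*fs/N_k stays at f_k.  Frames start at tau*hop for every tau with
    tau*hop inside the signal; the signal is zero-padded at the tail so each
    frame spans a full (possibly truncated) kernel.
    """
    x = segment.samples
    if x.size == 0:
        raise ValueError("empty segment")
    sr = segment.sample_rate
    freqs = config.bin_frequencies()
    over = np.nonzero(freqs > sr / 2.0)[0]
    if over.size:
        k = int(over[0])
        raise ValueError(
            f"CQT bin {k} at {freqs[k]:.2f} Hz exceeds the Nyquist frequency {sr / 2.0:.2f} Hz"
        )
    nominal = config.kernel_lengths(sr)
    lengths = np.minimum(nominal, x.size)  # truncation policy
    hop = config.hop
    n_frames = (x.size - 1) // hop + 1
    l_max = int(lengths.max())
    padded = np.concatenate([x, np.zeros(l_max)])
    frames = np.lib.stride_tricks.sliding_window_view(padded, l_max)[::hop][:n_frames]
    out = np.empty((config.total_bins, n_frames))
    for k in range(config.total_bins):
        lk, nk = int(lengths[k]), int(nominal[k])
        n = np.arange(lk)
        kernel = hann(lk) * np.exp(-2j * np.pi * config.quality_factor * n / nk)
        out[k] = np.abs(frames[:, :lk] @ kernel) / lk
    times = np.arange(n_frames) * hop / sr
    return Spectrogram(values=out, bin_frequencies=freqs, frame_times=times, kind="cqt")


def mel_scale(f) -> np.ndarray | float:
    """Mel(f) = 2595 log10(1 + f/700); f in Hz, f >= 0."""
    f = np.asarray(f, dtype=np.float64)
    if np.any(f < 0):
        raise ValueError("frequency must be non-negative")
    out = 2595.0 * np.log10(1.0 + f / 700.0)
    return float(out) if out.ndim == 0 else out


def mel_to_hz(m) -> np.ndarray | float:
    m = np.asarray(m, dtype=np.float64)
    out = 700.0 * (10.0 ** (m / 2595.0) - 1.0)
    return float(out) if out.ndim == 0 else out


def mel_filterbank(
    n_mels: int, n_fft: int, sample_rate: float, f_min: float = 0.0, f_max: Optional[float] = None
) -> np.ndarray:
    """Triangular filters (n_mels x (n_fft/2+1)) uniform on the mel scale.

    Filter i rises from edge i to i+1 and falls to i+2 over n_mels+2 edges
    placed uniformly in mel units between Mel(f_min) and Mel(f_max); peak
    weight 1 (no area normalization).
    """
    if f_max is None:
        f_max = sample_rate / 2.0
    if not (0 <= f_min < f_max <= sample_rate / 2.0):
        raise ValueError("require 0 <= f_min < f_max <= Nyquist")
    edges = mel_to_hz(np.linspace(mel_scale(f_min), mel_scale(f_max), n_mels + 2))
    bin_freqs = np.fft.rfftfreq(n_fft, d=1.0 / sample_rate)
    fb = np.zeros((n_mels, bin_freqs.size))
    for i in range(n_mels):
        lo, mid, hi = edges[i], edges[i + 1], edges[i + 2]
        up = (bin_freqs - lo) / (mid - lo) if mid > lo else np.zeros_like(bin_freqs)
        down = (hi - bin_freqs) / (hi - mid) if hi > mid else np.zeros_like(bin_freqs)
        fb[i] = np.clip(np.minimum(up, down), 0.0, 1.0)
    return fb


def mel_spectrogram(segment: AudioSegment, config: MelConfig = MelConfig()) -> Spectrogram:
    """Mel spectrogram: triangular filterbank applied to STFT magnitudes."""
    f_max = config.f_max if config.f_max is not None else segment.sample_rate / 2.0
    spec = stft(segment, STFTConfig(N=config.N, hop=config.hop))
    fb = mel_filterbank(config.n_mels, config.N, segment.sample_rate, config.f_min, f_max)
    mel_edges = mel_to_hz(
        np.linspace(mel_scale(config.f_min), mel_scale(f_max), config.n_mels + 2)
    )
    return Spectrogram(
        values=fb @ spec.values,
        bin_frequencies=mel_edges[1:-1],
        frame_times=spec.frame_times,
        kind="mel",
    )


def _load_lut() -> np.ndarray:
    with resources.files("foldear.data").joinpath("colormap_lut.csv").open("r") as fh:
        lut = np.loadtxt(fh, delimiter=",", skiprows=1)
    assert lut.shape == (256, 3)
    return lut


_LUT = _load_lut()


def bilinear_resize(image: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    """Bilinear resize with half-pixel-centered sampling.

    Output pixel (i, j) samples the source at ((i+0.5)*H/out_h - 0.5,
    (j+0.5)*W/out_w - 0.5), coordinates clamped to the source grid.  Works
    on 2-D maps and on H x W x C stacks.
    """
    img = np.asarray(image, dtype=np.float64)
    squeeze = img.ndim == 2
    if squeeze:
        img = img[:, :, None]
    h, w, _ = img.shape

    def _coords(out_n: int, n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        src = (np.arange(out_n) + 0.5) * n / out_n - 0.5
        src = np.clip(src, 0.0, n - 1.0)
        i0 = np.floor(src).astype(np.int64)
        i1 = np.minimum(i0 + 1, n - 1)
        return i0, i1, src - i0

    r0, r1, fr = _coords(out_h, h)
    c0, c1, fc = _coords(out_w, w)
    fr = fr[:, None, None]
    fc = fc[None, :, None]
    top = img[r0][:, c0] * (1 - fc) + img[r0][:, c1] * fc
    bot = img[r1][:, c0] * (1 - fc) + img[r1][:, c1] * fc
    out = top * (1 - fr) + bot * fr
    return out[:, :, 0] if squeeze else out


def render_image(spec: Spectrogram, size: int = IMAGE_SIZE) -> SpectrogramImage:
    """Render a magnitude spectrogram as the CNN's fixed-size RGB input.

    Pipeline: 20*log10(v + 1e-10) dB -> clip to [max - 80 dB, max] ->
    min-max normalize to [0, 1] (a flat map, e.g. silence, maps to 1) ->
    256-entry RGB lookup by nearest index -> bilinear resize to size x size.
    The dB + min-max combination makes the image invariant to global gain.
    """
    v = spec.values
    if v.size == 0:
        raise ValueError("cannot render an empty spectrogram")
    db = 20.0 * np.log10(v + _DB_FLOOR)
    top = db.max()
    db = np.clip(db, top - _DB_RANGE, top)
    lo, hi = db.min(), db.max()
    norm = np.ones_like(db) if hi == lo else (db - lo) / (hi - lo)
    idx = np.round(norm * 255.0).astype(np.int64)
    rgb = _LUT[idx]  # (F, T, 3)
    pixels = np.clip(bilinear_resize(rgb, size, size), 0.0, 1.0)
    return SpectrogramImage(pixels=pixels, kind=spec.kind)


def transform(segment: AudioSegment, kind: str, sample_rate_hint: Optional[int] = None) -> Spectrogram:
    """Dispatch to one of the three transforms by name with default configs."""
    if kind == "stft":
        return stft(segment)
    if kind == "cqt":
        return cqt(segment)
    if kind == "mel":
        return mel_spectrogram(segment)
    raise ValueError(f"unknown spectrogram kind {kind!r} (use stft, cqt or mel)")
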