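"""Synthetic sheepfold audio with the spectro-temporal structure of the task.

Real collar recordings of foraging, rumination and miscellaneous barn sound
are private, so this generator emulates their defining regularities:

* foraging — a fast, regular train of short broadband chewing transients
  (band-passed noise bursts, ~1-6 kHz, 3-4 events/s, 40-80 ms each);
* rumination — a slower, sustained rhythm of longer lower-band bursts
  (~0.4-3 kHz, 1-1.5 events/s, 80-150 ms);
* other — a heterogeneous mixture of harmonic bleats (f0 200-500 Hz, five
  harmonics, slow vibrato), single loud broadband coughs, soft rhythmic
  panting, and noise-only clips.

Events ride on pink (1/f) background noise scaled to a controllable
signal-to-background ratio; each segment is peak-normalized to 0.9 and is a
pure function of its seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import butter, sosfilt

from .audio_io import AudioSegment, write_label_table, write_wav


@dataclass
class EventModel:
    """Event process of one behavior class."""

    behavior: str
    event_rate: float = 3.5  # events / s
    duration_ms: tuple[float, float] = (40.0, 80.0)
    band_hz: tuple[float, float] = (1000.0, 6000.0)
    jitter: float = 0.3  # fraction of the inter-event period
    mixture: dict[str, float] | None = None  # "other" only

    def __post_init__(self) -> None:
        if self.event_rate <= 0:
            raise ValueError("event_rate must be positive")
        if self.mixture is not None and abs(sum(self.mixture.values()) - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")


FORAGING = EventModel("foraging", event_rate=3.5, duration_ms=(40, 80), band_hz=(1000, 6000))
RUMINATION = EventModel("rumination", event_rate=1.25, duration_ms=(80, 150), band_hz=(400, 3000))
OTHER = EventModel(
    "other",
    event_rate=2.0,
    duration_ms=(50, 120),
    band_hz=(500, 6000),
    mixture={"bleat": 0.4, "cough": 0.2, "pant": 0.2, "noise": 0.2},
)
CLASS_MODELS = {"foraging": FORAGING, "rumination": RUMINATION, "other": OTHER}


@dataclass
class CorpusSpec:
    n_per_class: int = 60
    duration_range: tuple[float, float] = (1.0, 3.0)
    sample_rate: int = 48_000
    snr_db: float = 10.0
    seed: int = 7

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if not np.isfinite(self.snr_db):
            raise ValueError("snr_db must be finite")


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """1/f noise via spectral shaping of white Gaussian noise."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1] if n > 1 else 1.0
    x = np.fft.irfft(spec / np.sqrt(f), n=n)
    return x / (np.std(x) + 1e-12)


def _burst(n: int, band: tuple[float, float], sr: int, rng: np.random.Generator) -> np.ndarray:
    """Hann-enveloped band-passed noise burst of n samples."""
    lo, hi = band
    nyq = sr / 2.0
    if hi >= nyq:
        raise ValueError(f"band upper edge {hi} Hz exceeds Nyquist {nyq} Hz")
    noise = rng.standard_normal(max(n, 16))
    sos = butter(4, [lo / nyq, hi / nyq], btype="band", output="sos")
    x = sosfilt(sos, noise)[:n]
    env = np.hanning(n)
    x = x * env
    return x / (np.max(np.abs(x)) + 1e-12)


def _bleat(duration: float, sr: int, rng: np.random.Generator) -> np.ndarray:
    """Harmonic stack with slow vibrato and a smooth envelope."""
    n = int(duration * sr)
    t = np.arange(n) / sr
    f0 = rng.uniform(200.0, 500.0)
    vib = 1.0 + 0.02 * np.sin(2 * np.pi * rng.uniform(4.0, 7.0) * t)
    phase = 2 * np.pi * np.cumsum(f0 * vib) / sr
    x = np.zeros(n)
    for h in range(1, 6):
        x += np.sin(h * phase + rng.uniform(0, 2 * np.pi)) / h
    x *= np.hanning(n)
    return x / (np.max(np.abs(x)) + 1e-12)


def _event_times(duration: float, rate: float, jitter: float, rng: np.random.Generator) -> np.ndarray:
    """Jittered periodic event onsets: (i + 0.5)/rate + U(-j/2, j/2)/rate."""
    n_events = int(np.floor(duration * rate))
    if n_events == 0:
        return np.empty(0)
    i = np.arange(n_events)
    times = (i + 0.5) / rate + rng.uniform(-jitter / 2, jitter / 2, size=n_events) / rate
    return np.clip(times, 0.0, duration)


def _place(signal: np.ndarray, burst: np.ndarray, start: int) -> None:
    end = min(start + burst.size, signal.size)
    if end > start:
        signal[start:end] += burst[: end - start]


def _components(
    model: EventModel,
    duration: float,
    sample_rate: int,
    snr_db: float,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Event train and scaled background before mixing and normalization."""
    if duration < 0.5:
        raise ValueError("duration must be >= 0.5 s")
    rng = np.random.default_rng(seed)
    n = int(duration * sample_rate)
    events = np.zeros(n)

    kind = model.behavior
    if model.mixture is not None:
        names = sorted(model.mixture)
        kind = rng.choice(names, p=[model.mixture[k] for k in names])

    if kind in ("foraging", "rumination", "pant"):
        rate = 2.0 if kind == "pant" else model.event_rate
        dur_ms = (30.0, 60.0) if kind == "pant" else model.duration_ms
        band = (800.0, 5000.0) if kind == "pant" else model.band_hz
        amp = 0.4 if kind == "pant" else 1.0
        for t0 in _event_times(duration, rate, model.jitter, rng):
            dur = rng.uniform(*dur_ms) / 1000.0
            b = _burst(int(dur * sample_rate), band, sample_rate, rng) * amp
            _place(events, b, int(t0 * sample_rate))
    elif kind == "bleat":
        t0 = rng.uniform(0.0, max(duration - 0.8, 0.0))
        _place(events, _bleat(min(0.8, duration), sample_rate, rng), int(t0 * sample_rate))
    elif kind == "cough":
        t0 = rng.uniform(0.1, max(duration - 0.2, 0.1))
        b = _burst(int(0.12 * sample_rate), (300.0, min(7000.0, sample_rate / 2 - 1)), sample_rate, rng)
        _place(events, 1.5 * b, int(t0 * sample_rate))
    elif kind == "noise":
        pass  # background only
    else:  # pragma: no cover - guarded by EventModel
        raise ValueError(f"unknown event kind {kind!r}")

    event_rms = float(np.sqrt(np.mean(events**2)))
    ref_rms = event_rms if event_rms > 0 else 0.1
    bg = _pink_noise(n, rng)
    bg *= ref_rms / (10.0 ** (snr_db / 20.0))
    return events, bg


def generate_segment(
    model: EventModel,
    duration: float,
    sample_rate: int,
    snr_db: float,
    seed: int,
) -> AudioSegment:
    """Synthesize one labelled segment; deterministic in the seed.

    The background is pink noise scaled ``snr_db`` below the event train's
    RMS (event-free clips keep an arbitrary reference RMS so the ratio is
    still defined); the mixed signal is peak-normalized to 0.9.
    """
    events, bg = _components(model, duration, sample_rate, snr_db, seed)
    x = events + bg
    peak = np.max(np.abs(x))
    if peak > 0:
        x = 0.9 * x / peak
    return AudioSegment(samples=x, sample_rate=sample_rate, label=model.behavior)


def _file_seed(master: int, index: int) -> int:
    """Stable per-file seed below 2**31 derived from the master seed."""
    h = hashlib.sha256(f"{master}:{index}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)


def generate_corpus(spec: CorpusSpec, out_dir: Path | str) -> Path:
    """Write ``3 * n_per_class`` WAV files, ``labels.csv`` and ``spec.json``.

    Per-file seeds are derived from the master seed so the corpus is
    reproducible file-by-file; re-running with the same spec produces
    byte-identical WAVs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    index = 0
    for behavior in ("foraging", "other", "rumination"):
        model = CLASS_MODELS[behavior]
        for i in range(spec.n_per_class):
            seed = _file_seed(spec.seed, index)
            rng = np.random.default_rng(seed)
            duration = rng.uniform(*spec.duration_range)
            seg = generate_segment(model, duration, spec.sample_rate, spec.snr_db, seed + 1)
            name = f"{behavior}_{i:04d}.wav"
            write_wav(out_dir / name, seg)
            rows.append((name, behavior))
            index += 1
    write_label_table(out_dir / "labels.csv", rows)
    meta = {
        "n_per_class": spec.n_per_class,
        "duration_range": list(spec.duration_range),
        "sample_rate": spec.sample_rate,
        "snr_db": spec.snr_db,
        "seed": spec.seed,
    }
    (out_dir / "spec.json").write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    return out_dir


def load_corpus(corpus_dir: Path | str) -> list[AudioSegment]:
    """Read a generated corpus back as labelled segments, labels.csv order."""
    from .audio_io import read_label_table, read_wav

    corpus_dir = Path(corpus_dir)
    table = read_label_table(corpus_dir / "labels.csv")
    segments = []
    for _, row in table.iterrows():
        seg = read_wav(corpus_dir / row["path"])
        seg.label = row["label"]
        segments.append(seg)
    return segments
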