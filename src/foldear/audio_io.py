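"""WAV input/output, framing, and energy-based segmentation.

Collar microphones record mono 48 kHz WAV; annotation cuts long recordings
into short behavior segments by an energy threshold plus a minimum-duration
(time) threshold.  This module supplies that plumbing: RIFF PCM / IEEE-float
WAV round-tripping, overlapping frame extraction, and the threshold
segmenter.  No resampling is ever performed here — transforms downstream
take the sample rate as data.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.io import wavfile

DEFAULT_SAMPLE_RATE = 48_000
LABELS = ("foraging", "other", "rumination")  # fixed alphabetical class order


@dataclass
class AudioSegment:
    """A mono audio snippet with amplitude in [-1, 1].

    Parameters
    ----------
    samples : ndarray
        1-D float array of amplitudes.
    sample_rate : int
        Samples per second (Hz), > 0.
    label : str, optional
        Behavior tag, one of ``{"foraging", "rumination", "other"}``.
    source_id : str, optional
        Provenance string (e.g. the originating file name).
    """

    samples: np.ndarray
    sample_rate: int = DEFAULT_SAMPLE_RATE
    label: Optional[str] = None
    source_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("AudioSegment samples must be 1-D (mono)")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.samples.size and not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")
        if self.label is not None and self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")

    @property
    def duration(self) -> float:
        """Segment length in seconds."""
        return self.samples.size / self.sample_rate


@dataclass
class FrameSet:
    """Overlapping frames cut from a signal (no padding, tail dropped)."""

    frames: np.ndarray  # (num_frames, frame_length)
    frame_length: int
    hop: int
    origin_offsets: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))

    @property
    def num_frames(self) -> int:
        return self.frames.shape[0]


def read_wav(path: os.PathLike | str) -> AudioSegment:
    """Read a RIFF WAV file to a mono [-1, 1] :class:`AudioSegment`.

    Integer PCM is scaled by the type's full-scale negative value (e.g.
    int16 by 32768); multi-channel audio is averaged to mono.  The header
    sample rate is kept as-is — no resampling.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    try:
        rate, data = wavfile.read(path)
    except Exception as exc:  # wave/scipy raise assorted types for bad payloads
        raise ValueError(f"{path} is not a readable WAV file: {exc}") from exc
    if data.size == 0:
        raise ValueError(f"{path} contains zero-length audio")
    if data.ndim == 2:
        data = data.astype(np.float64).mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        info = np.iinfo(data.dtype)
        if info.min < 0:  # signed PCM: full scale = |min| (32768 for int16)
            samples = data.astype(np.float64) / -float(info.min)
        else:  # uint8 WAV stores offset binary
            samples = (data.astype(np.float64) - 128.0) / 128.0
    else:
        samples = data.astype(np.float64)
    return AudioSegment(samples=samples, sample_rate=int(rate), source_id=path.stem)


def write_wav(path: os.PathLike | str, segment: AudioSegment, subtype: str = "PCM_16") -> None:
    """Write a segment as 16-bit PCM (default) or 32-bit float WAV.

    PCM_16 quantizes with round(x * 32768) clipped to the int16 range, the
    inverse of the scaling used by :func:`read_wav`, so a PCM-sourced signal
    round-trips within 1 LSB.
    """
    path = Path(path)
    if subtype == "PCM_16":
        q = np.round(segment.samples * 32768.0)
        data = np.clip(q, -32768, 32767).astype(np.int16)
    elif subtype == "FLOAT":
        data = segment.samples.astype(np.float32)
    else:
        raise ValueError(f"unsupported subtype {subtype!r} (use PCM_16 or FLOAT)")
    wavfile.write(path, int(segment.sample_rate), data)


def num_frames(n_samples: int, frame_length: int, hop: int) -> int:
    """floor((n - L)/hop) + 1 when n >= L, else 0."""
    if n_samples < frame_length:
        return 0
    return (n_samples - frame_length) // hop + 1


def frame_signal(segment: AudioSegment, frame_length: int, hop: int) -> FrameSet:
    """Cut a segment into contiguous overlapping frames.

    The trailing partial frame is dropped, never padded; a signal shorter
    than one frame yields an empty :class:`FrameSet`.
    """
    if frame_length < 1 or hop < 1:
        raise ValueError("frame_length and hop must be >= 1")
    x = segment.samples
    n = num_frames(x.size, frame_length, hop)
    if n == 0:
        return FrameSet(
            frames=np.empty((0, frame_length)), frame_length=frame_length, hop=hop,
            origin_offsets=np.empty(0, dtype=np.int64),
        )
    view = np.lib.stride_tricks.sliding_window_view(x, frame_length)[::hop][:n]
    offsets = np.arange(n, dtype=np.int64) * hop
    return FrameSet(frames=view.copy(), frame_length=frame_length, hop=hop, origin_offsets=offsets)


def segment_by_energy(
    segment: AudioSegment,
    energy_threshold: float,
    min_duration: float,
    frame_length: int = 2048,
    hop: int = 512,
) -> list[AudioSegment]:
    """Cut active regions out of a long recording.

    A frame is "active" when its mean-square energy is at or above
    ``energy_threshold``; maximal runs of consecutive active frames lasting
    at least ``min_duration`` seconds are converted back to sample ranges
    (run start = first frame's offset, run end = last frame's offset +
    frame_length) and sliced from the source.  Silence yields an empty list.
    """
    if energy_threshold <= 0 or min_duration <= 0:
        raise ValueError("energy_threshold and min_duration must be positive")
    fs = frame_signal(segment, frame_length, hop)
    if fs.num_frames == 0:
        return []
    energies = np.mean(fs.frames**2, axis=1)
    active = energies >= energy_threshold
    out: list[AudioSegment] = []
    i = 0
    while i < active.size:
        if not active[i]:
            i += 1
            continue
        j = i
        while j + 1 < active.size and active[j + 1]:
            j += 1
        start = int(fs.origin_offsets[i])
        end = min(int(fs.origin_offsets[j]) + frame_length, segment.samples.size)
        if (end - start) / segment.sample_rate >= min_duration:
            out.append(
                AudioSegment(
                    samples=segment.samples[start:end],
                    sample_rate=segment.sample_rate,
                    label=segment.label,
                    source_id=f"{segment.source_id or 'segment'}_{start}_{end}",
                )
            )
        i = j + 1
    return out


def read_label_table(path: os.PathLike | str) -> pd.DataFrame:
    """Read a headered CSV with columns ``path,label``; validate labels."""
    df = pd.read_csv(path)
    missing = {"path", "label"} - set(df.columns)
    if missing:
        raise ValueError(f"label table missing columns: {sorted(missing)}")
    bad = set(df["label"]) - set(LABELS)
    if bad:
        raise ValueError(f"unknown labels in table: {sorted(bad)}")
    return df


def write_label_table(path: os.PathLike | str, rows: list[tuple[str, str]]) -> None:
    pd.DataFrame(rows, columns=["path", "label"]).to_csv(path, index=False)
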