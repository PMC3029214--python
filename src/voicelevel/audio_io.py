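"""Audio and corpus I/O: WAV reading, endpoint trimming, framing, manifests.

All downstream analysis operates on :class:`Waveform` objects (float samples
nominally in ``[-1, 1]``) cut into 25 ms Hamming-windowed frames with 75 %
overlap, the framing convention used throughout the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

WORDS = ("mashin", "mar", "moosh", "gav", "mouz")
LEVELS = (1, 2, 3, 4)

__all__ = [
    "WORDS",
    "LEVELS",
    "Waveform",
    "UtteranceRecord",
    "FrameMatrix",
    "AudioFormatError",
    "EmptyUtteranceError",
    "read_wav",
    "write_wav",
    "trim_endpoints",
    "frame_signal",
    "read_manifest",
    "write_manifest",
]


class AudioFormatError(ValueError):
    """Raised when a file cannot be parsed as PCM WAV audio."""


class EmptyUtteranceError(ValueError):
    """Raised when no audio frame exceeds the trimming energy threshold."""


@dataclass(frozen=True)
class Waveform:
    """A mono audio signal.

    Parameters
    ----------
    samples
        1-D float array, nominally in ``[-1, 1]``.
    sample_rate
        Sampling frequency in Hz.
    """

    samples: np.ndarray
    sample_rate: int

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1 or samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples must be finite")
        if int(self.sample_rate) <= 0:
            raise ValueError("sample_rate must be positive")
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "sample_rate", int(self.sample_rate))

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate

    def __len__(self) -> int:
        return self.samples.size


@dataclass(frozen=True)
class UtteranceRecord:
    """One labelled utterance: a word spoken once by one child."""

    waveform: Waveform
    word: str
    level: int
    child_id: str
    repetition: int = 1

    def __post_init__(self) -> None:
        if self.word not in WORDS:
            raise ValueError(f"unknown word {self.word!r}; expected one of {WORDS}")
        if self.level not in LEVELS:
            raise ValueError(f"level must be in {LEVELS}, got {self.level}")
        if self.repetition < 1:
            raise ValueError("repetition must be >= 1")


@dataclass(frozen=True)
class FrameMatrix:
    """Hamming-windowed analysis frames of one utterance.

    ``frames`` has shape ``(T, L)``; each row is a raw segment multiplied by
    the Hamming window.  ``hop`` is ``round(L * (1 - overlap))``.
    """

    frames: np.ndarray
    frame_length_s: float
    overlap_fraction: float
    sample_rate: int
    window: np.ndarray = field(repr=False, default=None)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_length(self) -> int:
        return self.frames.shape[1]

    @property
    def hop(self) -> int:
        return int(round(self.frame_length * (1.0 - self.overlap_fraction)))


def read_wav(path: str | Path) -> Waveform:
    """Read a PCM WAV file into a mono :class:`Waveform`.

    Stereo files are mixed to mono by channel averaging; integer PCM is
    rescaled to ``[-1, 1]``.
    """
    path = Path(path)
    try:
        rate, data = wavfile.read(str(path))
    except Exception as exc:  # wavfile raises bare ValueError on bad headers
        raise AudioFormatError(f"cannot read WAV file {path}: {exc}") from exc
    if data.ndim == 2:
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        info = np.iinfo(data.dtype)
        scale = float(max(abs(info.min), info.max))
        data = data.astype(np.float64) / scale
    else:
        data = data.astype(np.float64)
    return Waveform(samples=data, sample_rate=int(rate))


def write_wav(path: str | Path, w: Waveform) -> None:
    """Write a waveform as 16-bit PCM WAV."""
    clipped = np.clip(w.samples, -1.0, 1.0)
    pcm = np.clip(np.round(clipped * 32768.0), -32768, 32767).astype(np.int16)
    wavfile.write(str(path), w.sample_rate, pcm)


def _subframe_energy_db(x: np.ndarray, sub_len: int) -> np.ndarray:
    n_sub = max(1, x.size // sub_len)
    trimmed = x[: n_sub * sub_len].reshape(n_sub, sub_len)
    energy = np.mean(trimmed**2, axis=1)
    peak = energy.max()
    if peak <= 0.0:
        return np.full(n_sub, -np.inf)
    with np.errstate(divide="ignore"):
        return 10.0 * np.log10(energy / peak)


def trim_endpoints(
    w: Waveform,
    energy_threshold_db: float = -35.0,
    min_voiced_s: float = 0.02,
) -> Waveform:
    """Strip leading/trailing silence around an isolated word.

    Short-time energy is measured on 10 ms sub-frames; the signal is cut
    from the first to the last sub-frame whose energy exceeds
    ``energy_threshold_db`` relative to the loudest sub-frame.  Runs of
    above-threshold sub-frames shorter than ``min_voiced_s`` are ignored so
    isolated clicks do not anchor the endpoints.
    """
    sub_len = max(1, int(round(0.010 * w.sample_rate)))
    db = _subframe_energy_db(w.samples, sub_len)
    voiced = db > energy_threshold_db
    if not voiced.any():
        raise EmptyUtteranceError("no frame exceeds the energy threshold")

    min_run = max(1, int(np.ceil(min_voiced_s / 0.010)))
    kept = np.zeros_like(voiced)
    i = 0
    while i < voiced.size:
        if voiced[i]:
            j = i
            while j < voiced.size and voiced[j]:
                j += 1
            if j - i >= min_run:
                kept[i:j] = True
            i = j
        else:
            i += 1
    if not kept.any():
        kept = voiced  # every run is short; fall back to raw threshold mask
    idx = np.flatnonzero(kept)
    start = idx[0] * sub_len
    stop = min(w.samples.size, (idx[-1] + 1) * sub_len)
    return Waveform(samples=w.samples[start:stop], sample_rate=w.sample_rate)


def frame_signal(
    w: Waveform,
    frame_length_s: float = 0.025,
    overlap: float = 0.75,
) -> FrameMatrix:
    """Cut a waveform into Hamming-windowed frames.

    Frame length ``L = floor(frame_length_s * fs)``, hop
    ``round(L * (1 - overlap))``; the trailing partial frame is dropped.
    """
    if not (0.0 <= overlap < 1.0):
        raise ValueError("overlap must be in [0, 1)")
    L = int(np.floor(frame_length_s * w.sample_rate))
    if L < 1 or w.samples.size < L:
        raise ValueError(
            f"signal of {w.samples.size} samples shorter than one frame ({L})"
        )
    hop = int(round(L * (1.0 - overlap)))
    hop = max(1, hop)
    T = (w.samples.size - L) // hop + 1
    window = np.hamming(L)
    idx = np.arange(L)[None, :] + hop * np.arange(T)[:, None]
    frames = w.samples[idx] * window[None, :]
    return FrameMatrix(
        frames=frames,
        frame_length_s=frame_length_s,
        overlap_fraction=overlap,
        sample_rate=w.sample_rate,
        window=window,
    )


MANIFEST_COLUMNS = ["path", "child_id", "word", "level", "repetition"]


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a corpus manifest CSV (columns path, child_id, word, level, repetition)."""
    df = pd.read_csv(path, dtype={"child_id": str})
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    bad_words = set(df["word"]) - set(WORDS)
    if bad_words:
        raise ValueError(f"manifest contains unknown words: {sorted(bad_words)}")
    if not df["level"].isin(LEVELS).all():
        raise ValueError("manifest levels must be in 1..4")
    return df[MANIFEST_COLUMNS]


def write_manifest(path: str | Path, rows: pd.DataFrame) -> None:
    rows[MANIFEST_COLUMNS].to_csv(path, index=False)


def load_utterances(manifest: pd.DataFrame, root: str | Path = ".") -> list[UtteranceRecord]:
    """Load every WAV referenced by a manifest into UtteranceRecords."""
    root = Path(root)
    records = []
    for row in manifest.itertuples(index=False):
        wav_path = Path(row.path)
        if not wav_path.is_absolute():
            wav_path = root / wav_path
        records.append(
            UtteranceRecord(
                waveform=read_wav(wav_path),
                word=row.word,
                level=int(row.level),
                child_id=str(row.child_id),
                repetition=int(row.repetition),
            )
        )
    return records
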