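"""Readers/writers for audio, IMU and hypnogram files, and the shared epoch grid.

All downstream processing works on three in-memory containers --
:class:`AudioRecording`, :class:`ImuRecording` and :class:`Hypnogram` --
plus the :class:`EpochGrid` that maps between recording time and the fixed
30-second scoring epochs used throughout sleep medicine.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.io import wavfile
from scipy.signal import resample_poly

__all__ = [
    "AudioRecording",
    "ImuRecording",
    "Hypnogram",
    "EpochGrid",
    "STAGE_ALPHABETS",
    "FormatError",
    "DataError",
    "read_audio",
    "write_audio",
    "read_imu",
    "write_imu",
    "read_hypnogram",
    "write_hypnogram",
    "align_to_epochs",
    "resample_audio",
]

EPOCH_SECONDS = 30.0

#: Stage alphabets: raw AASM labels and the three reduced staging systems
#: (2-stage wake/sleep, 3-stage wake/REM/NREM, 4-stage wake/REM/light/deep).
STAGE_ALPHABETS: dict[str, tuple[str, ...]] = {
    "raw": ("W", "REM", "N1", "N2", "N3"),
    "s2": ("W", "S"),
    "s3": ("W", "REM", "NREM"),
    "s4": ("W", "REM", "LS", "DS"),
}


class FormatError(ValueError):
    """A file does not conform to the expected on-disk format."""


class DataError(ValueError):
    """File parsed but its content violates an invariant."""


@dataclass
class AudioRecording:
    """Uniformly sampled single-channel audio.

    Parameters
    ----------
    samples : ndarray of float
        Amplitude series in arbitrary units, nominally in [-1, 1].
    sample_rate : float
        Sampling rate in Hz, > 0.
    start_time : float
        Offset of the first sample relative to epoch 0, in seconds.
    """

    samples: np.ndarray
    sample_rate: float
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise DataError("audio must be a non-empty 1-D array")
        if not self.sample_rate > 0:
            raise DataError("sample_rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise DataError("audio contains non-finite samples")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.samples.size) / self.sample_rate


@dataclass
class ImuRecording:
    """6-axis inertial stream: 3-axis accelerometer + 3-axis gyroscope.

    ``accel`` is in m/s^2 (gravity magnitude ~9.81 at rest), ``gyro`` in
    rad/s, both of shape (n, 3) at a common ``sample_rate``.
    """

    accel: np.ndarray
    gyro: np.ndarray
    sample_rate: float
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.accel = np.atleast_2d(np.asarray(self.accel, dtype=np.float64))
        self.gyro = np.atleast_2d(np.asarray(self.gyro, dtype=np.float64))
        if self.accel.shape != self.gyro.shape or self.accel.shape[1] != 3:
            raise DataError("accel and gyro must both have shape (n, 3)")
        if not self.sample_rate > 0:
            raise DataError("sample_rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.accel.shape[0]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate


@dataclass
class Hypnogram:
    """Per-epoch sleep stage labels over one of the declared alphabets."""

    labels: list[str]
    alphabet_id: str = "raw"
    epoch_seconds: float = EPOCH_SECONDS

    def __post_init__(self) -> None:
        if self.alphabet_id not in STAGE_ALPHABETS:
            raise DataError(f"unknown stage alphabet {self.alphabet_id!r}")
        self.labels = [str(l) for l in self.labels]
        alphabet = STAGE_ALPHABETS[self.alphabet_id]
        for i, label in enumerate(self.labels):
            if label not in alphabet:
                raise DataError(
                    f"epoch {i}: label {label!r} not in alphabet "
                    f"{self.alphabet_id!r} {alphabet}"
                )
        if self.epoch_seconds != EPOCH_SECONDS:
            raise DataError("epoch length is fixed at 30 s")

    @property
    def n_epochs(self) -> int:
        return len(self.labels)

    def __len__(self) -> int:
        return len(self.labels)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Hypnogram)
            and self.alphabet_id == other.alphabet_id
            and self.labels == other.labels
        )


@dataclass(frozen=True)
class EpochGrid:
    """The 30-second epoch grid: epoch k covers [30k, 30(k+1)) seconds."""

    n_epochs: int
    epoch_seconds: float = EPOCH_SECONDS
    origin: float = 0.0

    def start(self, k: int) -> float:
        return self.origin + k * self.epoch_seconds

    def end(self, k: int) -> float:
        return self.origin + (k + 1) * self.epoch_seconds

    def epoch_of(self, t: float | np.ndarray) -> np.ndarray:
        """Epoch index containing time ``t`` (half-open intervals)."""
        return np.floor((np.asarray(t) - self.origin) / self.epoch_seconds).astype(int)

    def __len__(self) -> int:
        return self.n_epochs


def read_audio(path) -> AudioRecording:
    """Read a mono PCM WAV file; samples are scaled to [-1, 1].

    Raises :class:`FormatError` for unreadable or multi-channel files.
    """
    try:
        rate, data = wavfile.read(path)
    except Exception as exc:  # scipy raises bare ValueError on bad headers
        raise FormatError(f"cannot read WAV file {path}: {exc}") from exc
    if data.ndim != 1:
        raise FormatError(f"{path}: expected mono audio, got {data.ndim} channels")
    if data.dtype == np.int16:
        samples = data / 32768.0
    elif data.dtype == np.int32:
        samples = data / 2147483648.0
    elif data.dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 128.0
    elif np.issubdtype(data.dtype, np.floating):
        samples = data.astype(np.float64)
    else:
        raise FormatError(f"{path}: unsupported WAV sample format {data.dtype}")
    return AudioRecording(samples=samples, sample_rate=float(rate))


def write_audio(audio: AudioRecording, path) -> None:
    """Write audio as 16-bit PCM WAV (samples clipped to [-1, 1])."""
    clipped = np.clip(audio.samples, -1.0, 1.0)
    pcm = np.round(clipped * 32767.0).astype(np.int16)
    wavfile.write(path, int(round(audio.sample_rate)), pcm)


_IMU_COLUMNS = ["t", "ax", "ay", "az", "gx", "gy", "gz"]


def read_imu(path) -> ImuRecording:
    """Read an IMU CSV with header ``t,ax,ay,az,gx,gy,gz``.

    The sample rate is inferred from the median timestamp increment.
    Non-monotone timestamps raise :class:`DataError`.
    """
    df = pd.read_csv(path)
    missing = [c for c in _IMU_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing IMU columns {missing}")
    t = df["t"].to_numpy(dtype=float)
    if t.size < 2:
        raise DataError(f"{path}: need at least 2 IMU samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        bad = int(np.argmax(dt <= 0))
        raise DataError(f"{path}: non-monotone timestamp at row {bad + 1}")
    rate = 1.0 / float(np.median(dt))
    return ImuRecording(
        accel=df[["ax", "ay", "az"]].to_numpy(dtype=float),
        gyro=df[["gx", "gy", "gz"]].to_numpy(dtype=float),
        sample_rate=rate,
        start_time=float(t[0]),
    )


def write_imu(imu: ImuRecording, path) -> None:
    t = imu.start_time + np.arange(imu.n_samples) / imu.sample_rate
    df = pd.DataFrame(
        np.column_stack([t, imu.accel, imu.gyro]), columns=_IMU_COLUMNS
    )
    df.to_csv(path, index=False)


def read_hypnogram(path, alphabet_id: str = "raw") -> Hypnogram:
    """Read a hypnogram: either one label per line or CSV ``epoch,label``."""
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    labels: list[str] = []
    for ln in lines:
        if "," in ln:
            parts = [p.strip() for p in ln.split(",")]
            if parts[0].lower() == "epoch":  # header row
                continue
            labels.append(parts[1])
        else:
            labels.append(ln)
    return Hypnogram(labels=labels, alphabet_id=alphabet_id)


def write_hypnogram(h: Hypnogram, path) -> None:
    with open(path, "w") as fh:
        fh.write("epoch,label\n")
        for i, label in enumerate(h.labels):
            fh.write(f"{i},{label}\n")


def align_to_epochs(recording_duration_s: float) -> EpochGrid:
    """Epoch grid for a recording: trailing partial epochs are discarded."""
    if not recording_duration_s > 0:
        raise ValueError("recording duration must be positive")
    return EpochGrid(n_epochs=int(recording_duration_s // EPOCH_SECONDS))


def resample_audio(audio: AudioRecording, target_rate: float = 5000.0) -> AudioRecording:
    """Resample to the reference 5 kHz rate so filter designs are fixed."""
    if audio.sample_rate == target_rate:
        return audio
    from fractions import Fraction

    frac = Fraction(target_rate / audio.sample_rate).limit_denominator(1000)
    out = resample_poly(audio.samples, frac.numerator, frac.denominator)
    return AudioRecording(out, target_rate, audio.start_time)
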