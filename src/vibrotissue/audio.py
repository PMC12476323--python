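"""Core audio container and WAV file I/O.

Recordings are mono sample sequences at a nominal 22050 Hz, tagged with the
physical recording they came from and (optionally) a tissue-class label.
Integer-PCM WAV files are rescaled to floats in [-1, 1] on read; files are
written as 32-bit float RIFF WAV to avoid quantization interacting with the
template-subtraction denoiser.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy.io import wavfile

logger = logging.getLogger(__name__)

DEFAULT_SAMPLE_RATE = 22050

# full-scale divisors for integer PCM subformats
_PCM_SCALE = {
    np.dtype(np.int16): 32768.0,
    np.dtype(np.int32): 2147483648.0,
}


@dataclass
class AudioRecording:
    """A mono audio signal with provenance metadata.

    Parameters
    ----------
    samples
        1-D float array of amplitudes.
    sample_rate
        Sampling rate in Hz.
    recording_id
        Identifier of the physical recording the samples came from; segments
        cut from one recording share this id (it is the grouping key for the
        leakage-free cross-validation split).
    class_id
        Optional tissue class in ``{0..4}`` (kidney, liver, muscle, rib, skin).
    """

    samples: np.ndarray
    sample_rate: int = DEFAULT_SAMPLE_RATE
    recording_id: str = ""
    class_id: int | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError(f"samples must be 1-D, got shape {self.samples.shape}")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate

    def with_samples(self, samples: np.ndarray) -> "AudioRecording":
        """Copy of this recording with the sample array replaced."""
        return replace(self, samples=np.asarray(samples, dtype=np.float64))


def read_wav(path: str | Path, expected_rate: int | None = None) -> AudioRecording:
    """Read a mono WAV file into an :class:`AudioRecording`.

    Integer PCM is scaled by its full-scale value into [-1, 1); float data is
    passed through. A sample rate differing from ``expected_rate`` is kept but
    logged as a warning.

    Raises
    ------
    IOError
        If the file is unreadable or not mono.
    """
    path = Path(path)
    try:
        rate, data = wavfile.read(path)
    except (ValueError, FileNotFoundError) as exc:
        raise IOError(f"cannot read WAV file {path}: {exc}") from exc
    if data.ndim != 1:
        raise IOError(f"{path}: expected mono audio, got {data.ndim} channels")
    if data.dtype in _PCM_SCALE:
        samples = data.astype(np.float64) / _PCM_SCALE[data.dtype]
    elif data.dtype == np.uint8:  # 8-bit WAV is unsigned
        samples = (data.astype(np.float64) - 128.0) / 128.0
    else:
        samples = data.astype(np.float64)
    if expected_rate is not None and rate != expected_rate:
        logger.warning("%s: sample rate %d Hz differs from expected %d Hz", path, rate, expected_rate)
    return AudioRecording(samples=samples, sample_rate=int(rate), recording_id=path.stem)


def write_wav(path: str | Path, rec: AudioRecording) -> None:
    """Write a recording as 32-bit float mono RIFF WAV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    wavfile.write(path, rec.sample_rate, rec.samples.astype(np.float32))
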