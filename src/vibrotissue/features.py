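"""Time–frequency image representations consumed by the classifiers.

Two representations are produced from each (raw or denoised) segment:

* **Mel-dB spectrogram** — STFT with a 1024-sample Hann window and hop 512,
  magnitudes mapped through a 64-filter Mel filterbank and converted to dB
  relative to the per-segment maximum, floored at -80 dB.
* **CWT scalogram** — magnitude of a continuous wavelet transform with the
  perfectly symmetric generalized Morse wavelet (γ = 3) at time-bandwidth
  product βγ = 60 (β = 20), on a logarithmic frequency grid (10 voices per
  octave, 20 Hz up to Nyquist), one column per input sample.

Scalograms destined for fixed-input models are bilinearly resized to
224 × 160. Corpora are featurized into HDF5 archives carrying features,
labels and recording ids.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import scipy.fft
from scipy import signal as sps

from .audio import AudioRecording, read_wav
from .synthetic import CorpusManifest

MEL_N_FFT = 1024
MEL_HOP = 512
N_MELS = 64
DB_FLOOR = -80.0
MORSE_GAMMA = 3.0
MORSE_TIME_BANDWIDTH = 60.0
CWT_VOICES_PER_OCTAVE = 10
CWT_FMIN = 20.0
RESIZE_ROWS, RESIZE_COLS = 224, 160


@dataclass
class Spectrogram:
    """2-D time–frequency energy array with axis metadata.

    ``values`` has frequency/scale rows by time columns; ``representation``
    is ``"mel_db"`` or ``"cwt"``. CWT rows are ordered by descending
    frequency.
    """

    values: np.ndarray
    representation: str
    freq_axis: np.ndarray
    time_axis: np.ndarray
    source_id: tuple[str, int] = ("", 0)


# ---------------------------------------------------------------------------
# Mel spectrogram


def hz_to_mel(f: np.ndarray | float) -> np.ndarray:
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=np.float64) / 700.0)


def mel_to_hz(m: np.ndarray | float) -> np.ndarray:
    return 700.0 * (10.0 ** (np.asarray(m, dtype=np.float64) / 2595.0) - 1.0)


def mel_filterbank(
    sample_rate: int, n_fft: int = MEL_N_FFT, n_mels: int = N_MELS,
    fmin: float = 0.0, fmax: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Triangular Mel filterbank (HTK mel scale, area-normalized).

    Returns ``(weights, center_freqs)`` with weights of shape
    ``(n_mels, n_fft//2 + 1)``.
    """
    if fmax is None:
        fmax = sample_rate / 2
    fft_freqs = np.linspace(0, sample_rate / 2, n_fft // 2 + 1)
    mel_pts = np.linspace(hz_to_mel(fmin), hz_to_mel(fmax), n_mels + 2)
    hz_pts = mel_to_hz(mel_pts)
    weights = np.zeros((n_mels, fft_freqs.size))
    for i in range(n_mels):
        lo, center, hi = hz_pts[i], hz_pts[i + 1], hz_pts[i + 2]
        up = (fft_freqs - lo) / max(center - lo, 1e-12)
        down = (hi - fft_freqs) / max(hi - center, 1e-12)
        weights[i] = np.maximum(0.0, np.minimum(up, down))
        weights[i] *= 2.0 / max(hi - lo, 1e-12)  # area normalization
    return weights, hz_pts[1:-1]


def _stft_magnitude(x: np.ndarray, n_fft: int, hop: int) -> np.ndarray:
    """Centered STFT magnitude with Hann window and reflect padding.

    Frame count is ``1 + len(x) // hop`` (frame k centered at sample k*hop).
    """
    pad = n_fft // 2
    xp = np.pad(x, pad, mode="reflect")
    n_frames = 1 + len(x) // hop
    window = sps.get_window("hann", n_fft, fftbins=True)
    frames = np.lib.stride_tricks.sliding_window_view(xp, n_fft)[: n_frames * hop : hop]
    return np.abs(np.fft.rfft(frames * window, axis=1)).T


def amplitude_to_db(a: np.ndarray, floor_db: float = DB_FLOOR) -> np.ndarray:
    """``20·log10(A / max(A))`` floored at ``floor_db``; all-zero input maps to the floor."""
    ref = float(a.max(initial=0.0))
    if ref <= 0:
        return np.full_like(a, floor_db, dtype=np.float64)
    db = 20.0 * np.log10(np.maximum(a, 1e-10 * ref) / ref)
    return np.maximum(db, floor_db)


def mel_spectrogram(
    rec: AudioRecording,
    n_fft: int = MEL_N_FFT,
    hop: int = MEL_HOP,
    n_mels: int = N_MELS,
    segment_index: int = 0,
) -> Spectrogram:
    """Mel-dB spectrogram: STFT(1024, hop 512, Hann, centered) → 64 Mel bins → dB."""
    x = rec.samples
    if x.size < n_fft:
        raise ValueError(f"recording ({x.size} samples) shorter than one window ({n_fft})")
    mag = _stft_magnitude(x, n_fft, hop)
    weights, centers = mel_filterbank(rec.sample_rate, n_fft, n_mels)
    mel = weights @ mag
    db = amplitude_to_db(mel)
    times = np.arange(db.shape[1]) * hop / rec.sample_rate
    return Spectrogram(db, "mel_db", centers, times, (rec.recording_id, segment_index))


# ---------------------------------------------------------------------------
# Generalized Morse wavelet CWT


def morse_peak_omega(beta: float, gamma: float) -> float:
    """Angular frequency (rad/sample) where the Morse frequency response peaks."""
    return (beta / gamma) ** (1.0 / gamma)


def morse_freq_response(omega: np.ndarray, beta: float, gamma: float) -> np.ndarray:
    """Analytic Morse wavelet in the frequency domain, peak value 2.

    ``ψ̂(ω) = 2 H(ω) a ω^β e^{-ω^γ}`` with the normalizing constant ``a``
    chosen so the response equals 2 at its peak (L1-style normalization:
    a unit-amplitude tone at the wavelet's center frequency yields unit
    transform magnitude).
    """
    omega = np.asarray(omega, dtype=np.float64)
    wp = morse_peak_omega(beta, gamma)
    log_a = -(beta * np.log(wp) - wp**gamma)
    out = np.zeros_like(omega)
    pos = omega > 0
    out[pos] = 2.0 * np.exp(log_a + beta * np.log(omega[pos]) - omega[pos] ** gamma)
    return out


def cwt_frequencies(
    sample_rate: int,
    fmin: float = CWT_FMIN,
    voices_per_octave: int = CWT_VOICES_PER_OCTAVE,
) -> np.ndarray:
    """Logarithmic center-frequency grid, descending from Nyquist to ``fmin``."""
    fmax = sample_rate / 2
    n_rows = int(np.ceil(np.log2(fmax / fmin) * voices_per_octave)) + 1
    return fmax * 2.0 ** (-np.arange(n_rows) / voices_per_octave)


def cwt_spectrogram(
    rec: AudioRecording,
    time_bandwidth: float = MORSE_TIME_BANDWIDTH,
    gamma: float = MORSE_GAMMA,
    fmin: float = CWT_FMIN,
    voices_per_octave: int = CWT_VOICES_PER_OCTAVE,
    segment_index: int = 0,
) -> Spectrogram:
    """Morse-wavelet scalogram (magnitude), one column per input sample.

    γ = 3 selects the symmetric member of the generalized Morse family; the
    time-bandwidth product βγ fixes β (β = 20 at the default 60). The FFT of
    the signal is multiplied by the scaled wavelet response at each center
    frequency and inverse-transformed.
    """
    x = rec.samples
    if x.size < 64:
        raise ValueError(f"recording too short for CWT ({x.size} < 64 samples)")
    beta = time_bandwidth / gamma
    n = x.size
    nfft = scipy.fft.next_fast_len(2 * n)  # zero-pad to reduce circular wrap-around
    xf = np.fft.fft(x, nfft)
    omega = 2 * np.pi * np.fft.fftfreq(nfft)
    wp = morse_peak_omega(beta, gamma)
    freqs = cwt_frequencies(rec.sample_rate, fmin, voices_per_octave)
    scales = wp / (2 * np.pi * freqs / rec.sample_rate)
    values = np.empty((freqs.size, n))
    for i, s in enumerate(scales):
        wf = morse_freq_response(s * omega, beta, gamma)
        values[i] = np.abs(np.fft.ifft(xf * wf)[:n])
    times = np.arange(n) / rec.sample_rate
    return Spectrogram(values, "cwt", freqs, times, (rec.recording_id, segment_index))


# ---------------------------------------------------------------------------
# Resizing


def _linear_coords(n_src: int, n_dst: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    # pixel-center convention; identity when n_src == n_dst
    src = (np.arange(n_dst) + 0.5) * n_src / n_dst - 0.5
    src = np.clip(src, 0, n_src - 1)
    i0 = np.floor(src).astype(int)
    i1 = np.minimum(i0 + 1, n_src - 1)
    w = src - i0
    return i0, i1, w


def _resize_1d(axis: np.ndarray, n_dst: int) -> np.ndarray:
    i0, i1, w = _linear_coords(axis.size, n_dst)
    return axis[i0] * (1 - w) + axis[i1] * w


def resize_spectrogram(spec: Spectrogram, rows: int = RESIZE_ROWS, cols: int = RESIZE_COLS) -> Spectrogram:
    """Bilinear resize to ``rows × cols`` with axis metadata rescaled.

    Resizing to the input's own shape is the identity.
    """
    if rows < 1 or cols < 1:
        raise ValueError("target shape must be at least 1x1")
    v = spec.values
    r0, r1, wr = _linear_coords(v.shape[0], rows)
    c0, c1, wc = _linear_coords(v.shape[1], cols)
    top = v[r0][:, c0] * (1 - wc) + v[r0][:, c1] * wc
    bot = v[r1][:, c0] * (1 - wc) + v[r1][:, c1] * wc
    out = top * (1 - wr[:, None]) + bot * wr[:, None]
    return Spectrogram(
        out,
        spec.representation,
        _resize_1d(np.asarray(spec.freq_axis, dtype=np.float64), rows),
        _resize_1d(np.asarray(spec.time_axis, dtype=np.float64), cols),
        spec.source_id,
    )


# ---------------------------------------------------------------------------
# Corpus featurization


@dataclass
class FeatureArchive:
    """In-memory view of a featurized corpus (HDF5-backed on disk)."""

    features: np.ndarray  # (n, rows, cols) float32
    labels: np.ndarray  # (n,) int
    recording_ids: np.ndarray  # (n,) str
    representation: str

    def __len__(self) -> int:
        return self.features.shape[0]

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with h5py.File(path, "w") as f:
            f.create_dataset("features", data=self.features.astype(np.float32))
            f.create_dataset("labels", data=self.labels.astype(np.int64))
            f.create_dataset(
                "recording_ids",
                data=np.asarray([s.encode() for s in self.recording_ids]),
            )
            f.attrs["representation"] = self.representation

    @classmethod
    def load(cls, path: str | Path) -> "FeatureArchive":
        with h5py.File(path, "r") as f:
            return cls(
                features=f["features"][()],
                labels=f["labels"][()],
                recording_ids=np.asarray([s.decode() for s in f["recording_ids"][()]]),
                representation=str(f.attrs["representation"]),
            )


def featurize_recording(
    rec: AudioRecording, representation: str, segment_index: int = 0,
    resize_cwt: tuple[int, int] | None = (RESIZE_ROWS, RESIZE_COLS),
) -> Spectrogram:
    if representation == "mel":
        return mel_spectrogram(rec, segment_index=segment_index)
    if representation == "cwt":
        spec = cwt_spectrogram(rec, segment_index=segment_index)
        if resize_cwt is not None:
            spec = resize_spectrogram(spec, *resize_cwt)
        return spec
    raise ValueError(f"unknown representation {representation!r} (expected 'mel' or 'cwt')")


def featurize_corpus(
    manifest: CorpusManifest,
    representation: str = "mel",
    denoised: bool = False,
    out_path: str | Path | None = None,
    resize_cwt: tuple[int, int] | None = (RESIZE_ROWS, RESIZE_COLS),
) -> FeatureArchive:
    """Featurize every segment in a manifest into one archive.

    ``denoised`` applies the template-subtraction denoiser per segment before
    feature extraction; raw and denoised archives share shapes and labels, so
    the four study datasets (raw/denoised × mel/cwt) are directly comparable.
    """
    from .denoise import denoise  # deferred: avoids import cycle at module load

    feats, labels, rids = [], [], []
    for _, row in manifest.df.iterrows():
        path = manifest.resolve_path(row)
        if not path.exists():
            raise IOError(f"manifest references missing file: {path}")
        rec = read_wav(path)
        rec.recording_id = str(row["recording_id"])
        rec.class_id = int(row["class_id"])
        if denoised:
            rec = denoise(rec)
        spec = featurize_recording(
            rec, representation, int(row["segment_index"]), resize_cwt
        )
        feats.append(spec.values.astype(np.float32))
        labels.append(rec.class_id)
        rids.append(rec.recording_id)
    if feats:
        features = np.stack(feats)
    else:
        features = np.zeros((0, 0, 0), dtype=np.float32)
    archive = FeatureArchive(
        features=features,
        labels=np.asarray(labels, dtype=np.int64),
        recording_ids=np.asarray(rids, dtype=object) if rids else np.asarray([], dtype=object),
        representation=representation,
    )
    if out_path is not None:
        archive.save(out_path)
    return archive
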