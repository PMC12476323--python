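"""Synthetic vibroacoustic corpus generator.

The study's needle-audio recordings are not publicly deposited, so every
downstream stage (denoising, spectrogram extraction, grouped splitting, CNN
training) is exercised on synthetic recordings with *known* class structure
and *known* injected interference:

* each tissue class is band-filtered Gaussian noise (class-specific frequency
  bands) plus Poisson-timed exponentially decaying transients — the simplest
  structure that makes Mel/CWT representations class-discriminative;
* the laboratory artifact is an additive impulse train with a long period
  (2048 samples by default) and a stable pulse shape, exactly the structure
  the template-subtraction denoiser targets;
* recordings are cut into fixed-length segments, many segments per recording,
  so recording-level leakage is a real hazard for naive splits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .audio import DEFAULT_SAMPLE_RATE, AudioRecording, write_wav

CLASS_NAMES = ("kidney", "liver", "muscle", "rib", "skin")

# Peak amplitude of the clean (pre-interference) signal. Kept well below the
# default interference amplitude so that, after debias/normalization of a
# corrupted recording, spikes sit above 0.9 and the background below 0.5.
_CLEAN_PEAK = 0.5


@dataclass
class TissueClassProfile:
    """Spectral signature of one synthetic tissue class.

    ``band_centers``/``band_gains`` parameterize stationary band-filtered
    noise; ``transient_rate`` (events/s) and ``transient_decay`` (s) add
    decaying tone bursts emulating stick-slip crackle of needle advance.
    """

    class_id: int
    band_centers: tuple[float, ...]
    band_gains: tuple[float, ...]
    transient_rate: float = 4.0
    transient_decay: float = 0.02

    def validate(self, sample_rate: int = DEFAULT_SAMPLE_RATE) -> None:
        nyquist = sample_rate / 2
        if not 0 <= self.class_id <= 4:
            raise ValueError(f"class_id must be in 0..4, got {self.class_id}")
        if len(self.band_centers) != len(self.band_gains):
            raise ValueError("band_centers and band_gains must have equal length")
        if any(c >= nyquist or c <= 0 for c in self.band_centers):
            raise ValueError(f"band centers must lie in (0, {nyquist}) Hz")
        if any(g < 0 for g in self.band_gains) or not any(g > 0 for g in self.band_gains):
            raise ValueError("band gains must be non-negative with at least one positive")


def default_profiles() -> tuple[TissueClassProfile, ...]:
    """Five pairwise-distinct class profiles (kidney, liver, muscle, rib, skin).

    Band centers are disjoint across classes so that a spectral classifier has
    a clean decision boundary to find — the generator's job is to make the
    classification target attainable, not to model real tissue acoustics.
    """
    return (
        TissueClassProfile(0, (350.0, 900.0), (1.0, 0.6)),
        TissueClassProfile(1, (1500.0, 2200.0), (1.0, 0.7)),
        TissueClassProfile(2, (3000.0, 4000.0), (1.0, 0.8)),
        TissueClassProfile(3, (5200.0, 6500.0), (1.0, 0.9)),
        TissueClassProfile(4, (8000.0, 9500.0), (1.0, 0.7)),
    )


@dataclass
class InterferenceSpec:
    """Additive periodic impulsive interference: ``amplitude * pulse`` repeated
    every ``period`` samples starting at ``phase_offset``."""

    period: int = 2048
    pulse_shape: np.ndarray = field(default_factory=lambda: default_pulse_shape())
    amplitude: float = 8.0
    phase_offset: int = 0

    def validate(self) -> None:
        pulse = np.asarray(self.pulse_shape, dtype=np.float64)
        if pulse.ndim != 1 or pulse.size == 0:
            raise ValueError("pulse_shape must be a non-empty 1-D sequence")
        if self.period < 2 * pulse.size:
            raise ValueError(
                f"period ({self.period}) must be at least twice the pulse length ({pulse.size})"
            )
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if not 0 <= self.phase_offset < self.period:
            raise ValueError("phase_offset must lie in [0, period)")

    def onsets(self, n_samples: int) -> np.ndarray:
        """Sample indices at which pulse repetitions start within a signal."""
        return np.arange(self.phase_offset, n_samples, self.period)


def default_pulse_shape(length: int = 64, decay_samples: float = 8.0) -> np.ndarray:
    """Rectangular-windowed damped sinusoid, unit peak at its first sample."""
    t = np.arange(length, dtype=np.float64)
    return np.exp(-t / decay_samples) * np.cos(2 * np.pi * t / 8.0)


@dataclass
class CorpusManifest:
    """Table mapping segment files to recordings and class labels.

    Columns: ``path, recording_id, class_id, segment_index``. ``root`` is the
    directory the (relative) paths are resolved against.
    """

    df: pd.DataFrame
    root: Path | None = None

    def __post_init__(self) -> None:
        required = ["path", "recording_id", "class_id", "segment_index"]
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise ValueError(f"manifest missing columns: {missing}")
        self.validate()

    def validate(self) -> None:
        pairs = self.df[["recording_id", "segment_index"]]
        if pairs.duplicated().any():
            raise ValueError("duplicate (recording_id, segment_index) pairs in manifest")
        classes_per_rec = self.df.groupby("recording_id")["class_id"].nunique()
        bad = classes_per_rec[classes_per_rec > 1]
        if len(bad):
            raise ValueError(f"recording_ids mapped to multiple classes: {list(bad.index)}")

    def __len__(self) -> int:
        return len(self.df)

    def resolve_path(self, row: pd.Series) -> Path:
        p = Path(row["path"])
        if not p.is_absolute() and self.root is not None:
            p = self.root / p
        return p

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "CorpusManifest":
        path = Path(path)
        df = pd.read_csv(path, dtype={"recording_id": str})
        return cls(df=df, root=path.parent)


def generate_recording(
    profile: TissueClassProfile,
    duration_s: float,
    sample_rate: int = DEFAULT_SAMPLE_RATE,
    seed: int | np.random.SeedSequence = 0,
) -> AudioRecording:
    """Generate one clean (interference-free) recording for a tissue class.

    Band-filtered Gaussian noise per profile band plus Poisson-timed decaying
    tone bursts at the band centers; peak amplitude normalized to 0.5.
    Deterministic given ``seed``.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if sample_rate <= 0:
        raise ValueError("sample_rate must be positive")
    profile.validate(sample_rate)
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * sample_rate))
    nyquist = sample_rate / 2

    x = np.zeros(n)
    for fc, gain in zip(profile.band_centers, profile.band_gains):
        if gain == 0:
            continue
        half_bw = max(0.08 * fc, 50.0)
        lo = max(fc - half_bw, 1.0) / nyquist
        hi = min(fc + half_bw, nyquist - 1.0) / nyquist
        sos = sps.butter(4, [lo, hi], btype="bandpass", output="sos")
        band = sps.sosfilt(sos, rng.standard_normal(n))
        rms = np.sqrt(np.mean(band**2))
        if rms > 0:
            band /= rms
        x += gain * band

    base_rms = np.sqrt(np.mean(x**2)) or 1.0
    n_events = rng.poisson(profile.transient_rate * duration_s)
    decay_n = max(int(profile.transient_decay * sample_rate), 1)
    burst_len = 5 * decay_n
    for _ in range(n_events):
        t0 = rng.integers(0, n)
        fc = rng.choice(profile.band_centers)
        amp = base_rms * rng.uniform(1.0, 2.0)
        tt = np.arange(min(burst_len, n - t0))
        burst = amp * np.exp(-tt / decay_n) * np.sin(
            2 * np.pi * fc * tt / sample_rate + rng.uniform(0, 2 * np.pi)
        )
        x[t0 : t0 + tt.size] += burst

    peak = np.max(np.abs(x))
    if peak > 0:
        x *= _CLEAN_PEAK / peak
    return AudioRecording(samples=x, sample_rate=sample_rate, class_id=profile.class_id)


def inject_interference(rec: AudioRecording, spec: InterferenceSpec) -> AudioRecording:
    """Add the periodic impulse train to a recording.

    ``out[t] = rec[t] + amplitude * pulse[(t - phase_offset) mod period]``
    wherever the pulse is defined. The recording must span at least two full
    interference periods (the template estimator needs >= 2 chunks).
    """
    spec.validate()
    n = len(rec)
    if n == 0:
        raise ValueError("recording is empty")
    if spec.period >= n:
        raise ValueError(
            f"period ({spec.period}) must be shorter than the recording ({n} samples); "
            "at least 2 full periods are required downstream"
        )
    pulse = np.asarray(spec.pulse_shape, dtype=np.float64)
    train = np.zeros(n)
    for onset in spec.onsets(n):
        end = min(onset + pulse.size, n)
        train[onset:end] += spec.amplitude * pulse[: end - onset]
    return rec.with_samples(rec.samples + train)


def _split_counts(total: int, parts: int) -> list[int]:
    base, rem = divmod(total, parts)
    return [base + (1 if i < rem else 0) for i in range(parts)]


def generate_corpus(
    class_counts: dict[int, int],
    recordings_per_class: int,
    segment_s: float = 1.0,
    interference: InterferenceSpec | None = None,
    seed: int = 0,
    out_dir: str | Path = "corpus",
    sample_rate: int = DEFAULT_SAMPLE_RATE,
    profiles: tuple[TissueClassProfile, ...] | None = None,
    write_clean: bool = False,
) -> CorpusManifest:
    """Generate a labelled corpus of WAV segments plus a manifest CSV.

    For each class, ``class_counts[class_id]`` segments are cut (non-
    overlapping) from ``recordings_per_class`` recordings; segments from one
    recording share a ``recording_id``. Interference, when given, is injected
    per recording with a seeded random phase. Deterministic given ``seed``.

    With ``write_clean`` the pre-interference signal of every segment is also
    written under ``out_dir/clean/`` (useful as a denoising oracle).
    """
    if recordings_per_class < 1:
        raise ValueError("recordings_per_class must be >= 1")
    for cid, cnt in class_counts.items():
        if cnt <= 0:
            raise ValueError(f"class {cid}: segment count must be positive")
        if recordings_per_class > cnt:
            raise ValueError(
                f"class {cid}: recordings_per_class ({recordings_per_class}) exceeds segment count ({cnt})"
            )
    if profiles is None:
        profiles = default_profiles()
    by_id = {p.class_id: p for p in profiles}
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise IOError(f"cannot create output directory {out_dir}: {exc}") from exc

    seg_len = int(round(segment_s * sample_rate))
    rows = []
    ss = np.random.SeedSequence(seed)
    for cid in sorted(class_counts):
        profile = by_id[cid]
        seg_counts = _split_counts(class_counts[cid], recordings_per_class)
        children = ss.spawn(recordings_per_class)
        for r, (n_segs, child) in enumerate(zip(seg_counts, children)):
            rid = f"rec_c{cid}_{r:03d}"
            rec_seed, phase_seed = child.spawn(2)
            duration = n_segs * segment_s
            clean = generate_recording(profile, duration, sample_rate, seed=rec_seed)
            clean_samples = clean.samples
            if interference is not None and interference.amplitude > 0:
                phase = int(np.random.default_rng(phase_seed).integers(0, interference.period))
                spec = InterferenceSpec(
                    period=interference.period,
                    pulse_shape=np.asarray(interference.pulse_shape, dtype=np.float64),
                    amplitude=interference.amplitude,
                    phase_offset=phase,
                )
                noisy = inject_interference(clean, spec).samples
            else:
                noisy = clean_samples
            for j in range(n_segs):
                seg = noisy[j * seg_len : (j + 1) * seg_len]
                fname = f"{rid}_seg{j:03d}.wav"
                write_wav(out_dir / fname, AudioRecording(seg, sample_rate, rid, cid))
                if write_clean:
                    cseg = clean_samples[j * seg_len : (j + 1) * seg_len]
                    write_wav(out_dir / "clean" / fname, AudioRecording(cseg, sample_rate, rid, cid))
                rows.append(
                    {"path": fname, "recording_id": rid, "class_id": cid, "segment_index": j}
                )
    manifest = CorpusManifest(df=pd.DataFrame(rows), root=out_dir)
    manifest.to_csv(out_dir / "manifest.csv")
    return manifest
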