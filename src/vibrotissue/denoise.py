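"""Removal of periodic impulsive interference by median template subtraction.

Needle-audio recordings are corrupted by an additive impulse train with a
long, stable period (roughly 2048 samples at 22050 Hz) — too impulsive and
too low-rate for frequency-domain filtering. The remedy, borrowed from ECG
artifact processing, is time-domain template subtraction:

1. debias the signal and normalize it to [-1, 1];
2. estimate the interference period T̂ as the dominant mode of distances
   between consecutive upcrossings of a threshold θ, swept over θ ∈ (0.6, 0.9)
   so no single ad-hoc threshold is relied upon — at high thresholds some
   spikes are missed and the modal distance becomes a *multiple* of T̂, which
   the estimator folds back onto the fundamental;
3. estimate one period of the interference as the per-phase *median* over all
   full T̂-sample chunks (the median, unlike the mean, is immune to the
   non-stationary vibroacoustic signal riding on top);
4. subtract the periodic extension of the template from the signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .audio import AudioRecording

logger = logging.getLogger(__name__)


class PeriodEstimationError(RuntimeError):
    """Raised when no threshold yields at least two upcrossings."""


def default_theta_grid(n: int = 31, lo: float = 0.6, hi: float = 0.9) -> np.ndarray:
    """``n`` thresholds evenly spaced strictly inside the open interval."""
    return np.linspace(lo, hi, n + 2)[1:-1]


@dataclass
class PeriodEstimate:
    """Per-threshold modal upcrossing distances and the folded dominant period."""

    thresholds: np.ndarray
    modal_distance_per_threshold: dict[float, int]
    dominant_period: int


@dataclass
class PulseTemplate:
    """One period of the estimated interference (per-phase median over chunks)."""

    values: np.ndarray
    period: int
    chunk_count: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.size != self.period:
            raise ValueError("template length must equal the period")
        if self.chunk_count < 2:
            raise ValueError("template needs at least 2 chunks")


def debias_normalize(rec: AudioRecording) -> AudioRecording:
    """Subtract the sample mean, then scale the peak to 1.

    A constant signal maps to all zeros (documented behaviour, not an error).
    """
    if len(rec) == 0:
        raise ValueError("recording is empty")
    x = rec.samples - rec.samples.mean()
    peak = np.max(np.abs(x))
    if peak > 0:
        x = x / peak
    return rec.with_samples(x)


def upcrossing_indices(samples: np.ndarray, theta: float) -> np.ndarray:
    """Indices ``t`` with ``samples[t-1] <= theta < samples[t]``, ascending."""
    x = np.asarray(samples, dtype=np.float64)
    return np.nonzero((x[:-1] <= theta) & (x[1:] > theta))[0] + 1


def _mode_smallest(values: np.ndarray) -> int:
    """Most frequent value; the smallest wins a tie (biases toward the fundamental)."""
    uniq, counts = np.unique(values, return_counts=True)
    return int(uniq[np.argmax(counts)])  # np.unique sorts ascending; argmax takes first max


def fold_multiples(modal_counts: dict[int, int], tol: int = 1) -> int:
    """Reduce modal distances that are near-multiples of a smaller candidate.

    Each modal value ``m`` votes (with its threshold count) for the smallest
    candidate ``c`` such that ``m ≈ k·c`` for some integer ``k >= 2`` within
    ``tol`` samples, or for itself. The candidate with the most votes wins;
    the smallest wins a tie.
    """
    candidates = sorted(modal_counts)
    votes = dict.fromkeys(candidates, 0)
    for m, cnt in modal_counts.items():
        target = m
        for c in candidates:
            if c >= m:
                break
            k = int(round(m / c))
            if k >= 2 and abs(m - k * c) <= tol:
                target = c
                break
        votes[target] += cnt
    best = max(votes.values())
    return min(c for c, v in votes.items() if v == best)


def estimate_period(
    rec: AudioRecording, theta_grid: np.ndarray | None = None
) -> PeriodEstimate:
    """Estimate the interference period from threshold-upcrossing distances.

    For each threshold θ the mode of consecutive upcrossing distances
    ``T_n = t_n - t_{n-1}`` is recorded; the dominant period is the modal
    value with most per-threshold votes after folding near-multiples.

    Raises
    ------
    PeriodEstimationError
        If fewer than two upcrossings occur at every threshold.
    """
    if theta_grid is None:
        theta_grid = default_theta_grid()
    theta_grid = np.asarray(theta_grid, dtype=np.float64)
    modes: dict[float, int] = {}
    for theta in theta_grid:
        idx = upcrossing_indices(rec.samples, theta)
        if idx.size < 2:
            continue
        modes[float(theta)] = _mode_smallest(np.diff(idx))
    if not modes:
        raise PeriodEstimationError(
            "no threshold in the grid produced two or more upcrossings"
        )
    modal_counts: dict[int, int] = {}
    for m in modes.values():
        modal_counts[m] = modal_counts.get(m, 0) + 1
    dominant = fold_multiples(modal_counts)
    return PeriodEstimate(
        thresholds=theta_grid,
        modal_distance_per_threshold=modes,
        dominant_period=dominant,
    )


def extract_template(rec: AudioRecording, period: int) -> PulseTemplate:
    """Per-phase median over all full ``period``-sample chunks.

    The trailing partial chunk is excluded. Requires at least two full chunks.
    """
    n = len(rec)
    if period < 1:
        raise ValueError("period must be >= 1")
    if n < 2 * period:
        raise ValueError(
            f"recording ({n} samples) must be at least twice the period ({period})"
        )
    n_chunks = n // period
    chunks = rec.samples[: n_chunks * period].reshape(n_chunks, period)
    return PulseTemplate(values=np.median(chunks, axis=0), period=period, chunk_count=n_chunks)


def subtract_template(rec: AudioRecording, template: PulseTemplate) -> AudioRecording:
    """Subtract the periodic extension of the template: ``out[t] = x[t] - p̂[t mod T̂]``.

    The trailing partial period is handled with the template prefix.
    """
    n = len(rec)
    idx = np.arange(n) % template.period
    return rec.with_samples(rec.samples - template.values[idx])


def denoise(
    rec: AudioRecording,
    theta_grid: np.ndarray | None = None,
    period: int | None = None,
) -> AudioRecording:
    """Full denoising chain: normalize → estimate period → median template → subtract.

    ``period`` bypasses estimation when the interference period is known.
    If the period cannot be estimated (or leaves fewer than two full chunks),
    the debiased/normalized signal is returned unchanged with a warning —
    recordings are never dropped, keeping corpus counts stable.
    """
    if len(rec) == 0:
        raise ValueError("recording is empty")
    normed = debias_normalize(rec)
    if period is None:
        try:
            period = estimate_period(normed, theta_grid).dominant_period
        except PeriodEstimationError:
            logger.warning(
                "recording %s: period estimation failed; returning normalized signal",
                rec.recording_id,
            )
            return normed
    if len(normed) < 2 * period:
        logger.warning(
            "recording %s: estimated period %d leaves <2 chunks; returning normalized signal",
            rec.recording_id,
            period,
        )
        return normed
    template = extract_template(normed, period)
    return subtract_template(normed, template)
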