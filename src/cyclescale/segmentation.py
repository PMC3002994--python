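"""Cycle segmentation of pseudoperiodic signals.

A rhythmic signal is cut into consecutive cycles at landmark extrema — local
minima (Rossler-style benchmarks) or local maxima (gait joint angles). A
landmark is a *strict* extremum of its surrounding window of ``min_separation``
samples on each side; raw sample-wise extrema would fragment noisy data into
spurious cycles. By default the window is half the dominant period, estimated
from the periodogram.

Cycles are half-open ``[l_i, l_{i+1})`` so that concatenating them reproduces
the original samples exactly, and the stride-interval series is simply the
landmark spacing divided by the sampling rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from .exceptions import FlatSpectrumError, SegmentationError
from .io import TimeSeries

__all__ = [
    "LandmarkSet",
    "CycleSet",
    "StrideIntervalSeries",
    "detect_landmarks",
    "auto_min_separation",
    "split_cycles",
    "stride_intervals",
]

#: Fisher g-test significance level for the largest periodogram ordinate;
#: above this p-value the spectrum is declared flat (no dominant rhythm)
FLAT_SPECTRUM_ALPHA = 0.01


@dataclass
class LandmarkSet:
    """Ordered landmark sample positions and how they were found."""

    indices: np.ndarray
    mode: str  # "minima" | "maxima"
    min_separation: int

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int64)
        if self.mode not in ("minima", "maxima"):
            raise ValueError(f"mode must be 'minima' or 'maxima', got {self.mode!r}")
        if self.indices.size >= 2 and not (np.diff(self.indices) > 0).all():
            raise ValueError("landmark indices must be strictly increasing")

    def __len__(self) -> int:
        return self.indices.size


@dataclass
class CycleSet:
    """Consecutive cycles cut from a signal, with their landmarks."""

    cycles: list[np.ndarray]
    landmarks: LandmarkSet
    fs: float

    def __len__(self) -> int:
        return len(self.cycles)


@dataclass
class StrideIntervalSeries:
    """Duration of each cycle, in seconds."""

    intervals: np.ndarray

    def __post_init__(self) -> None:
        self.intervals = np.asarray(self.intervals, dtype=np.float64)

    def __len__(self) -> int:
        return self.intervals.size


def auto_min_separation(ts: TimeSeries) -> int:
    """Half the dominant period, in samples.

    The dominant period is taken from the largest periodogram ordinate (zero
    frequency excluded). Dominance is judged by Fisher's g-test: with
    ``g = max(psd) / sum(psd)`` over the ``M`` positive-frequency ordinates,
    the white-noise null gives ``p ~ M (1 - g)^(M - 1)``; a peak with
    ``p >= FLAT_SPECTRUM_ALPHA`` means the spectrum is flat and a
    :class:`FlatSpectrumError` asks for a manual value.
    """
    if len(ts) < 64:
        raise SegmentationError(f"need >= 64 samples to infer a period, got {len(ts)}")
    freqs, psd = signal.periodogram(ts.values, fs=ts.fs, detrend="constant")
    freqs, psd = freqs[1:], psd[1:]
    peak = int(np.argmax(psd))
    g = psd[peak] / psd.sum()
    p_value = min(1.0, psd.size * (1.0 - g) ** (psd.size - 1))
    if p_value >= FLAT_SPECTRUM_ALPHA:
        raise FlatSpectrumError(
            f"no dominant spectral peak (Fisher g-test p = {p_value:.3g}); "
            "pass min_separation explicitly"
        )
    return max(1, round(0.5 * ts.fs / freqs[peak]))


def detect_landmarks(
    ts: TimeSeries,
    mode: str = "minima",
    min_separation: int | str = "auto",
) -> LandmarkSet:
    """Find cycle landmarks: strict windowed extrema of the signal.

    Index ``i`` is a landmark iff ``values[i]`` is strictly more extreme than
    every other sample in ``[i - w, i + w]`` with ``w = min_separation``.
    Leading/trailing positions whose window would run off the signal are
    excluded. Should two candidates ever fall within ``w`` of each other the
    more extreme one is kept, ties broken toward the earlier index (with the
    strict-window rule this cannot arise, but the tie policy is part of the
    contract and keeps the detector deterministic).
    """
    if mode not in ("minima", "maxima"):
        raise ValueError(f"mode must be 'minima' or 'maxima', got {mode!r}")
    w = auto_min_separation(ts) if min_separation == "auto" else int(min_separation)
    if w < 1:
        raise ValueError(f"min_separation must be >= 1, got {w}")
    n = len(ts)
    if n <= 2 * w:
        raise SegmentationError(f"signal length {n} too short for min_separation {w}")
    # Work on the negated signal for maxima so one code path serves both.
    sig = ts.values if mode == "minima" else -ts.values
    win_min = ndimage.minimum_filter(sig, size=2 * w + 1, mode="nearest")
    cand = np.flatnonzero(sig == win_min)
    cand = cand[(cand >= w) & (cand <= n - 1 - w)]
    # Strictness: the window minimum must be attained only once.
    strict = [
        int(i) for i in cand
        if np.count_nonzero(sig[i - w : i + w + 1] == sig[i]) == 1
    ]
    # Greedy min-separation pass; more extreme wins, ties keep the earlier.
    kept: list[int] = []
    for i in strict:
        if kept and i - kept[-1] < w:
            if sig[i] < sig[kept[-1]]:
                kept[-1] = i
        else:
            kept.append(i)
    if len(kept) < 3:
        raise SegmentationError(
            f"too few cycles: found {len(kept)} landmark(s), need >= 3 "
            "(is the signal oscillatory?)"
        )
    return LandmarkSet(indices=np.array(kept, dtype=np.int64), mode=mode, min_separation=w)


def split_cycles(ts: TimeSeries, landmarks: LandmarkSet) -> CycleSet:
    """Cut the signal into half-open cycles ``[l_i, l_{i+1})``.

    Concatenating the cycles reproduces ``ts.values[l_0:l_last]`` exactly.
    """
    idx = landmarks.indices
    if idx.size < 2:
        raise SegmentationError("need >= 2 landmarks to form a cycle")
    if idx[0] < 0 or idx[-1] >= len(ts):
        raise SegmentationError("landmarks out of range for this signal")
    cycles = [ts.values[idx[k] : idx[k + 1]].copy() for k in range(idx.size - 1)]
    short = [k for k, c in enumerate(cycles) if c.size < 3]
    if short:
        raise SegmentationError(f"cycle(s) {short} shorter than 3 samples")
    return CycleSet(cycles=cycles, landmarks=landmarks, fs=ts.fs)


def stride_intervals(landmarks: LandmarkSet, fs: float) -> StrideIntervalSeries:
    """Cycle durations in seconds: ``(l_{k+1} - l_k) / fs``."""
    if len(landmarks) < 2:
        raise SegmentationError("need >= 2 landmarks for stride intervals")
    if not fs > 0:
        raise ValueError(f"fs must be > 0, got {fs}")
    return StrideIntervalSeries(intervals=np.diff(landmarks.indices) / fs)
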