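"""Cycle-scale synchronization between two in-phase oscillatory signals.

Two signals that are strongly phase-synchronized (knee and ankle during
walking, or the x and y components of the same oscillator) defeat phase-based
synchronization indices: the phase index saturates for everyone. The
cycle-scale index sidesteps phase entirely and asks whether the *cycle-to-
cycle variability* of the two signals co-varies.

Dual segmentation: either signal's landmarks are a legitimate set of cut
points, so both schemes are used. Under scheme "x" both signals are cut at
x's landmarks (so cycle ``i`` of x and cycle ``i`` of y span the same time
window), each cycle set is embedded with the Laplacian eigenmap, and the
absolute Pearson correlation ``|corr(C_x, C_y)|`` is recorded; scheme "y" is
symmetric, and ``rho`` is the mean of the two. The absolute value is used
because the eigenvector sign is arbitrary per segmentation; anti-correlated
dynamics therefore look the same as correlated ones and must be judged from
the signed per-scheme values kept in the result.

Baselines: the Poincare index ``|corr(P_x, P_y)|`` (both signals read at x's
landmarks) and the stride-interval correlation (each signal's own landmarks,
truncated to the common length).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .embedding import laplacian_embedding, similarity_matrix
from .exceptions import ConnectivityError, SegmentationError
from .io import TimeSeries
from .segmentation import detect_landmarks, split_cycles, stride_intervals
from .dynamics import poincare_series

__all__ = ["SyncResult", "cycle_sync", "poincare_sync"]


@dataclass
class SyncResult:
    """Dual-segmentation synchronization summary."""

    rho_scheme_x: float  # |corr(C_x, C_y)| with both signals cut at x's landmarks
    rho_scheme_y: float  # same under y's landmarks
    rho: float  # mean of the two schemes
    rho_si: float  # signed corr of the two stride-interval series (baseline)
    n_cycles_scheme_x: int
    n_cycles_scheme_y: int
    corr_scheme_x: float = 0.0  # signed per-scheme correlations, for the record
    corr_scheme_y: float = 0.0


def _check_pair(ts_x: TimeSeries, ts_y: TimeSeries) -> None:
    if len(ts_x) != len(ts_y):
        raise ValueError(f"signals must have equal length, got {len(ts_x)} and {len(ts_y)}")
    if ts_x.fs != ts_y.fs:
        raise ValueError(f"signals must share fs, got {ts_x.fs} and {ts_y.fs}")


def _scheme_corr(
    src: TimeSeries,
    ts_x: TimeSeries,
    ts_y: TimeSeries,
    mode: str,
    min_separation,
    name: str,
) -> tuple[float, int]:
    """Signed corr(C_x, C_y) with both signals cut at ``src``'s landmarks."""
    lm = detect_landmarks(src, mode=mode, min_separation=min_separation)
    cyc_x = split_cycles(ts_x, lm)
    cyc_y = split_cycles(ts_y, lm)
    n = len(cyc_x)
    if n < 10:
        raise SegmentationError(f"scheme {name}: only {n} cycles, need >= 10")
    si = stride_intervals(lm, src.fs)
    try:
        c_x = laplacian_embedding(similarity_matrix(cyc_x), si)
        c_y = laplacian_embedding(similarity_matrix(cyc_y), si)
    except ConnectivityError as exc:
        raise ConnectivityError(f"scheme {name}: {exc}") from exc
    r = float(np.corrcoef(c_x.values, c_y.values)[0, 1])
    return r, n


def cycle_sync(
    ts_x: TimeSeries,
    ts_y: TimeSeries,
    mode: str = "maxima",
    min_separation="auto",
) -> SyncResult:
    """Dual-segmentation cycle-scale synchronization index ``rho``.

    See the module docstring for the scheme definitions. ``rho`` is symmetric
    in the two signals and invariant under positive affine rescaling of
    either.
    """
    _check_pair(ts_x, ts_y)
    r_x, n_x = _scheme_corr(ts_x, ts_x, ts_y, mode, min_separation, "x")
    r_y, n_y = _scheme_corr(ts_y, ts_x, ts_y, mode, min_separation, "y")
    lm_x = detect_landmarks(ts_x, mode=mode, min_separation=min_separation)
    lm_y = detect_landmarks(ts_y, mode=mode, min_separation=min_separation)
    si_x = stride_intervals(lm_x, ts_x.fs).intervals
    si_y = stride_intervals(lm_y, ts_y.fs).intervals
    m = min(si_x.size, si_y.size)
    if m >= 2 and np.ptp(si_x[:m]) > 0 and np.ptp(si_y[:m]) > 0:
        rho_si = float(np.corrcoef(si_x[:m], si_y[:m])[0, 1])
    else:
        rho_si = float("nan")
    return SyncResult(
        rho_scheme_x=abs(r_x),
        rho_scheme_y=abs(r_y),
        rho=(abs(r_x) + abs(r_y)) / 2.0,
        rho_si=rho_si,
        n_cycles_scheme_x=n_x,
        n_cycles_scheme_y=n_y,
        corr_scheme_x=r_x,
        corr_scheme_y=r_y,
    )


def poincare_sync(
    ts_x: TimeSeries,
    ts_y: TimeSeries,
    mode: str = "minima",
    min_separation="auto",
) -> float:
    """``|corr(P_x, P_y)|`` with both signals read at x's landmark indices."""
    _check_pair(ts_x, ts_y)
    lm = detect_landmarks(ts_x, mode=mode, min_separation=min_separation)
    if len(lm) - 1 < 10:
        raise SegmentationError(f"only {len(lm) - 1} cycles, need >= 10")
    p_x = poincare_series(ts_x, lm).values
    p_y = poincare_series(ts_y, lm).values
    return abs(float(np.corrcoef(p_x, p_y)[0, 1]))
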