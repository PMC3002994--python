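"""Per-cycle dynamics: return maps, Poincare baseline, and spectral exponents.

Two classical reductions of a pseudoperiodic signal to one point per cycle
are compared with the cycle series ``C``:

* **Poincare section** ``P(k)`` — the signal value at each landmark extremum,
  the textbook per-cycle reduction. Because it reads a single sample it is far
  more exposed to measurement noise than ``C``, which pools an entire cycle.
* **Quadratic return map** — regress ``s_{k+1}`` on ``s_k`` with
  ``y = a x^2 + b x + c``. For a chaotic oscillator with a unimodal first
  return map both ``C`` and ``P`` trace a clear parabola; the mean squared
  residual ``sigma^2 = RSS / (N - 1)`` (on z-scored series, so the arbitrary
  eigenvector scale drops out) quantifies how much noise has blurred it.
* **Spectral exponent** ``beta`` — the raw periodogram of a cycle series is
  fitted by ordinary least squares in log10-log10 coordinates; ``beta`` is
  minus the slope, i.e. PSD ~ 1/f^beta. ``beta ~ 0`` is white-noise-like,
  ``beta ~ 1`` indicates long-range correlation between cycles far apart.
  For gait the effective sampling interval of a cycle series is the mean
  stride interval in seconds; for unitless benchmarks it is one cycle.

The periodogram is deliberately raw — no Welch averaging, no taper — with the
zero-frequency ordinate excluded and, by default, the full positive band
fitted; a band override is exposed.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .exceptions import DegenerateFitError, FitError
from .embedding import CycleSeries
from .io import TimeSeries
from .segmentation import LandmarkSet

__all__ = [
    "PoincareSeries",
    "QuadraticFit",
    "SpectralFit",
    "poincare_series",
    "quadratic_return_fit",
    "noise_robustness_ratio",
    "periodogram",
    "spectral_slope",
    "classify_lrc",
]

#: default spectral-exponent threshold separating long-range-correlated from
#: white-noise-like cycle series (package convention, exposed everywhere)
LRC_THRESHOLD = 0.3


@dataclass
class PoincareSeries:
    """Signal values sampled at the landmark extrema (one per landmark)."""

    values: np.ndarray

    def __len__(self) -> int:
        return self.values.size


@dataclass
class QuadraticFit:
    """OLS fit of ``y = a x^2 + b x + c`` to a return map."""

    a: float
    b: float
    c: float
    sigma2: float  # RSS / (N - 1), N = number of return pairs
    r2: float
    standardized: bool


@dataclass
class SpectralFit:
    """Raw periodogram and (optionally) its log-log power-law fit."""

    frequencies: np.ndarray  # positive, cycles per unit time
    psd: np.ndarray
    delta_t: float  # effective sampling interval, seconds
    beta: float | None = None  # PSD ~ 1/f^beta
    intercept: float | None = None  # log10 PSD at log10 f = 0
    fit_band: tuple[float, float] | None = None


def _series_values(series) -> np.ndarray:
    if isinstance(series, (CycleSeries, PoincareSeries)):
        return np.asarray(series.values, dtype=np.float64)
    return np.asarray(series, dtype=np.float64)


def poincare_series(ts: TimeSeries, landmarks: LandmarkSet) -> PoincareSeries:
    """``P(k) = ts.values[l_k]``: the signal read at each landmark."""
    idx = landmarks.indices
    if idx.size and (idx[0] < 0 or idx[-1] >= len(ts)):
        raise ValueError("landmarks out of range for this signal")
    return PoincareSeries(values=ts.values[idx].copy())


def quadratic_return_fit(series, standardize: bool = True) -> QuadraticFit:
    """Least-squares quadratic fit of the first return map.

    With ``standardize`` (default) the series is z-scored first, making
    ``sigma2`` comparable across series with arbitrary scales (eigenvector
    scaling is arbitrary). ``sigma2 = RSS / (N - 1)`` over the ``N`` return
    pairs.
    """
    s = _series_values(series)
    if s.size < 10:
        raise ValueError(f"need length >= 10, got {s.size}")
    if np.ptp(s) == 0:
        raise DegenerateFitError("constant series: quadratic return fit is singular")
    if standardize:
        s = (s - s.mean()) / s.std()
    x, y = s[:-1], s[1:]
    with warnings.catch_warnings():
        warnings.simplefilter("error", np.exceptions.RankWarning)
        try:
            coeffs = np.polyfit(x, y, 2)
        except np.exceptions.RankWarning as exc:
            raise DegenerateFitError(f"singular quadratic fit: {exc}") from exc
    resid = y - np.polyval(coeffs, x)
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    n_pairs = x.size
    return QuadraticFit(
        a=float(coeffs[0]),
        b=float(coeffs[1]),
        c=float(coeffs[2]),
        sigma2=rss / (n_pairs - 1),
        r2=1.0 - rss / tss if tss > 0 else 0.0,
        standardized=standardize,
    )


def noise_robustness_ratio(C, P) -> float:
    """``sigma2(P) / sigma2(C)`` of the z-scored quadratic return fits.

    Values above 1 mean the Poincare section is more blurred by noise than the
    cycle series is — the advantage of pooling whole cycles.
    """
    c = _series_values(C)
    p = _series_values(P)
    if c.size < 10 or p.size < 10:
        raise ValueError("both series need length >= 10")
    fit_c = quadratic_return_fit(c, standardize=True)
    fit_p = quadratic_return_fit(p, standardize=True)
    return fit_p.sigma2 / fit_c.sigma2


def periodogram(series, delta_t: float = 1.0) -> SpectralFit:
    """Raw (boxcar, mean-removed) periodogram at positive frequencies.

    Density scaling: ``sum(psd) * delta_f`` equals the series variance
    (Parseval). The zero-frequency ordinate is dropped.
    """
    s = _series_values(series)
    if s.size < 16:
        raise ValueError(f"need length >= 16, got {s.size}")
    if not delta_t > 0:
        raise ValueError(f"delta_t must be > 0, got {delta_t}")
    freqs, psd = sps.periodogram(
        s, fs=1.0 / delta_t, window="boxcar", detrend="constant", scaling="density"
    )
    return SpectralFit(frequencies=freqs[1:], psd=psd[1:], delta_t=delta_t)


def spectral_slope(
    fit: SpectralFit, f_band: tuple[float, float] | None = None
) -> SpectralFit:
    """Fit ``log10 PSD = intercept - beta * log10 f`` over ``f_band`` by OLS.

    ``f_band`` defaults to the full positive band. Zero-power ordinates cannot
    be log-transformed and are dropped with a warning; at least 8 usable
    ordinates are required.
    """
    f, p = fit.frequencies, fit.psd
    if f_band is not None:
        lo, hi = f_band
        keep = (f >= lo) & (f <= hi)
        f, p = f[keep], p[keep]
    else:
        lo, hi = (float(f[0]), float(f[-1])) if f.size else (0.0, 0.0)
    pos = p > 0
    if not pos.all():
        warnings.warn(
            f"dropping {int((~pos).sum())} zero-power ordinate(s) from the log-log fit",
            stacklevel=2,
        )
        f, p = f[pos], p[pos]
    if f.size < 8:
        raise FitError(f"only {f.size} usable ordinates in band; need >= 8")
    slope, intercept = np.polyfit(np.log10(f), np.log10(p), 1)
    return dataclasses.replace(
        fit, beta=float(-slope), intercept=float(intercept), fit_band=(float(lo), float(hi))
    )


def classify_lrc(beta: float, threshold: float = LRC_THRESHOLD) -> str:
    """Label a spectral exponent: boundary-inclusive at ``threshold``."""
    if not np.isfinite(beta):
        raise ValueError(f"beta must be finite, got {beta}")
    return "long-range-correlated" if beta >= threshold else "white-noise-like"
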