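"""Synthetic benchmark generators with retained ground truth.

Three families of inputs exercise the whole pipeline:

* **Noisy Rossler trajectories** — the chaotic Rossler system
  ``dx/dt = -y - z``, ``dy/dt = x + a y``, ``dz/dt = b + z (x - c)`` with the
  standard chaotic parameters a = b = 0.2, c = 5.7, integrated with fixed-step
  RK4. Dynamical noise is injected after each step (Euler-Maruyama-style
  additive Gaussian perturbation of the state) with SD expressed as a percent
  of each state's noise-free SD, so "percent noise" is scale-free; measurement
  noise is added to the returned series only, as a percent of the signal SD.
  The x component is a canonical pseudoperiodic signal whose cycle series has
  a clean quadratic return map.
* **Power-law cycle sequences** — spectral synthesis: Fourier amplitudes
  proportional to ``f^(-beta/2)`` with iid uniform phases, inverse transform,
  z-scored. The expected periodogram slope is exactly ``-beta``; these are the
  ground truth for spectral-exponent recovery.
* **Gait-like bivariate pairs** — two signals built from the same cycle
  template (a base harmonic carrying a sharp landmark peak at each cycle
  onset, plus a second-harmonic component that makes cycles non-phase-
  coherent). The second component's amplitude is modulated cycle-by-cycle by
  latent power-law sequences ``h`` and ``h' = lam*h + sqrt(1-lam^2)*eps``, so
  the cross-signal cycle coupling is ``lam`` by construction while the two
  signals stay perfectly in phase (shared cycle onsets and periods), mirroring
  knee/ankle traces. Defaults emulate overground walking: 66.7 Hz sampling,
  ~1.1 s stride, 2% period jitter. The modulation enters a component that
  vanishes (with zero slope) at the cycle onset, so landmark detection and the
  stride-interval series are not perturbed by amplitude variation.

All generators are pure functions of their config + seed.
"""

from __future__ import annotations

import functools
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from numba import njit

from .exceptions import IntegrationError
from .io import TimeSeries

__all__ = [
    "RosslerConfig",
    "GaitSimConfig",
    "simulate_rossler",
    "synth_lrc_sequence",
    "simulate_gait_pair",
    "simulate_cohort",
]

#: fractional amplitude-modulation depth of the gait template's second
#: component; deep enough for an informative cycle series, shallow enough to
#: keep the similarity graph connected
GAIT_MOD_DEPTH = 0.2
#: base amplitude of the modulated template component
GAIT_MOD_BASE = 0.4


# ---------------------------------------------------------------------------
# Rossler system
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RosslerConfig:
    """Configuration of the noisy Rossler benchmark.

    Noise percentages are relative: ``dyn_noise_pct`` scales each state's
    noise-free SD (estimated from a noise-free pilot run with the same
    config), ``meas_noise_pct`` scales the SD of each returned component.
    The default (a, b, c) lie in the chaotic regime.
    """

    a: float = 0.2
    b: float = 0.2
    c: float = 5.7
    dt: float = 0.01
    n_samples: int = 200_000
    transient_samples: int = 10_000
    dyn_noise_pct: float = 1.0
    meas_noise_pct: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise ValueError(f"dt must be > 0, got {self.dt}")
        if self.dyn_noise_pct < 0 or self.meas_noise_pct < 0:
            raise ValueError("noise percentages must be >= 0")
        if self.n_samples < 2 or self.transient_samples < 0:
            raise ValueError("need n_samples >= 2 and transient_samples >= 0")


@njit(cache=True)
def _rk4_rossler(n, dt, a, b, c, x0, y0, z0, noise):  # pragma: no cover
    """Fixed-step RK4 with post-step additive noise; returns (states, bad_idx)."""
    out = np.empty((n, 3))
    x, y, z = x0, y0, z0
    for i in range(n):
        k1x = -y - z
        k1y = x + a * y
        k1z = b + z * (x - c)
        x2 = x + 0.5 * dt * k1x
        y2 = y + 0.5 * dt * k1y
        z2 = z + 0.5 * dt * k1z
        k2x = -y2 - z2
        k2y = x2 + a * y2
        k2z = b + z2 * (x2 - c)
        x3 = x + 0.5 * dt * k2x
        y3 = y + 0.5 * dt * k2y
        z3 = z + 0.5 * dt * k2z
        k3x = -y3 - z3
        k3y = x3 + a * y3
        k3z = b + z3 * (x3 - c)
        x4 = x + dt * k3x
        y4 = y + dt * k3y
        z4 = z + dt * k3z
        k4x = -y4 - z4
        k4y = x4 + a * y4
        k4z = b + z4 * (x4 - c)
        x += dt / 6.0 * (k1x + 2.0 * k2x + 2.0 * k3x + k4x) + noise[i, 0]
        y += dt / 6.0 * (k1y + 2.0 * k2y + 2.0 * k3y + k4y) + noise[i, 1]
        z += dt / 6.0 * (k1z + 2.0 * k2z + 2.0 * k3z + k4z) + noise[i, 2]
        if abs(x) > 1e6 or abs(y) > 1e6 or abs(z) > 1e6:
            return out, i
        out[i, 0] = x
        out[i, 1] = y
        out[i, 2] = z
    return out, -1


_INITIAL_STATE = (1.0, 1.0, 1.0)


@functools.lru_cache(maxsize=16)
def _noise_free_state_sds(
    a: float, b: float, c: float, dt: float, n_samples: int, transient: int
) -> tuple[float, float, float]:
    """Per-state SDs of the noise-free trajectory (pilot run, cached)."""
    n_total = transient + n_samples
    zeros = np.zeros((n_total, 3))
    states, bad = _rk4_rossler(n_total, dt, a, b, c, *_INITIAL_STATE, zeros)
    if bad >= 0:
        raise IntegrationError(
            f"noise-free Rossler pilot diverged at step {bad}; try a smaller dt"
        )
    sds = states[transient:].std(axis=0)
    return (float(sds[0]), float(sds[1]), float(sds[2]))


def simulate_rossler(config: RosslerConfig) -> tuple[TimeSeries, TimeSeries, TimeSeries]:
    """Integrate the (noisy) Rossler system; returns the x, y, z components.

    Sampling rate of the returned series is ``1/dt``. Bit-reproducible from
    the config (the same seed always yields the same output; with
    ``meas_noise_pct`` varied and everything else fixed, the underlying states
    are identical).
    """
    n_total = config.transient_samples + config.n_samples
    rng = np.random.default_rng(config.seed)
    if config.dyn_noise_pct > 0:
        sds = _noise_free_state_sds(
            config.a, config.b, config.c, config.dt,
            config.n_samples, config.transient_samples,
        )
        # Euler-Maruyama scaling: the per-step perturbation SD carries a
        # sqrt(dt) factor so that "percent dynamical noise" means the noise
        # accumulated over one unit of model time, independent of the step.
        scale = np.asarray(sds) * (config.dyn_noise_pct / 100.0) * np.sqrt(config.dt)
        noise = rng.standard_normal((n_total, 3)) * scale
    else:
        noise = np.zeros((n_total, 3))
    states, bad = _rk4_rossler(
        n_total, config.dt, config.a, config.b, config.c, *_INITIAL_STATE, noise
    )
    if bad >= 0:
        raise IntegrationError(f"Rossler integration diverged at step {bad}; try a smaller dt")
    states = states[config.transient_samples :]
    out = []
    fs = 1.0 / config.dt
    for k, name in enumerate("xyz"):
        series = states[:, k]
        if config.meas_noise_pct > 0:
            sd = series.std() * (config.meas_noise_pct / 100.0)
            series = series + rng.standard_normal(series.size) * sd
        out.append(TimeSeries(values=series, fs=fs, label=f"rossler-{name}"))
    return out[0], out[1], out[2]


# ---------------------------------------------------------------------------
# power-law (1/f^beta) cycle sequences
# ---------------------------------------------------------------------------

def synth_lrc_sequence(n: int, beta: float, seed: int | np.random.Generator = 0) -> np.ndarray:
    """Spectral synthesis of a unit-variance sequence with PSD ~ 1/f^beta.

    Fourier amplitudes proportional to ``f^(-beta/2)``, iid uniform phases
    (random sign at the Nyquist bin), inverse transform, z-scored.
    """
    if n < 16:
        raise ValueError(f"need n >= 16, got {n}")
    if beta < 0:
        raise ValueError(f"beta must be >= 0, got {beta}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_half = n // 2
    k = np.arange(1, n_half + 1, dtype=np.float64)
    amps = k ** (-beta / 2.0)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=n_half)
    coeffs = np.zeros(n_half + 1, dtype=np.complex128)
    coeffs[1:] = amps * np.exp(1j * phases)
    if n % 2 == 0:
        coeffs[-1] = amps[-1] * (1.0 if phases[-1] < np.pi else -1.0)
    x = np.fft.irfft(coeffs, n)
    return (x - x.mean()) / x.std()


# ---------------------------------------------------------------------------
# gait-like bivariate signals
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GaitSimConfig:
    """Configuration of the bivariate gait-like generator.

    ``beta_target`` is the spectral exponent of the latent cycle-amplitude
    sequence; ``coupling`` is the cross-signal correlation of the two latent
    sequences (0 = independent, 1 = identical). Defaults emulate overground
    walking recorded at 66.7 Hz with a ~1.1 s stride and mild period jitter.
    """

    n_cycles: int = 256
    base_period: float = 1.1  # seconds
    jitter_sd: float = 0.02  # fractional SD of cycle periods
    fs: float = 66.7
    beta_target: float = 1.0
    coupling: float = 0.8
    template: str = "two-harmonic"
    meas_noise_pct: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.coupling <= 1.0:
            raise ValueError(f"coupling must be in [0, 1], got {self.coupling}")
        if self.beta_target < 0:
            raise ValueError(f"beta_target must be >= 0, got {self.beta_target}")
        if self.n_cycles < 16:
            raise ValueError(f"need n_cycles >= 16, got {self.n_cycles}")
        if self.template not in _TEMPLATES:
            raise ValueError(f"unknown template {self.template!r}; have {list(_TEMPLATES)}")


def _two_harmonic(phi: np.ndarray, mod_amp: float) -> np.ndarray:
    """Base harmonic with a peak at phi = 0 plus a modulated second component.

    The modulated component ``(1 - cos 2*pi*phi) * cos(4*pi*phi + 1)``
    vanishes with zero slope at the cycle onset, so the landmark peak height
    and position are independent of the modulation amplitude.
    """
    return np.cos(2.0 * np.pi * phi) + mod_amp * (1.0 - np.cos(2.0 * np.pi * phi)) * np.cos(
        4.0 * np.pi * phi + 1.0
    )


_TEMPLATES = {"two-harmonic": _two_harmonic}


def _gait_signal(
    template, n_per_cycle: np.ndarray, latent: np.ndarray, n_lead: int, n_base: int
) -> np.ndarray:
    """Concatenate lead-in, modulated cycles, and lead-out."""
    factors = 1.0 + GAIT_MOD_DEPTH * latent
    if (factors <= 0).any():
        warnings.warn(
            "cycle amplitude factor <= 0; clipping at 0.1", stacklevel=3
        )
        factors = np.maximum(factors, 0.1)
    lead_in = template((np.arange(n_lead) + n_base - n_lead) / n_base, GAIT_MOD_BASE)
    lead_out = template(np.arange(n_lead) / n_base, GAIT_MOD_BASE)
    parts = [lead_in]
    for n_k, f_k in zip(n_per_cycle, factors):
        phi = np.arange(n_k) / n_k
        parts.append(template(phi, GAIT_MOD_BASE * f_k))
    parts.append(lead_out)
    return np.concatenate(parts)


def simulate_gait_pair(
    config: GaitSimConfig,
) -> tuple[TimeSeries, TimeSeries, dict]:
    """Generate an in-phase gait-like signal pair plus its ground truth.

    The two signals share cycle onsets and periods (perfectly in phase); their
    latent amplitude sequences ``h`` and ``h' = lam*h + sqrt(1-lam^2)*eps``
    have cross-correlation ``coupling`` in expectation. The ground-truth dict
    holds ``h``, ``h_prime``, the cycle ``periods`` (seconds, as realized on
    the sample grid) and the ``onsets`` (sample index of each cycle boundary,
    one per cycle plus the final boundary).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_cycles
    lam = config.coupling
    h = synth_lrc_sequence(n, config.beta_target, rng)
    eps = synth_lrc_sequence(n, config.beta_target, rng)
    h_prime = lam * h + np.sqrt(1.0 - lam * lam) * eps
    periods = config.base_period * (1.0 + config.jitter_sd * rng.standard_normal(n))
    periods = np.maximum(periods, 0.5 * config.base_period)
    n_per_cycle = np.maximum(np.rint(periods * config.fs).astype(np.int64), 8)
    n_base = max(int(round(config.base_period * config.fs)), 8)
    n_lead = int(np.ceil(0.6 * n_base))
    template = _TEMPLATES[config.template]
    sig_x = _gait_signal(template, n_per_cycle, h, n_lead, n_base)
    sig_y = _gait_signal(template, n_per_cycle, h_prime, n_lead, n_base)
    if config.meas_noise_pct > 0:
        pct = config.meas_noise_pct / 100.0
        sig_x = sig_x + rng.standard_normal(sig_x.size) * (pct * sig_x.std())
        sig_y = sig_y + rng.standard_normal(sig_y.size) * (pct * sig_y.std())
    onsets = n_lead + np.concatenate(([0], np.cumsum(n_per_cycle)))
    truth = {
        "h": h,
        "h_prime": h_prime,
        "periods": n_per_cycle / config.fs,
        "onsets": onsets,
        "config": asdict(config),
    }
    ts_x = TimeSeries(values=sig_x, fs=config.fs, label="gait-x")
    ts_y = TimeSeries(values=sig_y, fs=config.fs, label="gait-y")
    return ts_x, ts_y, truth


# ---------------------------------------------------------------------------
# two-group cohorts
# ---------------------------------------------------------------------------

#: group presets: healthy-control-like (long-range-correlated, strongly
#: coupled) vs neuropathic-like (white-noise-like, weakly coupled)
DEFAULT_GROUP_PARAMS = {
    "CO": {"beta_target": 1.0, "coupling": 0.8},
    "NP": {"beta_target": 0.0, "coupling": 0.1},
}


@dataclass
class CohortSubject:
    """One simulated subject: a labelled gait pair with its ground truth."""

    group: str
    subject: int
    ts_x: TimeSeries
    ts_y: TimeSeries
    truth: dict = field(repr=False)


def simulate_cohort(
    n_subjects_per_group: int,
    group_params: dict[str, dict] | None = None,
    seed: int = 0,
    base_config: GaitSimConfig | None = None,
) -> list[CohortSubject]:
    """Simulate a labelled two-group cohort of independent gait pairs.

    ``group_params`` maps group label -> overrides of :class:`GaitSimConfig`
    fields (defaults: a CO-like and an NP-like group). Subjects are
    independent; the whole cohort is reproducible from ``seed``.
    """
    if n_subjects_per_group < 0:
        raise ValueError("n_subjects_per_group must be >= 0")
    params = DEFAULT_GROUP_PARAMS if group_params is None else group_params
    base = asdict(base_config) if base_config is not None else asdict(GaitSimConfig())
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(max(1, n_subjects_per_group * len(params))) & 0x7FFFFFFF
    subjects: list[CohortSubject] = []
    i = 0
    for group, overrides in params.items():
        for k in range(n_subjects_per_group):
            cfg_dict = dict(base)
            cfg_dict.update(overrides)
            cfg_dict["seed"] = int(child_seeds[i])
            cfg = GaitSimConfig(**cfg_dict)
            ts_x, ts_y, truth = simulate_gait_pair(cfg)
            subjects.append(CohortSubject(group=group, subject=k, ts_x=ts_x, ts_y=ts_y, truth=truth))
            i += 1
    return subjects
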