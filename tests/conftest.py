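"""Shared fixtures: expensive simulations are computed once per session."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from cyclescale import (
    RosslerConfig,
    TimeSeries,
    detect_landmarks,
    laplacian_embedding,
    noise_robustness_ratio,
    poincare_series,
    similarity_matrix,
    simulate_rossler,
    split_cycles,
    stride_intervals,
)
from cyclescale.synchronization import cycle_sync, poincare_sync

#: seeds for the noisy-Rossler replicate experiments
NOISY_SEEDS = range(20)


@dataclass
class RosslerPipeline:
    ts: TimeSeries
    landmarks: object
    cycles: object
    si: object
    W: object
    C: object
    P: object


@pytest.fixture(scope="session")
def rossler_clean():
    """Noise-free Rossler x/y/z, ~200 x-cycles (deterministic)."""
    cfg = RosslerConfig(n_samples=120_000, dyn_noise_pct=0.0, meas_noise_pct=0.0, seed=0)
    return simulate_rossler(cfg)


@pytest.fixture(scope="session")
def rossler_clean_pipeline(rossler_clean) -> RosslerPipeline:
    """Full segmentation + embedding of the noise-free Rossler x component."""
    x, _, _ = rossler_clean
    lm = detect_landmarks(x, mode="minima")
    cycles = split_cycles(x, lm)
    si = stride_intervals(lm, x.fs)
    W = similarity_matrix(cycles)
    C = laplacian_embedding(W, si)
    P = poincare_series(x, lm)
    return RosslerPipeline(ts=x, landmarks=lm, cycles=cycles, si=si, W=W, C=C, P=P)


@pytest.fixture(scope="session")
def noisy_rossler_stats():
    """Per-seed statistics of the noisy Rossler benchmark (default noise).

    For each seed: the sigma^2 ratio of the Poincare vs cycle-series return
    fits, and the cycle-scale vs Poincare synchronization indices for (x, y).
    """
    stats = []
    for seed in NOISY_SEEDS:
        cfg = RosslerConfig(n_samples=75_000, seed=seed)  # defaults: 1% dyn, 5% meas
        x, y, _ = simulate_rossler(cfg)
        lm = detect_landmarks(x, mode="minima")
        cycles = split_cycles(x, lm)
        si = stride_intervals(lm, x.fs)
        C = laplacian_embedding(similarity_matrix(cycles), si)
        P = poincare_series(x, lm)
        stats.append(
            {
                "seed": seed,
                "n_cycles": len(cycles),
                "sigma2_ratio": noise_robustness_ratio(C, P),
                "rho_cycle": cycle_sync(x, y, mode="minima").rho,
                "rho_poincare": poincare_sync(x, y, mode="minima"),
            }
        )
    return stats


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
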