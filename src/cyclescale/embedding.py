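"""Cycle-scale dimensionality reduction.

Each cycle of a pseudoperiodic signal is a high-dimensional vector (one entry
per sample). Because consecutive cycles are near-duplicates of a common
waveform, the set of cycles lies close to a low-dimensional manifold, and the
interesting cycle-to-cycle variability can be captured by a *single scalar per
cycle* ``C(i)``.

Two reductions are provided:

* **Laplacian eigenmap** — pairwise similarity ``W_ij`` is the shift-maximized
  Pearson correlation between cycles ``i`` and ``j`` (the shorter vector slides
  along the longer one and the best-aligned correlation is kept). With degree
  matrix ``D_ii = sum_j W_ij`` and graph Laplacian ``L = D - W``, the embedding
  solves the generalized eigenproblem ``L v = lambda D v``. The smallest
  eigenvalue is 0 with a constant eigenvector (degenerate); the eigenvector of
  the *second* smallest eigenvalue, normalized to ``v^T D v = 1``, is the cycle
  series ``C``.
* **Classical MDS** — pairwise distance is the shift-minimized RMS difference;
  double-center ``-D^2/2`` and project on the top eigenvector scaled by the
  square root of its eigenvalue.

Negative correlations are clamped to zero by default: ``L = D - W`` with
negative weights loses positive-semidefiniteness and with it the guaranteed
zero eigenvalue. The raw (unclamped) matrix is kept for inspection. The graph
is dense — every pair of cycles contributes — with zero diagonal.

Eigenvectors are sign-ambiguous, so ``C`` is oriented by a fixed convention:
positive correlation with the stride-interval series when one is supplied and
informative, otherwise nonnegative skewness, otherwise a nonnegative leading
element.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy import linalg, sparse, stats

from .exceptions import ConnectivityError, DegenerateGeometryError, IsolatedCycleError
from .segmentation import CycleSet, StrideIntervalSeries

__all__ = [
    "SimilarityMatrix",
    "DistanceMatrix",
    "CycleSeries",
    "cycle_similarity",
    "cycle_distance",
    "similarity_matrix",
    "distance_matrix",
    "laplacian_embedding",
    "mds_embedding",
]

#: relative variance below which an alignment window counts as constant
_VAR_REL_TOL = 1e-12
#: relative eigenvalue tolerance for the zero mode / connectivity test
ZERO_EIG_TOL = 1e-8


@dataclass
class SimilarityMatrix:
    """Symmetric matrix of shift-maximized cycle correlations.

    ``W`` feeds the graph Laplacian (clamped to [0, 1] unless ``clamped`` is
    false); ``raw`` keeps the unclamped correlations in [-1, 1].
    """

    W: np.ndarray
    n: int
    clamped: bool
    raw: np.ndarray | None = None


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative matrix of shift-minimized RMS cycle distances."""

    D: np.ndarray
    n: int


@dataclass
class CycleSeries:
    """The 1-D cycle-scale representation ``C(i)``, one scalar per cycle."""

    values: np.ndarray
    method: str  # "laplacian" | "mds"
    eigenvalues: np.ndarray | None = None  # ascending; laplacian only
    sign_rule: str = ""

    def __len__(self) -> int:
        return self.values.size


# ---------------------------------------------------------------------------
# numba kernels: pairwise alignment over all offsets
# ---------------------------------------------------------------------------

@njit(cache=True)
def _max_shift_corr(a, b):  # pragma: no cover - exercised via wrappers
    """Max Pearson r between short vector ``a`` and any aligned window of ``b``.

    Returns (r, valid); valid is False when every offset had a constant window.
    """
    m = a.shape[0]
    n = b.shape[0]
    ma = 0.0
    for k in range(m):
        ma += a[k]
    ma /= m
    va = 0.0
    msq_a = 0.0
    for k in range(m):
        d = a[k] - ma
        va += d * d
        msq_a += a[k] * a[k]
    a_const = va <= _VAR_REL_TOL * max(msq_a, 1e-300)
    best = -2.0
    valid = False
    for s in range(n - m + 1):
        mb = 0.0
        for k in range(m):
            mb += b[s + k]
        mb /= m
        vb = 0.0
        msq_b = 0.0
        cov = 0.0
        for k in range(m):
            db = b[s + k] - mb
            vb += db * db
            msq_b += b[s + k] * b[s + k]
            cov += (a[k] - ma) * db
        if a_const or vb <= _VAR_REL_TOL * max(msq_b, 1e-300):
            continue
        r = cov / np.sqrt(va * vb)
        if r > 1.0:
            r = 1.0
        elif r < -1.0:
            r = -1.0
        valid = True
        if r > best:
            best = r
    return best, valid


@njit(cache=True)
def _min_shift_rmsd(a, b):  # pragma: no cover - exercised via wrappers
    """Min over offsets of the RMS difference between ``a`` and windows of ``b``."""
    m = a.shape[0]
    n = b.shape[0]
    best = np.inf
    for s in range(n - m + 1):
        acc = 0.0
        for k in range(m):
            d = a[k] - b[s + k]
            acc += d * d
        if acc < best:
            best = acc
    return np.sqrt(best / m)


@njit(cache=True)
def _pairwise_kernel(flat, starts, lengths, want_corr):  # pragma: no cover
    """All-pairs similarity (want_corr) or distance matrix over packed cycles."""
    n = lengths.shape[0]
    out = np.zeros((n, n))
    n_degenerate = 0
    for i in range(n):
        for j in range(i + 1, n):
            ci = flat[starts[i] : starts[i] + lengths[i]]
            cj = flat[starts[j] : starts[j] + lengths[j]]
            if lengths[i] <= lengths[j]:
                a, b = ci, cj
            else:
                a, b = cj, ci
            if want_corr:
                r, valid = _max_shift_corr(a, b)
                if not valid:
                    r = 0.0
                    n_degenerate += 1
                out[i, j] = r
                out[j, i] = r
            else:
                d = _min_shift_rmsd(a, b)
                out[i, j] = d
                out[j, i] = d
    return out, n_degenerate


def _pack(cycles: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    lengths = np.array([len(c) for c in cycles], dtype=np.int64)
    starts = np.concatenate(([0], np.cumsum(lengths)[:-1]))
    flat = np.concatenate([np.asarray(c, dtype=np.float64) for c in cycles])
    return flat, starts, lengths


# ---------------------------------------------------------------------------
# public pairwise operations
# ---------------------------------------------------------------------------

def _check_pair(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size < 3 or b.size < 3:
        raise ValueError(f"cycles must have length >= 3, got {a.size} and {b.size}")
    return a, b


def cycle_similarity(a, b) -> float:
    """Shift-maximized Pearson correlation between two cycles.

    The shorter vector slides along the longer one; the maximum correlation
    over all offsets is returned. Symmetric in its arguments. If every
    alignment window is constant the similarity is undefined; 0.0 is returned
    with a warning.
    """
    a, b = _check_pair(a, b)
    short, long_ = (a, b) if a.size <= b.size else (b, a)
    r, valid = _max_shift_corr(short, long_)
    if not valid:
        warnings.warn("degenerate similarity: constant window(s); returning 0.0", stacklevel=2)
        return 0.0
    return float(r)


def cycle_distance(a, b) -> float:
    """Shift-minimized RMS difference between two cycles (see module docs)."""
    a, b = _check_pair(a, b)
    short, long_ = (a, b) if a.size <= b.size else (b, a)
    return float(_min_shift_rmsd(short, long_))


def similarity_matrix(cycles: CycleSet | list, clamp: bool = True) -> SimilarityMatrix:
    """All-pairs shift-maximized correlation matrix.

    Each pair is computed once and mirrored, the diagonal is zero, and with
    ``clamp`` (default) negative correlations are set to 0 so the Laplacian
    stays positive semidefinite.
    """
    cyc = cycles.cycles if isinstance(cycles, CycleSet) else list(cycles)
    n = len(cyc)
    if n < 3:
        raise ValueError(f"need >= 3 cycles, got {n}")
    if any(len(c) < 3 for c in cyc):
        raise ValueError("every cycle must have length >= 3")
    flat, starts, lengths = _pack(cyc)
    raw, n_deg = _pairwise_kernel(flat, starts, lengths, True)
    if n_deg:
        warnings.warn(
            f"{n_deg} cycle pair(s) had only constant alignment windows; similarity set to 0",
            stacklevel=2,
        )
    W = np.clip(raw, 0.0, 1.0) if clamp else raw.copy()
    np.fill_diagonal(W, 0.0)
    return SimilarityMatrix(W=W, n=n, clamped=clamp, raw=raw)


def distance_matrix(cycles: CycleSet | list) -> DistanceMatrix:
    """All-pairs shift-minimized RMS distance matrix (zero diagonal)."""
    cyc = cycles.cycles if isinstance(cycles, CycleSet) else list(cycles)
    n = len(cyc)
    if n < 3:
        raise ValueError(f"need >= 3 cycles, got {n}")
    flat, starts, lengths = _pack(cyc)
    D, _ = _pairwise_kernel(flat, starts, lengths, False)
    return DistanceMatrix(D=D, n=n)


# ---------------------------------------------------------------------------
# sign convention
# ---------------------------------------------------------------------------

def _orient(v: np.ndarray, stride_si: np.ndarray | None) -> tuple[np.ndarray, str]:
    """Resolve the eigenvector sign ambiguity by a fixed convention."""
    if stride_si is not None and stride_si.size == v.size and np.ptp(stride_si) > 0:
        r = np.corrcoef(v, stride_si)[0, 1]
        if abs(r) >= 0.05:
            return (v if r >= 0 else -v), "corr(C, SI) >= 0"
    sk = stats.skew(v)
    if abs(sk) > 1e-12:
        return (v if sk >= 0 else -v), "skewness(C) >= 0"
    nz = np.flatnonzero(v)
    if nz.size and v[nz[0]] < 0:
        return -v, "first element >= 0"
    return v, "first element >= 0"


def _si_values(si) -> np.ndarray | None:
    if si is None:
        return None
    if isinstance(si, StrideIntervalSeries):
        return si.intervals
    return np.asarray(si, dtype=np.float64)


# ---------------------------------------------------------------------------
# embeddings
# ---------------------------------------------------------------------------

def laplacian_embedding(
    W: SimilarityMatrix,
    stride_intervals: StrideIntervalSeries | np.ndarray | None = None,
    zero_tol: float = ZERO_EIG_TOL,
) -> CycleSeries:
    """Solve ``L v = lambda D v`` and return the Fiedler-vector cycle series.

    Requires a clamped (nonnegative) similarity matrix whose graph is
    connected: exactly one eigenvalue within ``zero_tol * max eigenvalue`` of
    zero. The returned series is the eigenvector of the second-smallest
    eigenvalue with ``v^T D v = 1``, oriented by the package sign convention
    (optionally using the stride-interval series).
    """
    if not W.clamped or (W.W < 0).any():
        raise ValueError("laplacian_embedding requires a clamped (nonnegative) W")
    M = W.W
    deg = M.sum(axis=1)
    isolated = np.flatnonzero(deg == 0)
    if isolated.size:
        raise IsolatedCycleError(
            f"cycle(s) {isolated.tolist()} have zero similarity to all others"
        )
    L = np.diag(deg) - M
    evals, evecs = linalg.eigh(L, np.diag(deg))
    n_zero = int(np.count_nonzero(evals < zero_tol * max(evals[-1], np.finfo(float).tiny)))
    if n_zero >= 2:
        n_comp, _ = sparse.csgraph.connected_components(sparse.csr_matrix(M > 0))
        raise ConnectivityError(
            f"disconnected cycle graph: {n_comp} components "
            f"({n_zero} eigenvalues below tolerance)"
        )
    v = evecs[:, 1]
    v = v / np.sqrt(v @ (deg * v))  # enforce v^T D v = 1 exactly
    v, rule = _orient(v, _si_values(stride_intervals))
    return CycleSeries(values=v, method="laplacian", eigenvalues=evals, sign_rule=rule)


def mds_embedding(
    Dmat: DistanceMatrix,
    stride_intervals: StrideIntervalSeries | np.ndarray | None = None,
) -> CycleSeries:
    """Classical (Torgerson) MDS to one dimension.

    Double-centers ``-D^2 / 2`` and projects on the leading eigenvector scaled
    by the square root of its eigenvalue. A non-positive leading eigenvalue
    means the distances admit no 1-D Euclidean representation; a (near-)tied
    leading eigenpair makes the axis arbitrary and is flagged with a warning.
    """
    D = Dmat.D
    n = Dmat.n
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = -0.5 * J @ (D * D) @ J
    B = 0.5 * (B + B.T)
    evals, evecs = linalg.eigh(B)
    lam = evals[-1]
    if lam <= 0:
        raise DegenerateGeometryError("largest MDS eigenvalue is non-positive")
    if n >= 2 and (lam - evals[-2]) <= 1e-8 * lam:
        warnings.warn(
            "MDS leading eigenvalue is (near-)degenerate; the 1-D axis is arbitrary",
            stacklevel=2,
        )
    v = evecs[:, -1] * np.sqrt(lam)
    v, rule = _orient(v, _si_values(stride_intervals))
    return CycleSeries(values=v, method="mds", eigenvalues=None, sign_rule=rule)
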