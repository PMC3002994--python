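import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cyclescale import (
    ConnectivityError,
    DegenerateGeometryError,
    IsolatedCycleError,
    cycle_distance,
    cycle_similarity,
    distance_matrix,
    laplacian_embedding,
    mds_embedding,
    similarity_matrix,
)
from cyclescale.embedding import SimilarityMatrix, DistanceMatrix


# --- independent brute-force oracles (kept deliberately naive) -------------

def brute_max_corr(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    if len(a) > len(b):
        a, b = b, a
    m = len(a)
    return max(np.corrcoef(a, b[s : s + m])[0, 1] for s in range(len(b) - m + 1))


def brute_min_rmsd(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    if len(a) > len(b):
        a, b = b, a
    m = len(a)
    return min(
        np.sqrt(np.mean((a - b[s : s + m]) ** 2)) for s in range(len(b) - m + 1)
    )


def random_pair(rng):
    la = int(rng.integers(3, 40))
    lb = int(rng.integers(3, 40))
    return rng.standard_normal(la), rng.standard_normal(lb)


class TestCycleSimilarity:
    def test_self_correlation(self):
        assert cycle_similarity([1, 2, 3, 4], [1, 2, 3, 4]) == pytest.approx(1.0)

    def test_anticorrelation_equal_length(self):
        a = np.array([1.0, 2, 3, 4])
        assert cycle_similarity(a, -a) == pytest.approx(-1.0)

    def test_affine_subsegment_match(self):
        # [1,2,3] at offset 2 of b is affinely equal to [2,4,6]
        assert cycle_similarity([2, 4, 6], [9, 9, 1, 2, 3, 9]) == pytest.approx(1.0)

    def test_matches_brute_force_on_random_pairs(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            a, b = random_pair(rng)
            assert cycle_similarity(a, b) == pytest.approx(brute_max_corr(a, b), abs=1e-12)

    def test_degenerate_constant_windows(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert cycle_similarity([1.0, 1.0, 1.0], [2.0, 2.0, 2.0, 2.0]) == 0.0

    def test_too_short(self):
        with pytest.raises(ValueError):
            cycle_similarity([1, 2], [1, 2, 3])

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_symmetry_and_affine_invariance(self, seed):
        rng = np.random.default_rng(seed)
        a, b = random_pair(rng)
        assert cycle_similarity(a, b) == cycle_similarity(b, a)
        alpha = float(rng.uniform(0.1, 5.0))
        gamma = float(rng.uniform(-3.0, 3.0))
        assert cycle_similarity(a, alpha * a + gamma) == pytest.approx(1.0, abs=1e-9)


class TestCycleDistance:
    def test_identical(self):
        assert cycle_distance([1.0, 2, 3], [1.0, 2, 3]) == 0.0

    def test_constant_offset(self):
        assert cycle_distance([0.0, 0, 0], [1.0, 1, 1, 1]) == pytest.approx(1.0)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            a, b = random_pair(rng)
            assert cycle_distance(a, b) == pytest.approx(brute_min_rmsd(a, b), abs=1e-12)


class TestSimilarityMatrix:
    def test_identical_cycles(self):
        c = np.array([0.0, 1.0, 2.0, 1.0])
        W = similarity_matrix([c, c, c])
        assert np.allclose(np.diag(W.W), 0)
        off = W.W[~np.eye(3, dtype=bool)]
        assert np.allclose(off, 1.0)

    def test_clamp_zeroes_negative(self):
        a = np.array([0.0, 1.0, 0.0, 1.0, 0.5])
        b = np.array([1.0, 0.0, 1.0, 0.0, 0.5])
        c = np.array([0.0, 1.0, 0.1, 0.9, 0.4])
        W = similarity_matrix([a, b, c], clamp=True)
        assert W.raw[0, 1] < 0
        assert W.W[0, 1] == 0.0
        W2 = similarity_matrix([a, b, c], clamp=False)
        assert W2.W[0, 1] == W.raw[0, 1]

    def test_symmetric_and_matches_pairwise(self, rng):
        cycles = [rng.standard_normal(int(rng.integers(5, 15))) for _ in range(8)]
        W = similarity_matrix(cycles, clamp=False)
        assert np.array_equal(W.W, W.W.T)
        for i in range(8):
            for j in range(i + 1, 8):
                assert W.W[i, j] == pytest.approx(
                    cycle_similarity(cycles[i], cycles[j]), abs=1e-12
                )

    def test_rossler_cycles_highly_similar(self, rossler_clean_pipeline):
        W = rossler_clean_pipeline.W
        off = W.W[np.triu_indices(W.n, 1)]
        assert np.median(off) > 0.9
        assert off.min() > 0.5


class TestLaplacianEmbedding:
    def test_zero_mode_constant_eigenvector(self, rng):
        W = rng.uniform(0.05, 1.0, (12, 12))
        W = np.triu(W, 1)
        W = W + W.T
        sm = SimilarityMatrix(W=W, n=12, clamped=True)
        C = laplacian_embedding(sm)
        evals = C.eigenvalues
        assert abs(evals[0]) <= 1e-8 * evals[-1]
        # v0 constant: check via the Laplacian acting on ones
        deg = W.sum(1)
        L = np.diag(deg) - W
        assert np.abs(L @ np.ones(12)).max() <= 1e-9 * deg.max()

    def test_matches_independent_dense_solver(self, rng):
        # oracle: generic (non-symmetric) eigendecomposition of D^-1 L
        W = rng.uniform(0.0, 1.0, (8, 8))
        W = np.triu(W, 1)
        W = W + W.T
        sm = SimilarityMatrix(W=W, n=8, clamped=True)
        C = laplacian_embedding(sm)
        deg = W.sum(1)
        L = np.diag(deg) - W
        evals, evecs = np.linalg.eig(np.diag(1.0 / deg) @ L)
        order = np.argsort(evals.real)
        v = evecs[:, order[1]].real
        v = v / np.sqrt(v @ (deg * v))
        if np.dot(v, C.values) < 0:
            v = -v
        assert np.abs(v - C.values).max() <= 1e-8
        assert np.abs(np.sort(evals.real) - C.eigenvalues).max() <= 1e-8

    def test_two_block_separation(self):
        n = 6
        W = np.zeros((2 * n, 2 * n))
        W[:n, :n] = 1.0
        W[n:, n:] = 1.0
        np.fill_diagonal(W, 0.0)
        W[0, n] = W[n, 0] = 1e-6  # weak bridge keeps the graph connected
        C = laplacian_embedding(SimilarityMatrix(W=W, n=2 * n, clamped=True))
        a, b = C.values[:n], C.values[n:]
        gap = abs(a.mean() - b.mean())
        assert max(a.std(), b.std()) < 0.01 * gap

    def test_disconnected_graph_reports_components(self):
        W = np.zeros((6, 6))
        W[:3, :3] = 1.0
        W[3:, 3:] = 1.0
        np.fill_diagonal(W, 0.0)
        with pytest.raises(ConnectivityError, match="2 components"):
            laplacian_embedding(SimilarityMatrix(W=W, n=6, clamped=True))

    def test_isolated_cycle_named(self):
        W = np.ones((5, 5))
        np.fill_diagonal(W, 0.0)
        W[2, :] = W[:, 2] = 0.0
        with pytest.raises(IsolatedCycleError, match="2"):
            laplacian_embedding(SimilarityMatrix(W=W, n=5, clamped=True))

    def test_normalization_vDv(self, rossler_clean_pipeline):
        C = rossler_clean_pipeline.C
        deg = rossler_clean_pipeline.W.W.sum(1)
        assert C.values @ (deg * C.values) == pytest.approx(1.0, abs=1e-8)

    def test_permutation_equivariance(self, rng):
        W = rng.uniform(0.05, 1.0, (10, 10))
        W = np.triu(W, 1)
        W = W + W.T
        C = laplacian_embedding(SimilarityMatrix(W=W, n=10, clamped=True))
        perm = rng.permutation(10)
        Wp = W[np.ix_(perm, perm)]
        Cp = laplacian_embedding(SimilarityMatrix(W=Wp, n=10, clamped=True))
        v1, v2 = C.values[perm], Cp.values
        if np.dot(v1, v2) < 0:
            v2 = -v2
        assert np.abs(v1 - v2).max() <= 1e-8

    def test_signal_scale_invariance(self):
        # Pearson similarity ignores positive rescaling, hence so does C
        from cyclescale import TimeSeries, detect_landmarks, split_cycles

        t = np.arange(2000.0)
        base = np.sin(2 * np.pi * t / 100) + 0.1 * np.sin(2 * np.pi * t / 47)
        for scale in (1.0, 37.5):
            ts = TimeSeries(scale * base, fs=1.0)
            lm = detect_landmarks(ts, mode="minima", min_separation=50)
            W = similarity_matrix(split_cycles(ts, lm))
            if scale == 1.0:
                W_ref = W.W
        assert np.abs(W.W - W_ref).max() <= 1e-9


class TestMDSEmbedding:
    def test_collinear_points_exact(self):
        pts = np.array([0.0, 1.0, 2.0, 3.0])
        D = np.abs(pts[:, None] - pts[None, :])
        C = mds_embedding(DistanceMatrix(D=D, n=4))
        # affine match up to sign/shift
        v = C.values - C.values.mean()
        ref = pts - pts.mean()
        if np.dot(v, ref) < 0:
            v = -v
        assert np.abs(v - ref).max() <= 1e-10

    def test_regular_simplex_flagged(self):
        D = np.ones((4, 4)) - np.eye(4)
        with pytest.warns(UserWarning, match="degenerate"):
            mds_embedding(DistanceMatrix(D=D, n=4))

    def test_zero_distances_degenerate(self):
        with pytest.raises(DegenerateGeometryError):
            mds_embedding(DistanceMatrix(D=np.zeros((4, 4)), n=4))

    def test_distance_matrix_consistency(self, rng):
        cycles = [rng.standard_normal(int(rng.integers(5, 12))) for _ in range(6)]
        D = distance_matrix(cycles)
        for i in range(6):
            for j in range(i + 1, 6):
                assert D.D[i, j] == pytest.approx(
                    cycle_distance(cycles[i], cycles[j]), abs=1e-12
                )


class TestSignConvention:
    def test_si_correlation_orientation(self, rossler_clean_pipeline):
        C, si = rossler_clean_pipeline.C, rossler_clean_pipeline.si
        r = np.corrcoef(C.values, si.intervals)[0, 1]
        if abs(r) >= 0.05:
            assert r >= 0 and "SI" in C.sign_rule

    def test_skewness_fallback(self):
        from cyclescale.embedding import _orient

        v = np.array([-3.0, 0.1, 0.2, 0.3, 0.4])  # negatively skewed
        out, rule = _orient(v, None)
        from scipy.stats import skew

        assert skew(out) >= 0 and "skew" in rule
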