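# Methods

## The cycle-scale representation

A pseudoperiodic signal — gait joint angles, ECG, respiration, a chaotic
oscillator — repeats a stereotyped waveform with irregular cycle-to-cycle
variation. `cyclescale` treats each cycle as a high-dimensional vector (one
entry per sample) and reduces the set of cycles to one scalar per cycle,
`C(i)`, so that the cycle-to-cycle dynamics can be studied with ordinary
time-series tools after the periodic trend has been removed.

**Segmentation.** Cycles are cut at landmark extrema: local minima for
Rossler-style benchmarks, local maxima for gait. A landmark must be a strict
extremum of its surrounding window of `min_separation` samples on each side;
by default the window is half the dominant period, read off the largest
periodogram ordinate. Dominance is judged by Fisher's g-test at alpha = 0.01:
the raw-periodogram maximum under a white-noise null is about `ln M` times
the mean ordinate, so a fixed peak-to-median ratio cannot separate a genuine
rhythm from noise, whereas the g-test has a calibrated null. Cycles are
half-open `[l_i, l_{i+1})`, so concatenation reproduces the signal exactly
and every sample belongs to exactly one cycle. Ties in extremum value break
toward the earlier index; the detector is fully deterministic.

**Similarity and embedding.** Pairwise similarity is the shift-maximized
Pearson correlation: the shorter cycle slides along the longer one (offsets
`0 .. n-m`) and the largest correlation over offsets is kept. The graph is
dense (every pair), the diagonal is zero, and negative correlations are
clamped to zero before the Laplacian is formed — `L = D - W` loses positive
semidefiniteness with negative weights, and with it the guaranteed zero
eigenvalue; the raw matrix is retained for inspection. The embedding solves
`L v = lambda D v`; the eigenvector of the second-smallest eigenvalue,
normalized to `v' D v = 1`, is `C`. One eigenvalue within `1e-8` (relative)
of zero certifies connectivity; two or more raise an error that reports the
component count. The alternative reduction is classical MDS on the
shift-minimized RMS cycle distance, projected on the leading eigenvector
scaled by the square root of its eigenvalue.

**Sign convention.** Eigenvectors are sign-ambiguous. `C` is flipped so that
its correlation with the stride-interval series is nonnegative when that
correlation is informative (|r| >= 0.05); otherwise so that its skewness is
nonnegative; as a last resort so that the first nonzero element is
nonnegative. Synchronization additionally uses |corr|, so no result depends
on the convention.

**Derived statistics.**

* Quadratic return fit: regress `s_{k+1}` on `s_k` with `a x^2 + b x + c` by
  ordinary least squares on the z-scored series; `sigma2 = RSS/(N-1)` over
  the `N` return pairs. Z-scoring makes `sigma2` comparable between series
  with arbitrary scales (the eigenvector scale is arbitrary).
* Spectral exponent: raw periodogram (boxcar, mean removed, density scaling,
  zero frequency dropped), then OLS of `log10 PSD` on `log10 f` over the full
  positive band by default; `beta` is minus the slope. The effective sampling
  interval of a gait cycle series is the mean stride interval in seconds; for
  unitless benchmarks it is one cycle. `beta >= 0.3` is labelled
  long-range-correlated — a package convention (exposed as a flag), not a
  physiological constant.
* Dual-segmentation synchronization: both signals are cut at x's landmarks,
  each cycle set embedded, and `|corr(C_x, C_y)|` recorded; the same under
  y's landmarks; `rho` is the mean of the two. Cutting both signals at the
  same landmarks makes cycle `i` of both series span the same time window.
  Baselines: `|corr(P_x, P_y)|` at x's landmarks, and the correlation of the
  two stride-interval series from each signal's own landmarks.

## Synthetic benchmarks

**Noisy Rossler.** `dx/dt = -y - z, dy/dt = x + a y, dz/dt = b + z (x - c)`
with a = b = 0.2, c = 5.7 (chaotic regime), fixed-step RK4 at dt = 0.01,
initial state (1, 1, 1), 10 000 transient samples discarded. Dynamical noise
is an additive Gaussian state perturbation after each step with SD
`(pct/100) * state SD * sqrt(dt)` — the Euler-Maruyama scaling, so "percent
dynamical noise" means noise accumulated per unit model time and is
independent of the step size (without the `sqrt(dt)` factor the z equation
destabilizes). The reference state SDs come from a cached noise-free pilot
run of the same configuration. Measurement noise is iid Gaussian added to the
returned series only, as a percent of each component's SD. Defaults are 1%
dynamical and 5% measurement noise. The noise-free x component has mean
inter-minimum period 5.86 time units (checked against an adaptive-step
integration oracle) and about one cycle per 586 samples.

**Power-law cycle sequences.** Spectral synthesis: Fourier amplitudes
proportional to `f^(-beta/2)`, iid uniform phases (random sign at Nyquist),
inverse transform, z-scored. Because the amplitudes are deterministic, the
full-length periodogram of a synthesized sequence is essentially noiseless
and the recovered slope is near-exact — these sequences test the estimator's
calibration, not its sampling variability (the white-noise tests cover
that).

**Gait-like pairs.** Each cycle is a two-component template over phase
`phi in [0, 1)`: a base harmonic `cos(2 pi phi)` whose peak at `phi = 0`
provides the landmark, plus a modulated component
`(1 - cos 2 pi phi) cos(4 pi phi + 1)` that vanishes with zero slope at the
onset and gives the cycle its second, non-phase-coherent oscillation
(knee/ankle traces show the same multi-oscillation). The modulated
component's amplitude is `0.4 (1 + 0.2 h_k)` with `h` a power-law latent
sequence; its partner uses `h' = lam h + sqrt(1 - lam^2) eps`, so the
cross-signal cycle coupling is `lam` while the signals stay perfectly in
phase (shared onsets and periods). Because the modulation does not touch the
onset peak, landmark detection and the stride-interval series are exact by
construction; the cycle series `C` recovers `h` with correlation ~0.99 at
default noise. Defaults emulate the overground-walking recordings the
package targets: 66.7 Hz sampling, 1.1 s base stride, 2% period jitter, 2%
measurement noise, 256 cycles (about 4.7 minutes of walking; long enough for
a stable spectral fit while keeping a full cohort analysis interactive).
Amplitude-modulation depth 0.2 keeps the similarity graph connected while
leaving `C` informative. What the generator does *not* emulate: biomechanical
waveform asymmetries, within-cycle phase jitter, non-stationary drift, or
amplitude-period coupling — passing tests show the pipeline recovers the
latent structure this generator encodes, not that real gait satisfies the
same assumptions.

**Cohorts.** `simulate_cohort` draws independent subjects per group from
per-group overrides; the defaults contrast a healthy-control-like group
(beta = 1, lam = 0.8) with a neuropathic-like group (beta = 0, lam = 0.1),
the qualitative pattern reported for diabetic peripheral neuropathy. Group
comparison uses Welch's two-sample t-test by default (rank-sum available).

## Numerical choices and degenerate inputs

* Pearson windows with (relatively) zero variance are skipped; if every
  offset is degenerate the similarity is 0 with a warning.
* Eigensolver: dense symmetric-definite generalized solver
  (`scipy.linalg.eigh`); cycle counts are at most a few thousand, so no
  large-scale approximation is needed or provided.
* `v' D v = 1` is re-enforced explicitly after the solve.
* MDS with a (near-)tied leading eigenvalue warns that the axis is
  arbitrary; a non-positive leading eigenvalue is an error.
* Quadratic fits reject constant series; the spectral fit requires >= 8
  usable ordinates and drops zero-power ordinates with a warning.
* The similarity kernels are numba-compiled; results agree with naive
  brute-force enumeration to ~1e-15 (asserted at 1e-12 in tests).

## Known limitations

The Pearson similarity z-scores each aligned window, so the cycle graph sees
only cycle *shape*; per-cycle amplitude enters only through its correlation
with shape. On strongly chaotic oscillators the shape manifold is a curved
arc in feature space and the Fiedler vector, while essentially a
deterministic function of the underlying per-cycle coordinate (a degree-9
return-map fit reaches r^2 = 0.99 on noise-free Rossler), is a *nonlinearly
warped* one. Curvature-sensitive statistics — the quadratic return fit and
its residual `sigma2` — are therefore biased against the Laplacian `C` on
such data (quadratic r^2 = 0.59 where the Poincare section and the MDS
reduction reach 0.96-0.98), while rank- and correlation-based statistics are
unaffected: the cycle-scale synchronization index reaches 0.96-0.97 on noisy
Rossler where the Poincare baseline collapses to ~0.08, and the Laplacian
and MDS series agree at |corr| = 0.95. For return-map geometry on heavily
saturated similarity graphs, prefer the MDS reduction; for spectral and
synchronization analyses the Laplacian embedding is the robust default.
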