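# cyclescale

Cycle-scale dynamics and synchronization of pseudoperiodic signals.

Rhythmic physiological signals — gait joint angles, ECG, respiration —
repeat a stereotyped waveform whose *cycle-to-cycle* variation carries the
physiologically interesting information, hidden under a dominant periodic
trend and noise. `cyclescale` extracts that variation by dimensionality
reduction on whole cycles:

1. **Segment** the signal into consecutive cycles at landmark extrema
   (windowed strict minima or maxima).
2. **Embed**: build the similarity matrix `W_ij` = shift-maximized Pearson
   correlation between cycles i and j, form the graph Laplacian `L = D - W`
   (`D_ii = sum_j W_ij`), and solve `L v = lambda D v`. The eigenvector of
   the second-smallest eigenvalue (normalized `v' D v = 1`) is the cycle
   series `C(i)` — one scalar per cycle. Classical MDS on shift-minimized
   RMS cycle distances is provided as an alternative reduction.
3. **Characterize**: power spectral density of `C` with effective sampling
   interval equal to the mean stride interval, log-log least-squares slope
   `beta` (PSD ~ 1/f^beta; beta ~ 1 long-range correlation, beta ~ 0 white
   noise), and quadratic return-map fits `C(i+1) = a C(i)^2 + b C(i) + c`
   with residual variance `sigma^2`, compared against the classical
   Poincare-section baseline `P(k)` (the signal value at each landmark).
4. **Synchronize**: for two in-phase signals (knee/ankle), segment both at
   either signal's landmarks, embed each, and average `|corr(C_x, C_y)|`
   over the two segmentation schemes — a synchronization index `rho` that is
   not saturated by the strong phase locking that defeats phase-based
   indices.

A synthetic benchmark suite (noisy Rossler trajectories integrated with RK4,
1/f^beta cycle sequences by spectral synthesis, gait-like coupled pairs with
controllable spectral exponent and coupling, and two-group cohorts) ships as
first-class, tested code with retained ground truth. See `docs/methods.md`
for the model details and design choices.

## Worked example

```python
import numpy as np
from cyclescale import (GaitSimConfig, simulate_gait_pair,
                        cycle_sync, run_characterize)

cfg = GaitSimConfig(n_cycles=256, beta_target=1.0, coupling=0.8, seed=0)
ts_x, ts_y, truth = simulate_gait_pair(cfg)

record, inter = run_characterize(ts_x, mode="maxima")
print(f"n_cycles={record.derived['n_cycles']}  "
      f"beta={record.derived['beta']:.3f}  ({record.derived['lrc_class']})")

k0 = int(np.argmin(np.abs(truth["onsets"] - inter["landmarks"].indices[0])))
h = truth["h"][k0:k0 + len(inter["C"])]
print(f"corr(C, latent h) = {np.corrcoef(inter['C'].values, h)[0,1]:.3f}")

res = cycle_sync(ts_x, ts_y, mode="maxima")
print(f"rho={res.rho:.3f}  (schemes {res.rho_scheme_x:.3f}/{res.rho_scheme_y:.3f}, "
      f"SI baseline {res.rho_si:.3f})")
```

Output:

```
n_cycles=256  beta=0.990  (long-range-correlated)
corr(C, latent h) = 0.918
rho=0.804  (schemes 0.800/0.808, SI baseline 0.497)
```

The cycle series tracks the latent cycle-amplitude sequence (corr 0.92 at 2%
measurement noise), the spectral exponent estimate matches the generator's
`beta_target = 1`, and the synchronization index `rho = 0.80` matches the
generator's coupling `lambda = 0.8`. The stride-interval baseline cannot see
the coupling: the two signals share cycle onsets by construction, so their
stride intervals differ only by landmark jitter — exactly the situation in
which interval-based measures cannot discriminate coupling strength and the
cycle-scale index can.

The same pipeline is available from the shell:

```sh
cyclescale simulate gait --seed 0 --out demo/
cyclescale characterize --input demo/gait_pair.csv --column x --fs 66.7 \
    --mode maxima --out demo/
cyclescale sync --x demo/gait_pair.csv --y demo/gait_pair.csv \
    --column 0 --fs 66.7 --mode maxima --out demo/
```

Every command writes its full run configuration as JSON next to its outputs.

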