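# swarmtopo

Classify collective motion — and recover the parameters that generated it —
from the *shape* of the data.

`swarmtopo` simulates the planar D'Orsogna-type swarm model: N
self-propelled agents with positions x_i and velocities v_i obeying

    dx_i/dt = v_i,
    dv_i/dt = (α − β|v_i|²) v_i − ∇_i Σ_{j≠i} [ C e^(−|x_i−x_j|/ℓ) − e^(−|x_i−x_j|) ],

with self-propulsion α = 1.5, drag β = 0.5, and Morse-type social forces
parameterized by the repulsion amplitude ratio C and length ratio ℓ.
Depending on (C, ℓ) the group settles into a single mill, double mill,
double ring, collective swarm, or one of three escape patterns. The package
addresses the *inverse* problem: given only the trajectories, which of the
25 library combinations (C, ℓ ∈ {0.1, 0.5, 0.9, 2, 3}) produced them, and
which phenotype is being exhibited?

Two kinds of summaries feed the classifiers:

* **Order parameters** — polarization P, angular momentum M_ang, absolute
  angular momentum M_abs, and mean nearest-neighbor distance D_NN, each a
  scalar time series on 87 downsampled frames.
* **Crockers** — matrices b_k(ε_q, t_j) of Vietoris–Rips Betti numbers
  (b0 components, b1 loops) over 200 logarithmically spaced scales
  ε_q = 10^(−4+q·0.02) and the sampled frames, computed from positions
  alone, optionally lifted to 4D by a time-delay embedding
  [x_i(t), x_i(t−5Δt)] that restores velocity information without mixing
  units.

Parameter recovery is done unsupervised (PAM k-medoids, k = 25) and
supervised (one-vs-one linear SVM, stratified 5-fold cross-validation),
with optional PCA to 87 or 3 dimensions. The headline scientific result
this pipeline reproduces: topological features outperform the classical
order parameters at parameter recovery.

The Vietoris–Rips persistence engine is part of the package: H0 by
union-find (single-linkage merge heights), H1 by persistent cohomology with
clearing and lazy-heap column reduction, exact and cross-checked against a
brute-force boundary-matrix oracle. See `docs/methods.md` for the numerics.

## Worked example

Simulate one single-mill run, summarize it, and read off its topology:

```python
import numpy as np
from swarmtopo import (ModelParams, simulate, compute_series, cap_escape,
                       normalize_library, time_delay_embed, compute_crockers,
                       epsilon_grid)
from swarmtopo.tda import plateau_value

traj = simulate(ModelParams(C=0.5, ell=0.1), seed=7)   # N=200, t=100
s = compute_series(traj)                               # 87 frames
print(f"P={s.P[-5:].mean():.3f}  M_ang={s.M_ang[-5:].mean():.3f}  "
      f"M_abs={s.M_abs[-5:].mean():.3f}  D_NN={s.D_NN[-1]:.3f}")

ring = simulate(ModelParams(C=0.1, ell=0.1), seed=7)   # double ring
scaled, const = normalize_library([cap_escape(ring).positions])
clouds, idx = time_delay_embed(scaled[0])
b1 = compute_crockers(clouds, epsilon_grid(), max_dim=1,
                      frame_indices=idx)[1].betti
print(f"norm constant={const:.2f}  "
      f"late-time b1 plateau={plateau_value(b1[:, -1])}")
```

prints

```
P=0.003  M_ang=0.981  M_abs=0.981  D_NN=0.016
norm constant=0.99  late-time b1 plateau=2
```

The mill signature is M_ang ≈ M_abs ≈ 1 (coherent rotation, no net
translation: P ≈ 0) with a tight, stable nearest-neighbor spacing. The
double ring — two groups orbiting the same circle in opposite directions —
is invisible to a plain 2D position cloud (one circle) but shows exactly
two persistent loops, b1 = 2, over a contiguous band of scales in the
time-delay crocker.

The same machinery scales to the full experiment via the pipeline:

```sh
swarmtopo simulate --grid default --reps 100 --seed 0 --out library.h5
swarmtopo orderparams library.h5 --out op/
swarmtopo crocker library.h5 --embedding delay --out crockers.h5
swarmtopo classify library.h5 --features tda_delay/b0 --method svm
swarmtopo report --reps 10 --seed 0 --out results/     # full benchmark table
swarmtopo plot library.h5 --sim 0 --embedding delay --out crocker.png
```

(The reps=100 library is a multi-hour batch job; `report --reps 2` gives a
desk-scale smoke run.)

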