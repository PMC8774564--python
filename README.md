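# multit1

Multi-component T1 relaxometry from magnitude inversion-recovery MRI.

Low-resolution inversion-recovery (IR) series acquired at many inversion times
carry information about the *sub-voxel* composition of cortical tissue: each
compartment (cortical layer, white matter, CSF) relaxes with its own T1, and a
3 mm voxel's signal is the superposition of their recovery curves.  `multit1`
estimates that composition from magnitude IR data.  It is intended for
researchers working on laminar MRI, quantitative T1 mapping, and partial-volume
decomposition who need a robust voxelwise multi-exponential fit.

## Model

A voxel with `n ≤ 7` compartments observed at inversion time `TI` (ms) has
magnitude signal

```
M(TI) = Σ_j  M0_j · |1 − 2·exp(−TI / T1_j)| ,      j = 1..n
```

where `M0_j` is the equilibrium magnetization of compartment `j` (proportional
to its volume fraction) and `T1_j` its spin-lattice relaxation time.  Only
magnitude images are assumed (no polarity restoration), hence the absolute
value.  The coefficients are estimated by bound-constrained nonlinear least
squares,

```
min  F(M0_1..M0_n, T1_1..T1_n) = Σ_i ( y_i − M(TI_i) )² ,
```

solved by a trust-region iteration with a two-dimensional subspace subproblem
(steepest-descent + Newton directions, Coleman–Li affine scaling for the box
constraints, Gauss–Newton Hessian `2 JᵀJ`).  The multi-exponential objective
has many non-optimal local minima, so the solver is restarted from many
starting points drawn uniformly inside the bounds and the best local solution
is kept — with 100 starts the noiseless 7-component problem is recovered to
machine precision.

## Worked example

```python
import numpy as np
from multit1 import (VoxelSimulationSpec, generate_single_voxel_dataset,
                     default_fit_bounds, MultiStartConfig, multistart_fit,
                     match_components)

spec = VoxelSimulationSpec(seed=3)                 # 7 compartments, 105 TIs
series, truth = generate_single_voxel_dataset(spec, variance=0.0)
bounds = default_fit_bounds(float(series.magnitude.max()))
fit = multistart_fit(series, bounds,
                     MultiStartConfig(n_starts=100, seed=1, bounds=bounds),
                     n_components=7)
matched = fit.best_params.permuted(match_components(fit.best_params, truth))
print("objective:", fit.best_objective)
with np.printoptions(precision=2):
    print("T1 err %:", 100 * np.abs(matched.t1_ms - truth.t1_ms) / truth.t1_ms)
```

prints (machine-precision recovery of all seven T1 values — the objective sits
at the double-precision floor of the 105-point sum of squares):

```
objective: 1.2359241574278636e-25
T1 err %: [0.00e+00 5.68e-14 1.24e-13 0.00e+00 3.03e-14 1.34e-14 0.00e+00]
```

The same fit applied to a 4D NIfTI series is available from the shell:

```
multit1 simulate-phantom --seed 1 --out results/
multit1 fit-volume results/phantom_series.nii results/ti_ms.txt \
        --mask results/phantom_mask.nii --n-components 2 --out results/
```

which writes per-component `M0`/`T1` maps (NIfTI) plus objective and
convergence maps.  `multit1 table1|table2|table3` run the three validation
experiments and emit CSV summaries with provenance JSON.

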