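# cortexgrowth

Quantitative MRI relaxometry and longitudinal mixed-model analysis of
infant cortical microstructural growth.

## The problem

In the first six months of life the human cortex changes faster than at
any later age, driven largely by myelination. Quantitative MRI can track
this in vivo: the longitudinal relaxation time T1 falls as tissue
acquires myelin, and the relaxation rate R1 = 1/T1 rises approximately
linearly with the myelin volume fraction. This package implements the
analysis chain for such a study, for researchers in developmental
neuroimaging:

1. **T1 mapping** — voxelwise nonlinear least-squares estimation of the
   inversion-recovery signal model on magnitude images,

   S(t) = a (1 − b e^(−t/T1)),   fitted as |S(t)|,

   where t is the inversion time, a the initial-magnetization scale and
   b the inversion coefficient (b = 2 for a perfect inversion). The
   default schedule is 20 TIs from 50 ms in 150 ms steps. The absolute
   value (magnitude images discard the sign of the recovering signal)
   introduces a kink at the null point; the fitter handles it with an
   exact profiled grid search over T1 plus bounded multistart
   Levenberg–Marquardt-type refinement, and emits T1, R1 = 1/T1, R² and
   b maps.

2. **Longitudinal trajectories** — per cortical area, a linear mixed
   model of the area-mean metric y for infant i at age (days) a_ij:

   y_ij = β0 + u_i + β1 a_ij + ε_ij,   u_i ~ N(0, τ²),  ε_ij ~ N(0, σ²),

   so β0 is the estimated value at birth and β1 the rate of change per
   day. A random-slope alternative, likelihood-ratio model comparison,
   stream-level models with area/hemisphere/stream factors, and
   Bonferroni correction over the k(k−1)/2 pairwise area comparisons are
   included.

3. **Gene screen** — postnatal-vs-prenatal differential expression on
   RPKM matrices: fold change as the difference of group means of log2
   expression, per-gene two-sample t-tests, selection at linear fold
   change > 4 and p < 5.7×10⁻⁶, ranked by descending fold change, with
   enrichment-ready gene-list export.

4. **Overlap QA** — Dice coefficient 2|A∩B|/(|A|+|B|) between ROI
   definitions.

5. **Synthetic data** — seeded generators for every input: Rician
   (magnitude of complex Gaussian) IR voxel signals, a 13-infant /
   3-timepoint cohort (10 infants per timepoint, 7 longitudinal) with
   random intercepts and linear age trends, expression matrices with
   planted differentially expressed genes, and mask pairs with exact
   overlap counts — always returned with their ground truth, so every
   stage has parameter-recovery tests.

## Worked example

```python
import numpy as np
from cortexgrowth import (IRSimulationSpec, simulate_ir_voxels,
                          build_default_schedule, fit_t1_voxel,
                          CohortSimulationSpec, simulate_cohort, fit_lmm)

# --- T1 from one noisy magnitude IR series -------------------------
sched = build_default_schedule()
spec = IRSimulationSpec(a=1000, b=2.0, t1_ms=2000, noise_sigma=20,
                        n_voxels=1, seed=1)
signals, truth = simulate_ir_voxels(spec)
res = fit_t1_voxel(signals[0], sched)
print(f"T1 = {res.t1_ms:.1f} ms, b = {res.b:.3f}, R^2 = {res.r_squared:.5f}")

# --- growth trajectory of one area ---------------------------------
table, _ = simulate_cohort(CohortSimulationSpec(beta0=2.0, beta1=-1.5e-3,
                                                tau=0.05, sigma=0.03, seed=3))
fit = fit_lmm(table)
print(f"T1 at birth = {fit.intercept:.3f} s, "
      f"slope = {fit.slope * 1000:.3f} ms/day")
```

prints

```
T1 = 1958.8 ms, b = 2.023, R^2 = 0.99792
T1 at birth = 2.015 s, slope = -1.518 ms/day
```

The fitted T1 differs from the true 2000 ms by ~2%, the expected
statistical precision of the three-parameter magnitude fit at this
noise level (see `docs/methods.md`). The mixed-model intercept
estimates the area's T1 at age 0 (birth) and the slope its daily
decrease as the tissue myelinates — here recovering the generating
values 2.0 s and −1.5 ms/day from a 60-row cohort table.

The same analyses are scriptable from the shell:

```sh
cortexgrowth simulate cohort --seed 3 --out-prefix demo_
cortexgrowth trajectory --table demo_roi.tsv --areas V1 --out demo_fits.tsv
```

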