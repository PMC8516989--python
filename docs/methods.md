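# Methods

This note documents the models implemented in `cortexgrowth`, the
defaults and why, what the synthetic generators do and do not emulate,
and the numerical choices that matter.

## Inversion-recovery T1 estimation

**Model.** The longitudinal magnetization after an inversion pulse
recovers as S(t) = a (1 − b e^(−t/T1)), with inversion time t (ms),
amplitude a (scanner units, proportional to initial magnetization),
inversion coefficient b (dimensionless; 2 for a perfect inversion, so b
is bounded in [0, 2.5] by default) and relaxation time T1 (ms). Scanner
magnitude images keep |S|, not S, so the objective minimized per voxel
is

    SSE(a, b, T1) = Σ_i ( y_i − |a (1 − b e^(−t_i/T1))| )².

The default inversion-time schedule is the 20-point arithmetic sequence
50, 200, …, 2900 ms.

**Optimization.** |·| makes the objective non-smooth at the null point
t = T1·ln(b), so a single local search is unreliable. The fitter
exploits a structural fact: at fixed T1 the model is monotone in
e^(−t/T1), so the sign vector of the signed model is one of the n+1
single-crossing patterns, and under a fixed pattern the signed model is
linear in (c0, c1) = (a, −ab). A grid over T1 (default step 20 ms
across the T1 bounds) with this exact two-parameter profile gives a
near-global start; it is polished, together with null-point heuristic
starts (T1 ≈ t_min/ln 2 scaled by {0.5, 1, 2}) and fixed seeds at 500
and 2500 ms, by bounded trust-region least squares. The Jacobian is the
analytic Jacobian of the signed model with sign(m) applied afterward,
using sign(0) = +1 at the kink. Default bounds: T1 ∈ [50, 10000] ms
(infant cortical gray matter sits near 1500–2500 ms), b ∈ [0, 2.5],
a ∈ (0, 10·max signal]. Convergence: relative SSE tolerance 1e−10, 500
iterations per start. R² is computed about the series mean; a constant
(or all-zero) series has no identifiable T1 and returns a flagged
sentinel. No R² exclusion threshold is applied by default; one can be
set in `FitOptions`.

**Precision.** At SNR 50 (noise sigma = a/50) on the default schedule
with T1 = 2000 ms, the Cramér–Rao bound for the three-parameter
magnitude fit gives SD(T̂1)/T1 ≈ 5.5%, i.e. an expected median absolute
relative error near 3.7% for an efficient estimator; the implemented
fitter measures ≈ 4% and matches an exhaustive grid-search oracle's
SSE, so this dispersion is statistical, not algorithmic. The limiting
factors are the b–T1 trade-off (b free) and the schedule ending at
1.45·T1. Fixing b = 2 would shrink the bound to ≈ 0.5%, at the cost of
bias wherever inversion is imperfect; the package fits b.

**Maps.** T1 maps are emitted in seconds, R1 = 1/T1 in 1/s; voxels
outside the mask or with failed fits are NaN, which propagates through
ROI summaries that explicitly skip NaN.

## Myelin relations

R1 is modelled as linear in the myelin volume fraction mf ∈ [0, 1]:
R1(mf) = c0 + c1·mf, hence T1(mf) = 1/(c0 + c1·mf). The constants are
user parameters (defaults c0 = 0.3 /s, c1 = 0.5 /s chosen only to give
plausible infant cortical values ~0.4–0.6 /s); the module encodes the
structural consequence that an equal myelin increment produces a
constant R1 increment but a T1 change whose magnitude decreases with
baseline myelination — the reason growth rates are compared on the R1
scale.

## Longitudinal mixed models

**Per-area model.** value_ij = β0 + u_i + β1·age_ij + ε_ij with
per-infant random intercepts u_i ~ N(0, τ²). Age is in days and is
deliberately *not* centred: β0 is the estimated value at birth (age 0)
and β1 the rate per day. Estimation uses `statsmodels` MixedLM; the
package reports REML coefficients and refits by ML for likelihood-ratio
comparisons. Fixed-effect p-values and confidence intervals use t
statistics with residual degrees of freedom (n_obs − n_fixed).

**Model comparison.** The random-slope alternative adds a per-infant
age slope (two covariance parameters). LR = 2(ℓ_alt − ℓ_null) is
referred to χ² with df = parameter-count difference; because the null
lies on the boundary of the alternative's parameter space the test is
conservative (simulated null rejection ≈ 0.5–2% at nominal 5%), which
is documented rather than corrected (no boundary mixture), matching
common statistical-package practice. Because the boundary also traps
gradient optimizers, the random-slope fit is guarded: the nested model
is fitted alongside, and if the alternative's likelihood falls below it
the fit is retried warm-started from the nested solution and with
Powell's method, keeping the best likelihood.

**Stream-level models.** For a set of areas, fixed effects add
treatment-coded area and hemisphere factors (reference: first area in
hierarchy order, left hemisphere) and optional age interactions; the
default random structure is a random intercept and age slope per area
crossed with a random intercept per infant, implemented as variance
components within a single group (the standard crossed-effects
construction). The random age slope is internally parameterized per
year so its variance is numerically commensurable with the residual
variance. For the cross-stream model a categorical area factor would be
collinear with stream (stream is a function of area), so area enters as
its numeric hierarchy rank (1-based position along the stream) next to
the stream factor — consistent with reporting a single area
coefficient.

**Multiple comparisons.** Per-area analyses use Bonferroni thresholds
α/C with C = k(k−1)/2 for k areas (4→6, 9→36, 8→28), i.e. the pairwise
comparison counts rather than k; a single area is left unadjusted.

## Gene expression screen

Input is a genes × samples RPKM matrix plus sample metadata assigning
each sample to the postnatal target or prenatal control group. Linear
matrices are log2-scaled with a pseudocount (default 1.0; 0 is valid
when all values are positive). Fold change is the difference of group
means of log2 expression (target − control); the linear fold is
2^log2FC. Selection requires linear fold > 4 (equivalently log2FC > 2;
a two-sided |log2FC| mode exists) *and* a per-gene p-value below
5.7×10⁻⁶, treated as a user-supplied Bonferroni-style threshold (an
alternative mode computes 0.05/n_genes). Survivors are ranked by
descending fold change, ties broken by ascending p then symbol.

The per-gene test is the pooled-variance two-sample t-test on log2
values (df = n1 + n2 − 2); Welch's unequal-variance test is selectable.
With very small groups (3 postnatal donors) Welch's effective df drops
to ≈ 2.5 and its p-values cannot reach genome-wide thresholds even for
16-fold effects with tiny variance, so the pooled test — which shares
variance information across the groups — is the default. Degenerate
genes (zero variance in both groups) get p = 1 when group means agree
and p = 0, with a warning, when they differ.

## Dice overlap

dice(A, B) = 2|A∩B|/(|A|+|B|) on voxel index sets in a common grid; the
package does not re-implement surface alignment, so masks must already
live in one index space. Both-empty input is an error. Batch tables
report a group mean ± SD (SD 0, flagged n = 1, for a single pair).

## Synthetic data

The generators produce the study-shaped inputs with known truth:

- **IR voxels**: Rician magnitudes sqrt((S(t)+n1)² + n2²) with n1, n2 ~
  N(0, σ²) per TI — the correct magnitude-image noise model; σ = 0
  reduces exactly to |S(t)|. The study does not fix a voxelwise SNR, so
  the default σ is a free parameter; analyses here use SNR 50 as a
  plausible EPI operating point.
- **Cohort**: 13 infants × 3 timepoints (newborn 8–37 d, 3 mo 78–106 d,
  6 mo 167–195 d), 10 participating per timepoint, 7 complete — the
  default participation matrix assigns three infants two visits and
  three one visit. Ages are integer days uniform in the window
  (day-resolution ages; optionally shared across infants for a balanced
  design). Values follow the random-intercept model exactly; the
  multi-area generator reuses each infant's standardized intercept
  across areas, scaled by the area's τ.
- **Expression**: per-gene log2 baselines N(0, 1), within-group noise
  N(0, 0.1), 7 prenatal vs 3 postnatal samples, 1.2% of 1000 genes
  planted with +4 log2 (16-fold) in the postnatal group; emitted on the
  linear scale as 2^x.
- **Masks**: pairs with exact |A|, |B|, |A∩B| counts in a 10³ grid.

What the generators do *not* emulate: anatomy and spatial correlation,
partial voluming, motion, B1/inversion-efficiency spatial structure,
distortion, nonlinear growth, cross-area residual correlation beyond
the shared infant intercept, RPKM count noise (mean–variance coupling),
or co-expression structure. Passing tests therefore establish that the
estimators recover the generating process at study scale — not that
real acquisitions satisfy these models.

**Problem sizes.** Simulation-based checks use sizes chosen to keep the
whole suite fast while leaving Monte-Carlo error well below the margins
tested: 1000 voxels for noise robustness, 100–200 replicate cohorts for
recovery and coverage, 200–500 replicates for LRT calibration, one
1000-gene screen. Every stochastic routine takes an explicit seed and
is bitwise reproducible.

## Known limitations

- The trajectory model is strictly linear in age, appropriate for 0–6
  months only.
- Crossed random effects run as variance components in a single group;
  very large tables would benefit from a sparse implementation.
- The T1 fitter assumes non-negative magnitude input and a single
  compartment; no B1 or slice-profile correction.
- The gene screen tests each gene independently; no shrinkage or
  empirical-Bayes variance moderation is applied.
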