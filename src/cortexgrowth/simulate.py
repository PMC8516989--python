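"""Synthetic data with known ground truth for every pipeline stage.

Four generators mirror the study's inputs at desk scale:

* inversion-recovery voxel signals on the 20-TI schedule, with Rician
  noise (magnitude of a complex Gaussian) because the fit operates on
  magnitude images;
* a longitudinal cohort of 13 infants scanned at 0, 3 and 6 months
  (10 per timepoint, 7 complete) with per-infant random intercepts and a
  linear age trend per cortical area;
* prenatal/postnatal expression matrices on the RPKM scale with a
  planted set of differentially expressed genes;
* label-mask pairs with exact overlap counts for the Dice check.

Every generator takes an explicit seed and returns ground truth next to
the data, so parameter recovery can be asserted rather than assumed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import CohortDesign, LabelMask, TISchedule, validate_roi_table
from .relaxometry import build_default_schedule

__all__ = [
    "IRSimulationSpec",
    "CohortSimulationSpec",
    "ExpressionSimulationSpec",
    "simulate_ir_voxels",
    "simulate_cohort",
    "simulate_hierarchy",
    "simulate_expression",
    "simulate_mask_pair",
]


@dataclass(frozen=True)
class IRSimulationSpec:
    """True IR curve parameters plus the per-channel Gaussian noise sigma."""

    a: float = 1000.0
    b: float = 2.0
    t1_ms: float = 2000.0
    noise_sigma: float = 0.0
    schedule: TISchedule = field(default_factory=build_default_schedule)
    n_voxels: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.a <= 0 or self.t1_ms <= 0:
            raise ValueError("a and t1_ms must be positive")
        if not 0 <= self.b <= 2.5:
            raise ValueError("b must lie in [0, 2.5]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if self.n_voxels < 1:
            raise ValueError("n_voxels must be at least 1")


def simulate_ir_voxels(spec: IRSimulationSpec) -> tuple[np.ndarray, dict]:
    """Magnitude IR signals, shape (n_voxels, n_TI), plus ground truth.

    Each signal is sqrt((S(t) + n1)^2 + n2^2) with n1, n2 independent
    N(0, sigma^2) per voxel and TI — the Rician magnitude of the signed
    signal S(t) = a(1 - b exp(-t/T1)).  With sigma = 0 the output is
    exactly |S(t)|.
    """
    rng = np.random.default_rng(spec.seed)
    t = spec.schedule.as_array()
    clean = spec.a * (1.0 - spec.b * np.exp(-t / spec.t1_ms))
    if spec.noise_sigma == 0:
        signals = np.tile(np.abs(clean), (spec.n_voxels, 1))
    else:
        n1 = rng.normal(0.0, spec.noise_sigma, size=(spec.n_voxels, t.size))
        n2 = rng.normal(0.0, spec.noise_sigma, size=(spec.n_voxels, t.size))
        signals = np.hypot(clean[None, :] + n1, n2)
    truth = {"a": spec.a, "b": spec.b, "t1_ms": spec.t1_ms,
             "noise_sigma": spec.noise_sigma, "clean_signed": clean}
    return signals, truth


@dataclass(frozen=True)
class CohortSimulationSpec:
    """Linear growth of one area's metric across a longitudinal cohort.

    value = beta0 + u_i + beta1 * age_days + eps, with u_i ~ N(0, tau^2)
    per infant and eps ~ N(0, sigma^2) per row.  Ages are integer days
    drawn uniformly within each timepoint's window; with
    ``shared_ages=True`` every infant is scanned at the same age per
    timepoint (a balanced design).
    """

    design: CohortDesign = field(default_factory=CohortDesign.default)
    beta0: float = 2.0          # metric value at birth (age 0)
    beta1: float = -1.5e-3      # metric units per day
    tau: float = 0.05           # between-infant intercept SD
    sigma: float = 0.03         # residual SD
    area: str = "V1"
    metric: str = "t1_s"
    hemispheres: tuple[str, ...] = ("left", "right")
    shared_ages: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tau < 0 or self.sigma < 0:
            raise ValueError("tau and sigma must be non-negative")


def _draw_ages(design: CohortDesign, rng: np.random.Generator,
               shared: bool) -> pd.DataFrame:
    """Integer scan ages (days), one per participating infant x timepoint."""
    ages = pd.DataFrame(index=design.infants, columns=design.timepoints, dtype=float)
    for tp in design.timepoints:
        lo, hi = design.age_windows[tp]
        if shared:
            ages[tp] = float(rng.integers(lo, hi + 1))
        else:
            ages[tp] = rng.integers(lo, hi + 1, size=design.n_infants).astype(float)
    return ages


def simulate_cohort(spec: CohortSimulationSpec,
                    _ages: pd.DataFrame | None = None,
                    _u: pd.Series | None = None) -> tuple[pd.DataFrame, dict]:
    """One area's longitudinal ROI table plus the generating ground truth."""
    design = spec.design
    rng = np.random.default_rng(spec.seed)
    ages = _draw_ages(design, rng, spec.shared_ages) if _ages is None else _ages
    if _u is None:
        u = pd.Series(rng.normal(0.0, spec.tau, size=design.n_infants),
                      index=design.infants)
    else:
        u = _u * spec.tau
    rows = []
    for infant in design.infants:
        for tp in design.timepoints:
            if not design.participation.loc[infant, tp]:
                continue
            age = int(ages.loc[infant, tp])
            for hemi in spec.hemispheres:
                eps = rng.normal(0.0, spec.sigma)
                value = spec.beta0 + u[infant] + spec.beta1 * age + eps
                rows.append((infant, age, tp, hemi, spec.area, spec.metric, value))
    table = validate_roi_table(pd.DataFrame(rows, columns=[
        "infant_id", "age_days", "timepoint", "hemisphere", "area", "metric", "value"
    ]))
    truth = {"beta0": spec.beta0, "beta1": spec.beta1, "tau": spec.tau,
             "sigma": spec.sigma, "random_intercepts": u.to_dict(),
             "ages": ages.to_dict()}
    return table, truth


def simulate_hierarchy(area_specs: list[CohortSimulationSpec]) -> tuple[pd.DataFrame, dict]:
    """A combined multi-area table reusing one set of infant random effects.

    All specs must share the same cohort design (one scan per infant and
    timepoint serves every area); each infant's standardized random
    intercept is reused across areas, scaled by each area's tau.
    """
    if not area_specs:
        raise ValueError("need at least one area spec")
    design = area_specs[0].design
    for s in area_specs[1:]:
        if not s.design.participation.equals(design.participation) or \
                s.design.age_windows != design.age_windows:
            raise ValueError("all area specs must share one cohort design")
    names = [s.area for s in area_specs]
    if len(set(names)) != len(names):
        raise ValueError("area names must be distinct")
    rng = np.random.default_rng(area_specs[0].seed)
    ages = _draw_ages(design, rng, area_specs[0].shared_ages)
    z = pd.Series(rng.normal(0.0, 1.0, size=design.n_infants), index=design.infants)
    sub_seeds = rng.integers(0, 2**31, size=len(area_specs))
    tables, truths = [], {}
    for i, s in enumerate(area_specs):
        sub = replace(s, seed=int(sub_seeds[i]))
        tbl, truth = simulate_cohort(sub, _ages=ages, _u=z)
        tables.append(tbl)
        truths[s.area] = truth
    return validate_roi_table(pd.concat(tables, ignore_index=True)), truths


@dataclass(frozen=True)
class ExpressionSimulationSpec:
    """Prenatal/postnatal RPKM matrices with a planted DE gene set.

    Per-gene baselines are drawn on the log2 scale; planted genes get
    ``de_log2_effect`` added in the postnatal (target) group; the matrix
    is emitted on the linear RPKM scale as 2**x.  Defaults mirror a
    desk-scale screen: 1000 genes, 7 prenatal vs 3 postnatal donors,
    12 planted genes at 16-fold.
    """

    n_genes: int = 1000
    n_target_samples: int = 3      # postnatal donors
    n_control_samples: int = 7     # prenatal donors
    baseline_log2_mean: float = 0.0
    baseline_log2_sd: float = 1.0
    de_gene_fraction: float = 0.012
    de_log2_effect: float = 4.0    # 16-fold
    within_group_log2_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_target_samples < 2 or self.n_control_samples < 2:
            raise ValueError("need at least 2 samples per group")
        if not 0 <= self.de_gene_fraction <= 1:
            raise ValueError("de_gene_fraction must lie in [0, 1]")
        if not np.isfinite(self.de_log2_effect) or self.de_log2_effect <= 0:
            raise ValueError("de_log2_effect must be positive and finite")


def simulate_expression(spec: ExpressionSimulationSpec):
    """Returns (linear-scale matrix, sample metadata, planted gene set)."""
    rng = np.random.default_rng(spec.seed)
    genes = [f"GENE{i:05d}" for i in range(1, spec.n_genes + 1)]
    n_t, n_c = spec.n_target_samples, spec.n_control_samples
    samples = [f"post{i:02d}" for i in range(1, n_t + 1)] + \
              [f"pre{i:02d}" for i in range(1, n_c + 1)]
    baseline = rng.normal(spec.baseline_log2_mean, spec.baseline_log2_sd, spec.n_genes)
    log2 = baseline[:, None] + rng.normal(
        0.0, spec.within_group_log2_sd, size=(spec.n_genes, n_t + n_c))
    n_de = int(round(spec.de_gene_fraction * spec.n_genes))
    de_idx = rng.choice(spec.n_genes, size=n_de, replace=False)
    log2[de_idx, :n_t] += spec.de_log2_effect
    matrix = pd.DataFrame(2.0 ** log2, index=pd.Index(genes, name="gene"),
                          columns=samples)
    meta = pd.DataFrame({
        "sample_id": samples,
        "group": ["target_postnatal"] * n_t + ["control_prenatal"] * n_c,
        "region": ["V1"] * (n_t + n_c),
        "age_label": ["4 mos"] * n_t + ["21 pcw"] * n_c,
    })
    planted = sorted(genes[i] for i in de_idx)
    return matrix, meta, planted


def simulate_mask_pair(n_a: int, n_b: int, n_overlap: int,
                       grid_shape=(10, 10, 10), seed: int = 0):
    """Two label masks with |A| = n_a, |B| = n_b, |A∩B| = n_overlap exactly."""
    if n_overlap > min(n_a, n_b):
        raise ValueError("overlap cannot exceed either mask size")
    if min(n_a, n_b) < 0 or n_overlap < 0:
        raise ValueError("counts must be non-negative")
    n_total = int(np.prod(grid_shape))
    if n_a + n_b - n_overlap > n_total:
        raise ValueError("masks do not fit in the grid")
    rng = np.random.default_rng(seed)
    voxels = rng.choice(n_total, size=n_a + n_b - n_overlap, replace=False)
    shared = voxels[:n_overlap]
    only_a = voxels[n_overlap: n_overlap + (n_a - n_overlap)]
    only_b = voxels[n_overlap + (n_a - n_overlap):]
    mask_a = LabelMask(np.concatenate([shared, only_a]), grid_shape, "A")
    mask_b = LabelMask(np.concatenate([shared, only_b]), grid_shape, "B")
    return mask_a, mask_b
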