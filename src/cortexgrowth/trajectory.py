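"""Longitudinal mixed-model trajectories of cortical ROI metrics.

Each cortical area's mean metric (T1, R1 or MD) is modelled as a linear
function of postnatal age in days with a random intercept per infant,

    value_ij = beta0 + u_i + beta1 * age_ij + eps_ij,   u_i ~ N(0, tau^2),

so the fixed intercept estimates the metric at birth (age 0) and the
fixed slope its rate of change per day.  A random-slope alternative and
likelihood-ratio model comparison are available, as are stream-level
models with area/hemisphere/stream factors and their age interactions.
Estimation is delegated to :class:`statsmodels.regression.mixed_linear_model.MixedLM`;
this module owns the model specification, the birth-intercept
parameterisation (age is never centred), inference conventions
(t statistics on residual degrees of freedom) and the Bonferroni
bookkeeping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf

from .core import LabelMask, QuantitativeMap, validate_roi_table

__all__ = [
    "DORSAL_AREAS", "VENTRAL_AREAS", "SENSORIMOTOR_AREAS",
    "LMMSpec", "TrajectoryModel", "TrajectoryResults", "ModelComparison",
    "roi_distribution", "build_roi_table",
    "fit_lmm", "compare_lmm", "fit_per_area", "fit_stream_lmm",
    "pairwise_comparison_count", "bonferroni_threshold",
]

#: Retinotopic areas in hierarchical order, per stream.
DORSAL_AREAS = ("V1d", "V2d", "V3d", "V3A", "V3B", "IPS0", "IPS1", "IPS2", "IPS3")
VENTRAL_AREAS = ("V1v", "V2v", "V3v", "hV4", "VO1", "VO2", "PHC1", "PHC2")
SENSORIMOTOR_AREAS = ("V1", "A1", "S1", "M1")

_STREAM_OF = {a: "dorsal" for a in DORSAL_AREAS}
_STREAM_OF.update({a: "ventral" for a in VENTRAL_AREAS})


def area_stream(area: str) -> str:
    try:
        return _STREAM_OF[area]
    except KeyError:
        raise KeyError(f"area {area!r} is not in a known visual stream") from None


def area_hierarchy_rank(area: str) -> int:
    """1-based position of an area along its visual stream hierarchy."""
    for stream in (DORSAL_AREAS, VENTRAL_AREAS):
        if area in stream:
            return stream.index(area) + 1
    raise KeyError(f"area {area!r} is not in a known visual stream")


def pairwise_comparison_count(k: int) -> int:
    """Number of pairwise comparisons among k areas: k(k-1)/2."""
    if k < 1:
        raise ValueError("need at least one area")
    return k * (k - 1) // 2


def bonferroni_threshold(alpha: float, k_areas: int) -> float:
    """Per-test alpha after Bonferroni over the k(k-1)/2 pairwise comparisons.

    A single area involves no multiple comparisons: alpha is unadjusted.
    """
    c = pairwise_comparison_count(k_areas)
    return alpha / c if c else alpha


# ---------------------------------------------------------------------------
# ROI aggregation

@dataclass(frozen=True)
class ROISummary:
    mean: float
    sd: float
    n: int
    hist_counts: np.ndarray
    hist_edges: np.ndarray


def roi_distribution(qmap: QuantitativeMap, mask: LabelMask, bins: int = 50) -> ROISummary:
    """Distribution of finite map values inside a label mask."""
    if mask.shape != qmap.shape:
        raise ValueError(f"mask grid {mask.shape} != map grid {qmap.shape}")
    vals = qmap.values.ravel()[mask.indices]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError(f"mask {mask.label!r} contains no finite voxels")
    counts, edges = np.histogram(vals, bins=bins)
    return ROISummary(float(vals.mean()), float(vals.std(ddof=0)), int(vals.size),
                      counts, edges)


def build_roi_table(maps: dict, masks: dict, ages: dict) -> pd.DataFrame:
    """Aggregate per-scan maps into a tidy longitudinal ROI table.

    Parameters
    ----------
    maps : {(infant_id, timepoint): QuantitativeMap or list thereof}
        One or more metric maps per scan.
    masks : {(area, hemisphere): LabelMask}
    ages : {(infant_id, timepoint): age in days}
    """
    rows = []
    for (infant, tp), scan_maps in maps.items():
        if isinstance(scan_maps, QuantitativeMap):
            scan_maps = [scan_maps]
        age = ages[(infant, tp)]
        for qmap in scan_maps:
            for (area, hemi), mask in masks.items():
                if mask is None:
                    raise ValueError(f"missing mask for area {area!r}")
                summ = roi_distribution(qmap, mask)
                rows.append((infant, age, tp, hemi, area, qmap.metric, summ.mean))
    return validate_roi_table(pd.DataFrame(rows, columns=[
        "infant_id", "age_days", "timepoint", "hemisphere", "area", "metric", "value"
    ]))


# ---------------------------------------------------------------------------
# Mixed models

#: Random-effect presets.
#: infant                - random intercept per infant (the per-area default)
#: infant+slope          - random intercept and age slope per infant
#: area+infant           - random intercept and age slope per area, crossed
#:                         with a random intercept per infant (stream default)
#: area                  - random intercept and age slope per area only
RANDOM_PRESETS = ("infant", "infant+slope", "area+infant", "area")


@dataclass(frozen=True)
class LMMSpec:
    """Specification of one linear mixed model on an ROI table."""

    metric: str = "t1_s"
    factors: tuple[str, ...] = ()          # among {"area", "hemisphere", "stream"}
    age_interactions: tuple[str, ...] = () # factors whose age interaction is included
    random: str = "infant"
    criterion: str = "reml"

    def __post_init__(self) -> None:
        if self.random not in RANDOM_PRESETS:
            raise ValueError(f"random must be one of {RANDOM_PRESETS}")
        if self.criterion not in ("ml", "reml"):
            raise ValueError("criterion must be 'ml' or 'reml'")
        bad = set(self.factors) - {"area", "hemisphere", "stream", "area_rank"}
        if bad:
            raise ValueError(f"unknown factors {sorted(bad)}")
        if "area" in self.factors and "stream" in self.factors:
            raise ValueError(
                "categorical area and stream are collinear (stream is a "
                "function of area); use area_rank with stream")
        if not set(self.age_interactions) <= set(self.factors):
            raise ValueError("age_interactions must be a subset of factors")


@dataclass
class ModelComparison:
    loglik_null: float
    loglik_alt: float
    lr_stat: float
    df_diff: int
    p_value: float


class TrajectoryModel:
    """A linear mixed model of one metric's growth, statsmodels-style.

    Build from a tidy ROI table (``from_roi_table``) or directly; ``fit``
    returns a :class:`TrajectoryResults`.
    """

    def __init__(self, table: pd.DataFrame, spec: LMMSpec):
        table = validate_roi_table(table)
        data = table[table["metric"] == spec.metric].copy()
        if data.empty:
            raise ValueError(f"no rows with metric {spec.metric!r}")
        if "stream" in spec.factors:
            data["stream"] = [area_stream(a) for a in data["area"]]
        if "area_rank" in spec.factors:
            data["area_rank"] = [area_hierarchy_rank(a) for a in data["area"]]
        self.spec = spec
        self.data = data.reset_index(drop=True)
        self._validate_design()

    @classmethod
    def from_roi_table(cls, table: pd.DataFrame, metric: str = "t1_s",
                       **spec_kwargs) -> "TrajectoryModel":
        return cls(table, LMMSpec(metric=metric, **spec_kwargs))

    # -- internals ----------------------------------------------------------

    def _validate_design(self) -> None:
        d = self.data
        if d["age_days"].nunique() < 2:
            raise ValueError("need at least 2 distinct ages")
        if self.spec.random in ("infant", "infant+slope") and d["infant_id"].nunique() < 2:
            raise ValueError("need at least 2 infants for infant random effects")
        if self.spec.random in ("area+infant", "area") and d["area"].nunique() < 2:
            raise ValueError("need at least 2 areas for area random effects")
        for f in self.spec.factors:
            if d[f].nunique() < 2:
                raise ValueError(f"factor {f!r} needs at least 2 levels")

    def _ordered_levels(self, factor: str) -> list[str]:
        levels = sorted(self.data[factor].unique())
        if factor == "area":
            order = list(DORSAL_AREAS) + list(VENTRAL_AREAS) + list(SENSORIMOTOR_AREAS)
            known = [a for a in order if a in levels]
            levels = known + [a for a in levels if a not in known]
        elif factor == "hemisphere":
            levels = [h for h in ("left", "right") if h in levels]
        elif factor == "stream":
            levels = [s for s in ("dorsal", "ventral") if s in levels]
        return levels

    def _term(self, factor: str) -> str:
        if factor == "area_rank":  # numeric hierarchy position
            return "area_rank"
        lv = self._ordered_levels(factor)
        return f"C({factor}, Treatment('{lv[0]}'))"

    def _formula(self) -> str:
        terms = ["age_days"]
        terms += [self._term(f) for f in self.spec.factors]
        terms += [f"age_days:{self._term(f)}" for f in self.spec.age_interactions]
        return "value ~ " + " + ".join(terms)

    def _build(self):
        d = self.data
        rnd = self.spec.random
        if rnd in ("infant", "infant+slope"):
            re_formula = "~age_days" if rnd == "infant+slope" else "~1"
            return smf.mixedlm(self._formula(), d, groups=d["infant_id"],
                               re_formula=re_formula)
        # crossed random effects via variance components in a single group;
        # the random age slope uses a per-year column so its variance is on
        # a scale the optimizer can resolve against the residual variance
        d = d.assign(age_years=d["age_days"] / 365.25)
        vcf = {"area_intercept": "0 + C(area)",
               "area_slope": "0 + C(area):age_years"}
        if rnd == "area+infant":
            vcf["infant_intercept"] = "0 + C(infant_id)"
        return smf.mixedlm(self._formula(), d, groups=np.ones(len(d)),
                           vc_formula=vcf, re_formula="0")

    # -- fitting ------------------------------------------------------------

    def fit(self, criterion: str | None = None, **fit_kwargs) -> "TrajectoryResults":
        """Fit by REML (default, for reported coefficients) or ML (for LRTs)."""
        criterion = (criterion or self.spec.criterion).lower()
        if criterion not in ("ml", "reml"):
            raise ValueError("criterion must be 'ml' or 'reml'")
        model = self._build()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(reml=(criterion == "reml"), **fit_kwargs)
            if self.spec.random == "infant+slope":
                res = self._best_against_nested(model, res, criterion, fit_kwargs)
        if not np.all(np.isfinite(res.fe_params)) or not np.isfinite(res.llf):
            raise RuntimeError(
                f"mixed model did not converge to finite estimates "
                f"(converged={res.converged}); formula: {self._formula()}")
        return TrajectoryResults(self, res, criterion)

    def _best_against_nested(self, model, res, criterion: str, fit_kwargs):
        """Guard the random-slope fit against local optima.

        The random-intercept model lies on the boundary of the
        random-slope parameter space, so the slope model's maximized
        likelihood can never genuinely be lower; when the optimizer
        lands below it, refit warm-started from the nested solution
        (slope variance near zero) and keep the better fit.
        """
        from statsmodels.regression.mixed_linear_model import MixedLMParams

        nested_spec = LMMSpec(metric=self.spec.metric, factors=self.spec.factors,
                              age_interactions=self.spec.age_interactions,
                              random="infant", criterion=criterion)
        nested = TrajectoryModel(self.data, nested_spec)._build().fit(
            reml=(criterion == "reml"))
        if res.llf >= nested.llf - 1e-10:
            return res
        scale = max(float(nested.scale), 1e-12)
        tau2 = float(np.atleast_2d(np.asarray(nested.cov_re))[0, 0]) / scale
        age_scale = float(np.square(self.data["age_days"]).mean())
        cov0 = np.array([[max(tau2, 1e-8), 0.0], [0.0, 1e-8 / age_scale]])
        start = MixedLMParams.from_components(
            fe_params=np.asarray(nested.fe_params), cov_re=cov0)
        best = res
        for kwargs in ({"start_params": start}, {"method": "powell"},
                       {"method": "powell", "start_params": start}):
            try:
                cand = model.fit(reml=(criterion == "reml"), **{**fit_kwargs, **kwargs})
            except Exception:
                continue
            if np.isfinite(cand.llf) and cand.llf > best.llf:
                best = cand
            if best.llf >= nested.llf - 1e-10:
                break
        return best


class TrajectoryResults:
    """Estimates, uncertainties and diagnostics of one fitted trajectory LMM.

    Fixed-effect p-values use t statistics with residual degrees of
    freedom (n_obs - n_fixed); variance components are reported as SDs
    alongside variances.
    """

    def __init__(self, model: TrajectoryModel, sm_result, criterion: str):
        self.model = model
        self._res = sm_result
        self.criterion = criterion
        self.n_obs = int(sm_result.model.exog.shape[0])
        self.k_fixed = int(sm_result.model.exog.shape[1])
        self.df_resid = self.n_obs - self.k_fixed
        self.loglik = float(sm_result.llf)
        self.converged = bool(sm_result.converged)

    # -- fixed effects ------------------------------------------------------

    @property
    def fe_table(self) -> pd.DataFrame:
        """Per fixed term: estimate, se, t, df, p."""
        est = self._res.fe_params
        se = self._res.bse_fe
        t = est / se
        p = 2.0 * stats.t.sf(np.abs(t), self.df_resid)
        return pd.DataFrame({
            "estimate": est, "se": se, "t": t,
            "df": self.df_resid, "p": p,
        })

    @property
    def intercept(self) -> float:
        """Estimated metric value at birth (age 0)."""
        return float(self._res.fe_params["Intercept"])

    @property
    def slope(self) -> float:
        """Estimated change in the metric per day of age."""
        return float(self._res.fe_params["age_days"])

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        """t-based confidence intervals for the fixed effects."""
        q = stats.t.ppf(1.0 - alpha / 2.0, self.df_resid)
        est, se = self._res.fe_params, self._res.bse_fe
        return pd.DataFrame({"lower": est - q * se, "upper": est + q * se})

    # -- variance components ------------------------------------------------

    @property
    def variance_components(self) -> dict:
        out = {}
        mdl = self._res.model
        if mdl.k_re:
            cov = np.atleast_2d(np.asarray(self._res.cov_re))
            names = mdl.data.exog_re_names
            for i, nm in enumerate(names):
                key = "intercept" if nm in ("Intercept", "Group") else nm
                out[f"var_{key}"] = float(cov[i, i])
            if mdl.k_re == 2:
                out["cov_intercept_slope"] = float(cov[0, 1])
        if mdl.k_vc:
            for nm, v in zip(mdl.exog_vc.names, np.asarray(self._res.vcomp)):
                out[f"var_{nm}"] = float(v)
        out["var_residual"] = float(self._res.scale)
        return out

    @property
    def n_parameters(self) -> int:
        """Fixed effects + covariance parameters (incl. residual variance)."""
        mdl = self._res.model
        q = mdl.k_re
        return self.k_fixed + q * (q + 1) // 2 + mdl.k_vc + 1

    @property
    def r_squared(self) -> float:
        """Squared correlation of fitted (incl. random effects) vs observed."""
        fitted = np.asarray(self._res.fittedvalues, dtype=float)
        obs = np.asarray(self.model.data["value"], dtype=float)
        c = np.corrcoef(fitted, obs)[0, 1]
        return float(c ** 2)

    # -- presentation -------------------------------------------------------

    def summary(self) -> str:
        spec = self.model.spec
        lines = [
            "Cortical trajectory linear mixed model",
            "=" * 54,
            f"Metric: {spec.metric}    Criterion: {self.criterion.upper()}",
            f"Random effects: {spec.random}    n_obs: {self.n_obs}",
            f"Log-likelihood: {self.loglik:.4f}    R^2 (fit vs obs): {self.r_squared:.4f}",
            "",
            "Fixed effects (intercept = value at birth; age slope per day):",
            self.fe_table.to_string(float_format=lambda v: f"{v:.6g}"),
            "",
            "Variance components:",
        ]
        for k, v in self.variance_components.items():
            lines.append(f"  {k}: {v:.6g}")
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (f"<TrajectoryResults metric={self.model.spec.metric!r} "
                f"intercept={self.intercept:.4g} slope={self.slope:.4g} "
                f"n_obs={self.n_obs}>")


# ---------------------------------------------------------------------------
# Functional surface

def fit_lmm(table: pd.DataFrame, spec: LMMSpec | None = None,
            **spec_kwargs) -> TrajectoryResults:
    """Fit one LMM on a (subset of a) tidy ROI table."""
    spec = spec or LMMSpec(**spec_kwargs)
    return TrajectoryModel(table, spec).fit()


def compare_lmm(fit_null: TrajectoryResults, fit_alt: TrajectoryResults) -> ModelComparison:
    """Likelihood-ratio test of two nested ML fits on identical rows.

    LR = 2*(llf_alt - llf_null), referred to a chi-square with df equal
    to the parameter-count difference.  Variance parameters on the
    boundary make this conservative.
    """
    for f in (fit_null, fit_alt):
        if f.criterion != "ml":
            raise ValueError("likelihood-ratio comparison requires ML fits (criterion='ml')")
    if fit_null.n_obs != fit_alt.n_obs:
        raise ValueError("fits must use identical rows")
    if not np.array_equal(fit_null._res.model.exog, fit_alt._res.model.exog):
        raise ValueError("fits must share the same fixed-effect design")
    df = fit_alt.n_parameters - fit_null.n_parameters
    if df < 0:
        raise ValueError("null model is not nested in the alternative")
    lr = 2.0 * (fit_alt.loglik - fit_null.loglik)
    lr = max(lr, 0.0)
    if df == 0:  # identical specifications
        p = 1.0 if lr < 1e-8 else 0.0
    else:
        p = float(stats.chi2.sf(lr, df))
    return ModelComparison(fit_null.loglik, fit_alt.loglik, lr, df, p)


def fit_per_area(table: pd.DataFrame, areas, metric: str = "t1_s",
                 alpha: float = 0.05, hemisphere: str | None = None,
                 random: str = "infant") -> pd.DataFrame:
    """Per-area birth-value/slope LMM fits with Bonferroni-adjusted flags.

    The adjusted threshold is alpha / C with C = k(k-1)/2 pairwise
    comparisons among the k areas (4 areas -> 6, 9 -> 36, 8 -> 28).
    Returns one row per area: intercept, slope, their SEs and p-values,
    and significance at the adjusted threshold.
    """
    areas = list(areas)
    table = validate_roi_table(table)
    if hemisphere is not None:
        table = table[table["hemisphere"] == hemisphere]
    threshold = bonferroni_threshold(alpha, len(areas))
    rows = []
    for area in areas:
        sub = table[(table["area"] == area) & (table["metric"] == metric)]
        if sub.empty:
            raise ValueError(f"area {area!r} missing from table")
        res = fit_lmm(sub, LMMSpec(metric=metric, random=random))
        fe = res.fe_table
        rows.append({
            "area": area,
            "intercept": res.intercept,
            "intercept_se": fe.loc["Intercept", "se"],
            "intercept_p": fe.loc["Intercept", "p"],
            "slope": res.slope,
            "slope_se": fe.loc["age_days", "se"],
            "slope_p": fe.loc["age_days", "p"],
            "n_obs": res.n_obs,
            "r_squared": res.r_squared,
            "slope_significant": fe.loc["age_days", "p"] < threshold,
        })
    out = pd.DataFrame(rows).set_index("area")
    out.attrs["alpha"] = alpha
    out.attrs["n_comparisons"] = pairwise_comparison_count(len(areas))
    out.attrs["adjusted_threshold"] = threshold
    return out


def fit_stream_lmm(table: pd.DataFrame, metric: str = "t1_s",
                   factors: tuple[str, ...] = ("area", "hemisphere"),
                   age_interactions: tuple[str, ...] = (),
                   random: str = "area+infant",
                   criterion: str = "reml") -> TrajectoryResults:
    """Stream-level LMM with age plus categorical factors.

    Defaults model one stream's areas with treatment-coded area and
    hemisphere effects, random intercept and age slope per area crossed
    with a random intercept per infant.  For the cross-stream model use
    ``factors=("area", "stream")``.
    """
    spec = LMMSpec(metric=metric, factors=tuple(factors),
                   age_interactions=tuple(age_interactions),
                   random=random, criterion=criterion)
    return TrajectoryModel(table, spec).fit()
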