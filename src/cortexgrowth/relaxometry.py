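"""Voxelwise T1 estimation from magnitude inversion-recovery signals.

The recovery of longitudinal magnetization after an inversion pulse is an
exponential in the inversion time t:

    S(t) = a * (1 - b * exp(-t / T1))

with ``a`` proportional to the initial magnetization, ``b`` the effective
inversion coefficient (2 for a perfect inversion), and ``T1`` the
longitudinal relaxation time.  Scanner magnitude images discard the sign
of S, so the model actually fitted to the data is ``|S(t)|``.  The kink
that the absolute value introduces at the null point is handled by
multistart nonlinear least squares seeded from a profiled grid search
over T1; for a fixed T1 and a fixed sign pattern the magnitude model is
linear in (a, a*b), and because the model is monotone in exp(-t/T1) only
the single-crossing sign patterns can be optimal, so the grid profile is
exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .core import QuantitativeMap, TISchedule

__all__ = [
    "FitOptions",
    "T1FitResult",
    "build_default_schedule",
    "predict_ir_signal",
    "fit_t1_voxel",
    "fit_t1_volume",
    "compute_r1_map",
]

LN2 = float(np.log(2.0))


def build_default_schedule() -> TISchedule:
    """The 20-TI schedule: 50 ms first TI, 150 ms spacing (50 ... 2900 ms)."""
    return TISchedule(50.0 + 150.0 * np.arange(20))


def predict_ir_signal(a: float, b: float, t1_ms: float, schedule: TISchedule) -> np.ndarray:
    """Magnitude IR signal |a(1 - b exp(-t/T1))| at each inversion time."""
    if t1_ms <= 0:
        raise ValueError(f"t1_ms must be positive, got {t1_ms}")
    t = schedule.as_array()
    return np.abs(a * (1.0 - b * np.exp(-t / t1_ms)))


@dataclass(frozen=True)
class FitOptions:
    """Controls for the voxelwise magnitude IR fit.

    T1 bounds default to 50-10000 ms, wide around infant cortex
    (~1500-2500 ms); b is bounded in [0, 2.5] around the perfect-inversion
    value 2; the amplitude is bounded by 10x the largest observed signal.
    """

    t1_bounds_ms: tuple[float, float] = (50.0, 10000.0)
    b_bounds: tuple[float, float] = (0.0, 2.5)
    max_iter: int = 500
    sse_rtol: float = 1e-10
    extra_t1_starts_ms: tuple[float, ...] = (500.0, 2500.0)
    t1_grid_step_ms: float = 20.0
    r2_exclude_below: float | None = None  # no R^2 exclusion by default

    def __post_init__(self) -> None:
        lo, hi = self.t1_bounds_ms
        if not (0 < lo < hi):
            raise ValueError("t1 bounds must be positive and ordered")
        blo, bhi = self.b_bounds
        if not (0 <= blo < bhi):
            raise ValueError("b bounds must be non-negative and ordered")


@dataclass(frozen=True)
class T1FitResult:
    a: float
    b: float
    t1_ms: float
    r_squared: float
    converged: bool
    n_starts_tried: int
    sse: float


_SENTINEL = T1FitResult(np.nan, np.nan, np.nan, np.nan, False, 0, np.nan)


def _sign_patterns(n: int) -> np.ndarray:
    """All single-crossing sign vectors (-1...-1, +1...+1), shape (n+1, n)."""
    s = np.ones((n + 1, n))
    for k in range(n + 1):
        s[k, :k] = -1.0
    return s


def _profile_grid(y: np.ndarray, t: np.ndarray, t1_grid: np.ndarray,
                  b_bounds: tuple[float, float], a_max: float):
    """Exact profile of the magnitude SSE over a T1 grid.

    For each grid T1 the signed model c0 + c1*exp(-t/T1) is fit by linear
    least squares under every single-crossing sign pattern; infeasible
    solutions (a <= 0 or b outside bounds) fall back to b clamped at its
    bounds with the amplitude profiled alone.  Returns the best
    (sse, a, b, t1) found.
    """
    n = y.size
    S = _sign_patterns(n)                      # (P, n)
    Z = S * y                                  # signed data per pattern
    E = np.exp(-np.outer(1.0 / t1_grid, t))    # (G, n)
    s1e = E.sum(axis=1)                        # (G,)
    see = (E * E).sum(axis=1)
    sz = Z.sum(axis=1)                         # (P,)
    sze = E @ Z.T                              # (G, P)
    syy = float(y @ y)

    det = n * see - s1e ** 2
    det = np.where(np.abs(det) < 1e-30, np.nan, det)
    c0 = (see[:, None] * sz[None, :] - s1e[:, None] * sze) / det[:, None]
    c1 = (n * sze - s1e[:, None] * sz[None, :]) / det[:, None]
    sse = syy - c0 * sz[None, :] - c1 * sze
    with np.errstate(invalid="ignore", divide="ignore"):
        b = -c1 / c0
    feasible = (c0 > 0) & (c0 <= a_max) & (b >= b_bounds[0]) & (b <= b_bounds[1])
    sse = np.where(feasible, sse, np.inf)

    # b clamped at its bounds, amplitude profiled in closed form
    for b_fix in b_bounds:
        g = 1.0 - b_fix * E                    # (G, n)
        gg = (g * g).sum(axis=1)
        gg = np.where(gg < 1e-30, np.nan, gg)
        a_fix = (g @ Z.T) / gg[:, None]        # (G, P)
        sse_fix = syy - a_fix ** 2 * gg[:, None]
        ok = (a_fix > 0) & (a_fix <= a_max)
        sse_fix = np.where(ok, sse_fix, np.inf)
        better = sse_fix < sse
        sse = np.where(better, sse_fix, sse)
        c0 = np.where(better, a_fix, c0)
        b = np.where(better, b_fix, b)

    if not np.isfinite(sse).any():
        return None
    g_idx, p_idx = np.unravel_index(np.nanargmin(sse), sse.shape)
    return float(sse[g_idx, p_idx]), float(c0[g_idx, p_idx]), float(b[g_idx, p_idx]), float(t1_grid[g_idx])


def _residual_and_jac(t: np.ndarray, y: np.ndarray):
    """Residual |model| - y and its Jacobian on the signed model.

    The gradient of |m| is sign(m) * dm; at the kink (m = 0) the
    subgradient convention sign = +1 is used.
    """

    def resid(theta):
        a, b, t1 = theta
        return np.abs(a * (1.0 - b * np.exp(-t / t1))) - y

    def jac(theta):
        a, b, t1 = theta
        e = np.exp(-t / t1)
        m = a * (1.0 - b * e)
        s = np.where(m >= 0, 1.0, -1.0)
        return np.column_stack((
            s * (1.0 - b * e),
            s * (-a * e),
            s * (-a * b * e * t / t1 ** 2),
        ))

    return resid, jac


def fit_t1_voxel(series: np.ndarray, schedule: TISchedule,
                 options: FitOptions | None = None) -> T1FitResult:
    """Fit (a, b, T1) of the magnitude IR model to one voxel's signals.

    Minimizes the sum of squared differences between the observed
    magnitudes and |a(1 - b exp(-t/T1))| by bounded nonlinear least
    squares from multiple starts; the best start wins.  R^2 is computed
    about the series mean.
    """
    options = options or FitOptions()
    y = np.asarray(series, dtype=float).ravel()
    t = schedule.as_array()
    if y.size != t.size:
        raise ValueError(f"series length {y.size} != schedule length {t.size}")
    if np.isnan(y).any():
        raise ValueError("series contains NaN")
    if (y < 0).any():
        raise ValueError("magnitude signals must be non-negative")
    sst = float(((y - y.mean()) ** 2).sum())
    if sst == 0.0:  # constant (incl. all-zero) series: T1 unidentified
        return _SENTINEL

    t1_lo, t1_hi = options.t1_bounds_ms
    b_lo, b_hi = options.b_bounds
    a_max = 10.0 * float(y.max())

    # multistart seeds: null-point heuristic, fixed seeds, profiled grid best
    t1_null = t[int(np.argmin(y))] / LN2
    starts: list[tuple[float, float, float]] = []
    for t1_0 in (0.5 * t1_null, t1_null, 2.0 * t1_null, *options.extra_t1_starts_ms):
        starts.append((float(y.max()), 2.0, float(np.clip(t1_0, t1_lo, t1_hi))))
    n_grid = max(2, int(np.ceil((t1_hi - t1_lo) / options.t1_grid_step_ms)) + 1)
    grid = np.linspace(t1_lo, t1_hi, n_grid)
    best_grid = _profile_grid(y, t, grid, (b_lo, b_hi), a_max)
    if best_grid is not None:
        _, a_g, b_g, t1_g = best_grid
        starts.append((a_g, float(np.clip(b_g, b_lo, b_hi)), t1_g))

    resid, jac = _residual_and_jac(t, y)
    lower = np.array([0.0, b_lo, t1_lo])
    upper = np.array([a_max, b_hi, t1_hi])
    best = None
    for a0, b0, t1_0 in starts:
        x0 = np.clip([max(a0, 1e-12), b0, t1_0], lower + 1e-12, upper - 1e-12)
        try:
            sol = least_squares(
                resid, x0, jac=jac, bounds=(lower, upper), method="trf",
                ftol=options.sse_rtol, xtol=1e-14, gtol=1e-14,
                max_nfev=options.max_iter * 4,
            )
        except Exception:
            continue
        sse = float(2.0 * sol.cost)
        if best is None or sse < best[0]:
            best = (sse, sol.x)
    if best is None:
        return _SENTINEL
    sse, (a_hat, b_hat, t1_hat) = best
    r2 = 1.0 - sse / sst
    return T1FitResult(
        a=float(a_hat), b=float(b_hat), t1_ms=float(t1_hat),
        r_squared=float(r2), converged=True, n_starts_tried=len(starts),
        sse=sse,
    )


def fit_t1_volume(series_4d: np.ndarray, schedule: TISchedule,
                  options: FitOptions | None = None,
                  mask: np.ndarray | None = None,
                  voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)):
    """Fit every voxel of a 4D (x, y, z, TI) series inside a mask.

    Returns T1 (seconds), R1 (1/s), R^2 and b maps; voxels outside the
    mask, or whose fit fails, are NaN.
    """
    options = options or FitOptions()
    series_4d = np.asarray(series_4d, dtype=float)
    if series_4d.ndim != 4:
        raise ValueError(f"expected 4D series, got shape {series_4d.shape}")
    if series_4d.shape[3] != len(schedule):
        raise ValueError(
            f"series has {series_4d.shape[3]} frames, schedule {len(schedule)} TIs"
        )
    shape = series_4d.shape[:3]
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    mask = np.asarray(mask).astype(bool)
    if mask.shape != shape:
        raise ValueError(f"mask shape {mask.shape} != volume shape {shape}")

    t1 = np.full(shape, np.nan)
    r2 = np.full(shape, np.nan)
    bmap = np.full(shape, np.nan)
    for idx in np.argwhere(mask):
        res = fit_t1_voxel(series_4d[tuple(idx)], schedule, options)
        if not res.converged:
            continue
        if options.r2_exclude_below is not None and res.r_squared < options.r2_exclude_below:
            continue
        i, j, k = idx
        t1[i, j, k] = res.t1_ms / 1000.0
        r2[i, j, k] = res.r_squared
        bmap[i, j, k] = res.b

    t1_map = QuantitativeMap(t1, metric="t1_s", voxel_size_mm=voxel_size_mm)
    r1_map = compute_r1_map(t1_map)
    r2_map = QuantitativeMap(r2, metric="r_squared", voxel_size_mm=voxel_size_mm)
    b_map = QuantitativeMap(bmap, metric="b_dimensionless", voxel_size_mm=voxel_size_mm)
    return t1_map, r1_map, r2_map, b_map


def compute_r1_map(t1_map: QuantitativeMap) -> QuantitativeMap:
    """Relaxation rate R1 = 1/T1 (1/s), elementwise; NaN propagates."""
    if t1_map.metric != "t1_s":
        raise ValueError(f"expected a t1_s map, got {t1_map.metric!r}")
    with np.errstate(divide="ignore", invalid="ignore"):
        r1 = 1.0 / t1_map.values
    return QuantitativeMap(r1, metric="r1_per_s", voxel_size_mm=t1_map.voxel_size_mm)
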