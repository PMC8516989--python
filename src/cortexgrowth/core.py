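"""Shared domain types for quantitative-MRI growth analysis.

The package revolves around a small set of containers: an inversion-time
schedule (:class:`TISchedule`), voxel grids of quantitative metrics
(:class:`QuantitativeMap`), voxel label sets (:class:`LabelMask`), tidy
longitudinal ROI tables (plain :class:`pandas.DataFrame` validated by
:func:`validate_roi_table`), and the longitudinal cohort design
(:class:`CohortDesign`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Recognised quantitative map metrics.
MAP_METRICS = ("t1_s", "r1_per_s", "md_mm2_per_s", "r_squared", "b_dimensionless")

#: Metrics that may appear in a longitudinal ROI table.
ROI_METRICS = ("t1_s", "r1_per_s", "md_mm2_per_s")

TIMEPOINTS = ("newborn", "3mo", "6mo")
HEMISPHERES = ("left", "right")

#: Postnatal age windows (days, inclusive) for each scan timepoint:
#: newborns were scanned at 8-37 days, the 3-month visit at 78-106 days
#: and the 6-month visit at 167-195 days.
AGE_WINDOWS = {"newborn": (8, 37), "3mo": (78, 106), "6mo": (167, 195)}

ROI_TABLE_COLUMNS = (
    "infant_id",
    "age_days",
    "timepoint",
    "hemisphere",
    "area",
    "metric",
    "value",
)

ROI_TABLE_KEY = ("infant_id", "timepoint", "hemisphere", "area", "metric")


@dataclass(frozen=True)
class TISchedule:
    """Ordered inversion times (ms) of an inversion-recovery acquisition.

    At least three distinct times are required to identify the three
    parameters (a, b, T1) of the recovery curve.
    """

    times_ms: tuple[float, ...]

    def __init__(self, times_ms) -> None:
        times = tuple(float(t) for t in times_ms)
        if len(times) < 3:
            raise ValueError(f"need at least 3 inversion times, got {len(times)}")
        if times[0] <= 0:
            raise ValueError("inversion times must be positive")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("inversion times must be strictly increasing")
        object.__setattr__(self, "times_ms", times)

    def __len__(self) -> int:
        return len(self.times_ms)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.times_ms, dtype=float)


@dataclass
class QuantitativeMap:
    """A 3D grid of a quantitative metric; unfit/background voxels are NaN."""

    values: np.ndarray
    metric: str
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(f"map must be 3D, got shape {self.values.shape}")
        if self.metric not in MAP_METRICS:
            raise ValueError(f"unknown metric {self.metric!r}; expected one of {MAP_METRICS}")
        vs = tuple(float(v) for v in self.voxel_size_mm)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError("voxel_size_mm must be 3 positive floats")
        self.voxel_size_mm = vs
        finite = self.values[np.isfinite(self.values)]
        if self.metric in ("t1_s", "r1_per_s") and finite.size and (finite <= 0).any():
            raise ValueError(f"{self.metric} values must be strictly positive where fit")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass(frozen=True)
class LabelMask:
    """A set of voxel indices (flat, row-major) in a fixed grid, with a label.

    Masks live in voxel index space; two masks are comparable only when
    their grids agree.
    """

    indices: np.ndarray
    shape: tuple[int, ...]
    label: str = ""

    def __init__(self, indices, shape, label: str = "") -> None:
        idx = np.asarray(indices, dtype=np.int64).ravel()
        if idx.size and idx.min() < 0:
            raise ValueError("mask indices must be non-negative")
        n_total = int(np.prod(shape))
        if idx.size and idx.max() >= n_total:
            raise ValueError("mask index outside grid")
        uniq = np.unique(idx)
        if uniq.size != idx.size:
            raise ValueError("mask indices must be unique")
        object.__setattr__(self, "indices", uniq)
        object.__setattr__(self, "shape", tuple(int(s) for s in shape))
        object.__setattr__(self, "label", str(label))

    @classmethod
    def from_volume(cls, volume: np.ndarray, label: str = "") -> "LabelMask":
        vol = np.asarray(volume)
        return cls(np.flatnonzero(vol), vol.shape, label)

    def to_volume(self) -> np.ndarray:
        vol = np.zeros(self.shape, dtype=np.uint8)
        vol.ravel()[self.indices] = 1
        return vol

    def __len__(self) -> int:
        return int(self.indices.size)


@dataclass(frozen=True)
class CohortDesign:
    """Which infants are scanned at which timepoints, and the age windows.

    The default mirrors a 13-infant longitudinal cohort with 10 infants
    per timepoint of which seven completed all three visits; the remaining
    six contributed one or two visits each.
    """

    participation: pd.DataFrame  # bool, infants x timepoints
    age_windows: dict = field(default_factory=lambda: dict(AGE_WINDOWS))

    def __post_init__(self) -> None:
        part = self.participation
        if not set(part.columns) <= set(TIMEPOINTS):
            raise ValueError(f"timepoint columns must be among {TIMEPOINTS}")
        if part.dtypes.apply(lambda d: d != bool).any():
            raise ValueError("participation entries must be boolean")
        if (part.sum(axis=0) == 0).any():
            raise ValueError("every timepoint needs at least one participating infant")
        for tp, (lo, hi) in self.age_windows.items():
            if not (0 < lo <= hi):
                raise ValueError(f"bad age window for {tp}: ({lo}, {hi})")

    @property
    def n_infants(self) -> int:
        return len(self.participation)

    @property
    def infants(self) -> list[str]:
        return list(self.participation.index)

    @property
    def timepoints(self) -> list[str]:
        return list(self.participation.columns)

    @classmethod
    def complete(cls, n_infants: int = 13) -> "CohortDesign":
        """Every infant scanned at every timepoint (fully balanced)."""
        infants = [f"infant{i:02d}" for i in range(1, n_infants + 1)]
        part = pd.DataFrame(True, index=infants, columns=list(TIMEPOINTS))
        return cls(part)

    @classmethod
    def default(cls) -> "CohortDesign":
        """13 infants, 3 timepoints, 10 per timepoint, 7 longitudinal."""
        infants = [f"infant{i:02d}" for i in range(1, 14)]
        part = pd.DataFrame(False, index=infants, columns=list(TIMEPOINTS))
        part.iloc[:7, :] = True  # seven complete longitudinal infants
        part.loc["infant08", ["newborn", "3mo"]] = True
        part.loc["infant09", ["3mo", "6mo"]] = True
        part.loc["infant10", ["newborn", "6mo"]] = True
        part.loc["infant11", "newborn"] = True
        part.loc["infant12", "3mo"] = True
        part.loc["infant13", "6mo"] = True
        return cls(part)


def validate_roi_table(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a tidy longitudinal ROI table and return it typed.

    Columns: infant_id, age_days, timepoint, hemisphere, area, metric,
    value. The key (infant_id, timepoint, hemisphere, area, metric) must
    be unique.
    """
    missing = [c for c in ROI_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"ROI table missing columns: {missing}")
    out = table.loc[:, list(ROI_TABLE_COLUMNS)].copy()
    out["infant_id"] = out["infant_id"].astype(str)
    out["age_days"] = out["age_days"].astype(int)
    if (out["age_days"] <= 0).any():
        raise ValueError("age_days must be positive")
    for col, allowed in (
        ("timepoint", TIMEPOINTS),
        ("hemisphere", HEMISPHERES),
        ("metric", ROI_METRICS),
    ):
        bad = set(out[col]) - set(allowed)
        if bad:
            raise ValueError(f"unknown {col} code(s) {sorted(bad)}; expected one of {allowed}")
    out["area"] = out["area"].astype(str)
    out["value"] = out["value"].astype(float)
    dup = out.duplicated(subset=list(ROI_TABLE_KEY))
    if dup.any():
        first = out.loc[dup.idxmax(), list(ROI_TABLE_KEY)]
        raise ValueError(f"duplicate ROI table key: {tuple(first)}")
    return out.reset_index(drop=True)
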