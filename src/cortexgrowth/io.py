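"""Readers and writers for volumes, ROI tables, config, and logging.

Volumes travel as NIfTI-1 with a JSON sidecar carrying the metadata the
container has no canonical field for: the quantitative metric name for 3D
maps, and the inversion-time schedule (key ``"inversion_times_ms"``) for
4D inversion-recovery series.  Tables are tab-separated with fixed
lowercase headers so round-trips are bit-exact across languages.
"""

from __future__ import annotations

import json
import logging
import sys
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .core import QuantitativeMap, TISchedule, validate_roi_table

log = logging.getLogger("cortexgrowth")

_FLOAT_FMT = "%.17g"  # shortest round-trippable float64 text


def _sidecar_path(path) -> Path:
    p = Path(path)
    name = p.name
    for ext in (".nii.gz", ".nii"):
        if name.endswith(ext):
            return p.with_name(name[: -len(ext)] + ".json")
    return p.with_suffix(".json")


def write_volume(qmap: QuantitativeMap, path) -> Path:
    """Write a 3D map as NIfTI plus a JSON sidecar with the metric name."""
    affine = np.diag(list(qmap.voxel_size_mm) + [1.0])
    img = nib.Nifti1Image(qmap.values.astype(np.float64), affine)
    nib.save(img, str(path))
    sidecar = _sidecar_path(path)
    sidecar.write_text(json.dumps({"metric": qmap.metric}, indent=1) + "\n")
    return sidecar


def read_volume(path) -> QuantitativeMap:
    """Read a 3D quantitative map; the metric is taken from the sidecar."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D volume, got shape {data.shape}")
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"missing metric sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    return QuantitativeMap(data, metric=meta["metric"], voxel_size_mm=voxel_size)


def write_ir_series(signals: np.ndarray, schedule: TISchedule, path) -> Path:
    """Write a 4D (x, y, z, TI) magnitude series with its TI sidecar."""
    signals = np.asarray(signals, dtype=np.float64)
    if signals.ndim != 4:
        raise ValueError(f"IR series must be 4D, got shape {signals.shape}")
    if signals.shape[3] != len(schedule):
        raise ValueError(
            f"series has {signals.shape[3]} frames but schedule has {len(schedule)} TIs"
        )
    img = nib.Nifti1Image(signals, np.eye(4))
    nib.save(img, str(path))
    sidecar = _sidecar_path(path)
    sidecar.write_text(
        json.dumps({"inversion_times_ms": list(schedule.times_ms)}, indent=1) + "\n"
    )
    return sidecar


def read_ir_series(path) -> tuple[np.ndarray, TISchedule]:
    """Read a 4D IR series; the TI schedule comes from the JSON sidecar."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 4:
        raise ValueError(f"expected a 4D series, got shape {data.shape}")
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"missing TI sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    if "inversion_times_ms" not in meta:
        raise KeyError(f"sidecar {sidecar} lacks key 'inversion_times_ms'")
    schedule = TISchedule(meta["inversion_times_ms"])
    if data.shape[3] != len(schedule):
        raise ValueError(
            f"series has {data.shape[3]} frames but sidecar {sidecar} "
            f"lists {len(schedule)} inversion times"
        )
    return data, schedule


def write_roi_table(table: pd.DataFrame, path) -> None:
    validate_roi_table(table).to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_roi_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype={"infant_id": str})
    return validate_roi_table(table)


def load_config(path) -> dict:
    """Load a YAML (or JSON, a YAML subset) config file into a dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        cfg = {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping")
    return cfg


def setup_logging(verbose: bool = False) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("cortexgrowth")
    root.handlers[:] = [handler]
    root.setLevel(logging.DEBUG if verbose else logging.INFO)
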