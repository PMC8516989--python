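"""Dice-coefficient quality check on ROI delineations.

Used to quantify how well an atlas-projected region (e.g. the calcarine
sulcus from an adult parcellation) agrees with an individually defined
reference, in voxel index space: dice(A, B) = 2|A∩B| / (|A| + |B|).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import LabelMask

__all__ = ["dice", "dice_table"]


def dice(a: LabelMask, b: LabelMask) -> float:
    """Dice overlap 2|A∩B|/(|A|+|B|) of two masks on the same grid."""
    if a.shape != b.shape:
        raise ValueError(f"masks live in different grids: {a.shape} vs {b.shape}")
    if len(a) == 0 and len(b) == 0:
        raise ValueError("Dice of two empty masks is undefined")
    n_inter = np.intersect1d(a.indices, b.indices, assume_unique=True).size
    return 2.0 * n_inter / (len(a) + len(b))


def dice_table(pairs: dict) -> pd.DataFrame:
    """Dice coefficient per mask pair plus a group mean +/- SD summary.

    Parameters
    ----------
    pairs : {(subject, hemisphere): (LabelMask, LabelMask)}

    Returns a table with one row per pair and a final ``summary`` row
    carrying the group mean and SD (SD 0 by convention when n = 1).
    """
    if not pairs:
        raise ValueError("need at least one mask pair")
    rows = []
    for (subject, hemi), (a, b) in pairs.items():
        rows.append({"subject": subject, "hemisphere": hemi,
                     "dice": dice(a, b)})
    out = pd.DataFrame(rows)
    coeffs = out["dice"].to_numpy()
    sd = float(coeffs.std(ddof=1)) if coeffs.size > 1 else 0.0
    summary = pd.DataFrame([{
        "subject": "summary", "hemisphere": "all",
        "dice": float(coeffs.mean()), "sd": sd, "n": coeffs.size,
    }])
    return pd.concat([out, summary], ignore_index=True)
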