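"""The linear relation between myelin content and relaxation rate.

R1 = 1/T1 increases approximately linearly with the voxel myelin
fraction, R1(mf) = c0 + c1*mf, which makes R1 the natural scale on which
to compare growth rates across cortical areas: an equal myelin increment
produces an equal R1 increment everywhere, whereas the corresponding T1
change shrinks as the baseline myelination rises.  The constants c0
(non-myelin baseline rate) and c1 (rate per unit myelin fraction) are
user parameters; the relation here encodes structure, not a calibration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class MyelinLinearModel:
    """R1(mf) = c0 + c1 * mf, with mf the myelin volume fraction in [0, 1]."""

    c0: float = 0.3  # baseline rate at zero myelin, 1/s
    c1: float = 0.5  # rate increase per unit myelin fraction, 1/s

    def __post_init__(self) -> None:
        if self.c1 <= 0:
            raise ValueError("c1 must be positive")
        if self.c0 < 0:
            raise ValueError("c0 must be non-negative")


def _check_mf(mf):
    mf = np.asarray(mf, dtype=float)
    if ((mf < 0) | (mf > 1)).any():
        raise ValueError("myelin fraction must lie in [0, 1]")
    return mf


def r1_from_myelin(model: MyelinLinearModel, mf):
    """Relaxation rate (1/s) at myelin fraction mf."""
    mf = _check_mf(mf)
    return model.c0 + model.c1 * mf


def t1_from_myelin(model: MyelinLinearModel, mf):
    """Relaxation time (s) at myelin fraction mf: 1/(c0 + c1*mf)."""
    rate = r1_from_myelin(model, mf)
    if (np.asarray(rate) <= 0).any():
        raise ValueError("relaxation rate must be positive to invert")
    return 1.0 / rate


def delta_t1_for_delta_myelin(model: MyelinLinearModel, mf, d_mf):
    """T1 change (s) caused by a myelin increment d_mf at baseline mf.

    For a fixed positive increment the magnitude of the T1 change is
    strictly decreasing in the baseline myelin fraction, while the R1
    change is the constant c1*d_mf.
    """
    mf = np.asarray(mf, dtype=float)
    return t1_from_myelin(model, mf + d_mf) - t1_from_myelin(model, mf)
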