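"""Heuristic transmit-field (B1+) correction of MT-saturation maps.

MT_sat carries a residual dependence on the local radio-frequency transmit
field.  With B1 expressed as a fraction of the nominal flip angle (1.0 =
nominal), the corrected map is

    MT_sat_corr = MT_sat_uncorr * (1 - C) / (1 - C * B1)

with the pulse-specific constant C (0.4 for the MT pulse this default was
calibrated for; it must be recalibrated for other pulses and is therefore a
parameter everywhere, never a hard-coded constant).

Three correction variants are managed: correction with a measured reference
B1+ map, no correction, and correction with a data-driven B1+ estimate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .volume_io import VolumeMap, require_compatible

__all__ = [
    "DEFAULT_C",
    "Variant",
    "B1Map",
    "correct_mtsat",
    "bias_factor",
]

log = logging.getLogger(__name__)

DEFAULT_C = 0.4


class Variant(str, Enum):
    """The three MT_sat correction variants compared by the pipeline."""

    REFERENCE_B1 = "b1"        # measured B1+ field map
    NONE = "none"              # no correction
    DATA_DRIVEN = "datadriven"  # retrospective, image-derived B1+ estimate


@dataclass
class B1Map:
    """A transmit-field map as fraction of nominal (1.0 = nominal flip angle).

    Maps supplied in percent-of-nominal units (values around 100) are
    auto-detected by their median and rescaled, with a warning.
    """

    field: VolumeMap

    def __post_init__(self) -> None:
        vals = self.field.values
        finite = vals[np.isfinite(vals)]
        if finite.size and np.median(finite) > 10.0:
            log.warning(
                "B1 map median %.1f suggests percent-of-nominal units; dividing by 100",
                np.median(finite),
            )
            self.field = self.field.with_values(vals / 100.0, unit_label="fraction of nominal")


def _check_c(C: float) -> None:
    if not (0.0 <= C < 1.0):
        raise ValueError(f"C must be in [0, 1), got {C}")


def bias_factor(b1: B1Map, C: float = DEFAULT_C) -> VolumeMap:
    """Multiplicative factor (1 - C) / (1 - C * B1) applied by the correction.

    Strictly increasing in B1 for C > 0, equal to 1 at nominal field.
    """
    _check_c(C)
    vals = b1.field.values
    denom = 1.0 - C * vals
    bad = np.isfinite(denom) & (denom <= 0.0)
    if bad.any():
        raise ValueError(
            f"correction denominator 1 - C*B1 <= 0 at {int(bad.sum())} voxel(s); "
            "B1 values are outside the admissible range"
        )
    return b1.field.with_values((1.0 - C) / denom, unit_label="dimensionless")


def correct_mtsat(mtsat_no: VolumeMap, b1: B1Map, C: float = DEFAULT_C) -> VolumeMap:
    """Apply the heuristic B1+ correction voxel-wise.

    Voxels where B1 is undefined become undefined (NaN) in the output.
    """
    require_compatible(mtsat_no, b1.field)
    factor = bias_factor(b1, C)
    return mtsat_no.with_values(mtsat_no.values * factor.values)
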