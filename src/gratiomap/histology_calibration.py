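"""Histology-anchored calibration of the MT_sat -> MVF proportionality.

Myelin volume fraction cannot be read off an MT_sat map directly; the map is
assumed proportional to MVF without intercept,

    MVF = alpha * MT_sat,

and alpha is fixed by equating the group-average MT_sat inside a calibration
region with a histologically known myelin volume fraction there.  The
histological MVF is computed from a fiber table (inner axon radius r, myelin
sheath thickness m, fiber count) via cross-sectional areas:

    TAV_m = sum count * pi * r^2              (myelinated-axon volume)
    TMV   = sum count * pi * (r+m)^2 - TAV_m  (myelin volume)
    TAV_u = unmyelinated_frac * TAV_m         (unmyelinated axons, default 43%)
    TV    = (TAV_m + TAV_u + TMV) / (1 - evf_frac)
    MVF_hist = TMV / TV

where the extracellular volume fraction defaults to 25% of the total.  The
43% default comes from the convention of reporting unmyelinated axons as 30%
of the total axonal volume: 0.3 / (1 - 0.3) = 0.43.

Because alpha absorbs any global scaling of MT_sat, each correction variant
gets its own alpha; by construction the calibration-region group-mean MVF
then equals MVF_hist for every variant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .volume_io import VolumeMap, masked_mean

__all__ = [
    "FiberTable",
    "CalibrationResult",
    "mvf_from_histology",
    "calibrate_alpha",
    "read_fiber_table",
]

DEFAULT_UNMYELINATED_FRAC = 0.43
DEFAULT_EVF_FRAC = 0.25


@dataclass
class FiberTable:
    """Histological fiber records: (inner radius r, myelin thickness m, count).

    Accepts per-fiber rows (count 1) or binned histogram rows (count > 1);
    r and m share one length unit, which cancels in the volume fractions.
    """

    r: np.ndarray
    m: np.ndarray
    count: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=np.float64)
        self.m = np.asarray(self.m, dtype=np.float64)
        self.count = np.asarray(self.count, dtype=np.float64)
        if not (self.r.shape == self.m.shape == self.count.shape) or self.r.ndim != 1:
            raise ValueError("r, m, count must be 1-D arrays of equal length")
        if self.r.size == 0:
            raise ValueError("empty fiber table")
        if (self.r <= 0).any() or (self.m < 0).any() or (self.count < 1).any():
            raise ValueError("require r > 0, m >= 0, count >= 1")

    @classmethod
    def from_records(cls, records: Iterable[tuple[float, float, float]]) -> "FiberTable":
        arr = np.asarray(list(records), dtype=np.float64)
        if arr.size == 0:
            raise ValueError("empty fiber table")
        return cls(arr[:, 0], arr[:, 1], arr[:, 2])


@dataclass
class CalibrationResult:
    """Areas, histological MVF and (optionally) the fitted alpha."""

    mvf_hist: float
    tav_m: float
    tmv: float
    tav_u: float
    tev: float
    tv: float
    mean_mtsat_roi: float | None = None
    alpha: float | None = None
    variant_tag: str | None = None


def mvf_from_histology(
    fibers: FiberTable,
    unmyelinated_frac: float = DEFAULT_UNMYELINATED_FRAC,
    evf_frac: float = DEFAULT_EVF_FRAC,
) -> CalibrationResult:
    """Histological myelin volume fraction from a fiber table.

    Invariant under splitting any histogram bin into identical sub-bins, and
    under a common rescaling of the length unit.
    """
    if unmyelinated_frac < 0:
        raise ValueError("unmyelinated_frac must be >= 0")
    if not (0 <= evf_frac < 1):
        raise ValueError("evf_frac must be in [0, 1)")
    tav_m = float(np.sum(fibers.count * np.pi * fibers.r**2))
    outer = float(np.sum(fibers.count * np.pi * (fibers.r + fibers.m) ** 2))
    tmv = outer - tav_m
    tav_u = unmyelinated_frac * tav_m
    tv = (tav_m + tav_u + tmv) / (1.0 - evf_frac)
    tev = evf_frac * tv
    return CalibrationResult(
        mvf_hist=tmv / tv, tav_m=tav_m, tmv=tmv, tav_u=tav_u, tev=tev, tv=tv
    )


def calibrate_alpha(
    mvf_hist: float,
    mtsat_map_group: Sequence[VolumeMap],
    calib_roi: VolumeMap | np.ndarray,
    variant_tag: str | None = None,
) -> CalibrationResult:
    """Fit alpha = MVF_hist / (group-average MT_sat in the calibration region).

    The group average is the unweighted mean of per-map (subject/session) ROI
    means, pooling all supplied maps.
    """
    if not mtsat_map_group:
        raise ValueError("need at least one MT_sat map")
    per_map = [masked_mean(m, calib_roi) for m in mtsat_map_group]
    group_mean = float(np.mean(per_map))
    if group_mean <= 0:
        raise ValueError(f"non-positive group-mean MT_sat in calibration ROI: {group_mean}")
    return CalibrationResult(
        mvf_hist=float(mvf_hist),
        tav_m=np.nan, tmv=np.nan, tav_u=np.nan, tev=np.nan, tv=np.nan,
        mean_mtsat_roi=group_mean,
        alpha=float(mvf_hist) / group_mean,
        variant_tag=variant_tag,
    )


def read_fiber_table(path: str) -> FiberTable:
    """Read a fiber table TSV with columns r, m, count (count optional)."""
    df = pd.read_csv(path, sep="\t")
    if not {"r", "m"}.issubset(df.columns):
        raise ValueError("fiber table needs columns: r, m [, count]")
    count = df["count"].to_numpy() if "count" in df.columns else np.ones(len(df))
    return FiberTable(df["r"].to_numpy(), df["m"].to_numpy(), count)
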