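"""Voxel-wise MVF, AWF, AVF and MR g-ratio maps.

The aggregate MR g-ratio of a voxel is computed from the myelin volume
fraction (MVF, from calibrated MT_sat) and axon volume fraction (AVF, from
NODDI parameters corrected for the missing myelin water signal):

    MVF = alpha * MT_sat
    AWF = (1 - nu_iso) * nu_icvf          (axonal water fraction)
    AVF = (1 - MVF) * AWF
    g   = sqrt(AVF / (MVF + AVF)) = sqrt(1 - MVF / (MVF + AVF))

g ranges from 0 (no axon, all myelin) to 1 (no myelin).  Noisy MT_sat can
push MVF outside [0, 1]; such voxels are counted and reported, and are
clipped only when explicitly requested — g itself stays real whenever both
fractions are non-negative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .volume_io import VolumeMap, require_compatible

__all__ = [
    "GratioVoxelSet",
    "compute_mvf",
    "compute_awf",
    "compute_avf",
    "compute_g",
    "compute_all",
]

log = logging.getLogger(__name__)

#: tolerance on "fraction in [0,1]" input checks
FRACTION_TOL = 1e-9


@dataclass
class GratioVoxelSet:
    """The per-variant bundle of derived maps plus the alpha used."""

    mvf: VolumeMap
    awf: VolumeMap
    avf: VolumeMap
    g: VolumeMap
    alpha: float
    variant_tag: str | None = None


def _count_out_of_range(name: str, vals: np.ndarray) -> int:
    bad = np.isfinite(vals) & ((vals < 0) | (vals > 1))
    n = int(bad.sum())
    if n:
        log.warning("%s outside [0, 1] at %d voxel(s); carried through unclipped", name, n)
    return n


def compute_mvf(mtsat: VolumeMap, alpha: float) -> VolumeMap:
    """Myelin volume fraction alpha * MT_sat; out-of-range voxels reported."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    out = mtsat.with_values(alpha * mtsat.values, unit_label="fraction")
    _count_out_of_range("MVF", out.values)
    return out


def _check_fraction_input(name: str, vol: VolumeMap) -> None:
    vals = vol.values
    bad = np.isfinite(vals) & ((vals < -FRACTION_TOL) | (vals > 1 + FRACTION_TOL))
    if bad.any():
        raise ValueError(f"{name} outside [0, 1] at {int(bad.sum())} voxel(s)")


def compute_awf(nu_icvf: VolumeMap, nu_iso: VolumeMap) -> VolumeMap:
    """Axonal water fraction (1 - nu_iso) * nu_icvf."""
    require_compatible(nu_icvf, nu_iso)
    _check_fraction_input("nu_icvf", nu_icvf)
    _check_fraction_input("nu_iso", nu_iso)
    return nu_icvf.with_values((1.0 - nu_iso.values) * nu_icvf.values, unit_label="fraction")


def compute_avf(
    mtsat: VolumeMap, alpha: float, nu_icvf: VolumeMap, nu_iso: VolumeMap
) -> VolumeMap:
    """Axon volume fraction (1 - alpha*MT_sat) * (1 - nu_iso) * nu_icvf."""
    require_compatible(mtsat, nu_icvf, nu_iso)
    mvf = compute_mvf(mtsat, alpha)
    awf = compute_awf(nu_icvf, nu_iso)
    return mtsat.with_values((1.0 - mvf.values) * awf.values, unit_label="fraction")


def compute_g(mvf: VolumeMap, avf: VolumeMap) -> VolumeMap:
    """MR g-ratio sqrt(AVF / (MVF + AVF)); undefined where MVF = AVF = 0.

    Strictly decreasing in MVF at fixed AVF > 0 and increasing in AVF at
    fixed MVF > 0.
    """
    require_compatible(mvf, avf)
    m, a = mvf.values, avf.values
    for name, vals in (("MVF", m), ("AVF", a)):
        neg = np.isfinite(vals) & (vals < -FRACTION_TOL)
        if neg.any():
            raise ValueError(f"negative {name} at {int(neg.sum())} voxel(s)")
    total = m + a
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(total > 0, a / total, np.nan)
        g = np.sqrt(np.clip(ratio, 0.0, 1.0))
    g = np.where(np.isfinite(total), g, np.nan)
    return mvf.with_values(g, unit_label="dimensionless")


def compute_all(
    mtsat: VolumeMap,
    alpha: float,
    nu_icvf: VolumeMap,
    nu_iso: VolumeMap,
    variant_tag: str | None = None,
    clip: bool = False,
) -> GratioVoxelSet:
    """Full per-variant map set from MT_sat + NODDI inputs.

    With ``clip=True``, MVF, nu_icvf and nu_iso are clamped to [0, 1] before
    the downstream maps are formed.
    """
    if clip:
        mtsat = mtsat.with_values(np.clip(mtsat.values, 0.0, 1.0 / alpha))
        nu_icvf = nu_icvf.with_values(np.clip(nu_icvf.values, 0.0, 1.0))
        nu_iso = nu_iso.with_values(np.clip(nu_iso.values, 0.0, 1.0))
    mvf = compute_mvf(mtsat, alpha)
    awf = compute_awf(nu_icvf, nu_iso)
    avf = mtsat.with_values((1.0 - mvf.values) * awf.values, unit_label="fraction")
    g = compute_g(mvf, avf)
    return GratioVoxelSet(mvf=mvf, awf=awf, avf=avf, g=g, alpha=alpha, variant_tag=variant_tag)
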