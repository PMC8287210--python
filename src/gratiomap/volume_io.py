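"""Volumetric containers and masked arithmetic shared by every pipeline stage.

All quantitative maps (MT_sat, B1+, NODDI fractions, MVF/AVF/g, SNR, tissue
probabilities, CoV) travel through the pipeline as :class:`VolumeMap`: a 3-D
scalar grid plus a voxel-to-world affine.  Undefined voxels are encoded as
IEEE NaN — never as zero, since zero is a legitimate value for several of the
quantities (e.g. MT_sat in CSF).  All volumes participating in one analysis
must live on one grid; spatial registration and resampling are out of scope,
so grid compatibility is *checked*, not repaired.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "VolumeMap",
    "LabelAtlas",
    "read_volume",
    "write_volume",
    "check_compatible",
    "require_compatible",
    "masked_mean",
    "read_atlas",
    "write_atlas",
    "DEFAULT_GRID_TOL",
]

#: Default absolute tolerance (world units) for affine agreement.
DEFAULT_GRID_TOL = 1e-4


@dataclass
class VolumeMap:
    """A 3-D scalar voxel grid with affine metadata.

    Parameters
    ----------
    values
        3-D float array; NaN marks undefined voxels.
    affine
        4x4 voxel-to-world transform.
    unit_label
        Free-text unit annotation, e.g. ``"p.u."`` or ``"fraction"``.
    """

    values: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    unit_label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.values.ndim != 3 or min(self.values.shape) < 1:
            raise ValueError(
                f"VolumeMap requires a 3-D grid, got shape {self.values.shape}"
            )
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_sizes(self) -> np.ndarray:
        """Voxel edge lengths (world units per voxel) along each axis."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def with_values(self, values: np.ndarray, unit_label: str | None = None) -> "VolumeMap":
        """New map on the same grid with different values."""
        return replace(
            self,
            values=np.asarray(values, dtype=np.float64),
            unit_label=self.unit_label if unit_label is None else unit_label,
        )

    def defined(self) -> np.ndarray:
        """Boolean array of voxels carrying a finite value."""
        return np.isfinite(self.values)


@dataclass
class LabelAtlas:
    """Integer ROI label grid plus an id -> name table. Label 0 is background."""

    labels: np.ndarray
    names: dict[int, str]
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            rounded = np.rint(self.labels)
            if not np.allclose(self.labels, rounded):
                raise ValueError("atlas labels must be integers")
            self.labels = rounded.astype(np.int32)
        if self.labels.ndim != 3:
            raise ValueError("atlas label grid must be 3-D")
        self.affine = np.asarray(self.affine, dtype=np.float64)
        present = set(int(v) for v in np.unique(self.labels)) - {0}
        missing = present - set(self.names)
        if missing:
            raise ValueError(f"atlas ids without a name entry: {sorted(missing)}")

    @property
    def ids(self) -> list[int]:
        """Sorted non-background ids present in the grid."""
        return sorted(set(int(v) for v in np.unique(self.labels)) - {0})

    def mask(self, roi_id: int) -> np.ndarray:
        return self.labels == roi_id


def read_volume(path: str | os.PathLike) -> VolumeMap:
    """Read a NIfTI-1/2 image into a :class:`VolumeMap`.

    4-D images whose trailing axes are singletons are squeezed; anything that
    is not 3-D after squeezing is rejected.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such volume: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    data = np.squeeze(data)
    if data.ndim != 3:
        raise ValueError(
            f"{path}: expected a 3-D volume, got shape {data.shape} after squeezing"
        )
    return VolumeMap(values=data, affine=np.asarray(img.affine))


def write_volume(vol: VolumeMap, path: str | os.PathLike) -> None:
    """Write a :class:`VolumeMap` as NIfTI (float64, NaN for undefined)."""
    img = nib.Nifti1Image(vol.values.astype(np.float64), vol.affine)
    nib.save(img, str(path))


def check_compatible(a: VolumeMap, b: VolumeMap, tol: float = DEFAULT_GRID_TOL) -> bool:
    """True iff shapes match and affines agree elementwise within ``tol``."""
    if a.shape != b.shape:
        return False
    return bool(np.all(np.abs(a.affine - b.affine) <= tol))


def require_compatible(*vols: VolumeMap, tol: float = DEFAULT_GRID_TOL) -> None:
    """Raise ``ValueError`` unless all volumes share one grid."""
    ref = vols[0]
    for v in vols[1:]:
        if not check_compatible(ref, v, tol):
            raise ValueError(
                f"incompatible grids: {ref.shape} vs {v.shape} "
                "(or affines disagree beyond tolerance)"
            )


def _as_bool_mask(mask: VolumeMap | np.ndarray) -> np.ndarray:
    arr = mask.values if isinstance(mask, VolumeMap) else np.asarray(mask)
    if arr.dtype != bool:
        arr = np.nan_to_num(arr, nan=0.0) > 0.5
    return arr


def masked_mean(vol: VolumeMap, mask: VolumeMap | np.ndarray) -> float:
    """Mean of ``vol`` over foreground mask voxels, ignoring NaN voxels.

    Raises if the mask is empty or every masked value is undefined.
    """
    m = _as_bool_mask(mask)
    if isinstance(mask, VolumeMap):
        require_compatible(vol, mask)
    elif m.shape != vol.shape:
        raise ValueError("mask shape does not match volume")
    if not m.any():
        raise ValueError("empty mask")
    vals = vol.values[m]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("all masked voxels are undefined")
    return float(vals.mean())


def read_atlas(nifti_path: str | os.PathLike, names_path: str | os.PathLike) -> LabelAtlas:
    """Load an integer label NIfTI plus a two-column TSV (id, name)."""
    vol = read_volume(nifti_path)
    table = pd.read_csv(names_path, sep="\t")
    if not {"id", "name"}.issubset(table.columns):
        raise ValueError("atlas name table needs columns: id, name")
    names = {int(r.id): str(r.name) for r in table.itertuples()}
    return LabelAtlas(labels=vol.values, names=names, affine=vol.affine)


def write_atlas(atlas: LabelAtlas, nifti_path: str | os.PathLike, names_path: str | os.PathLike) -> None:
    img = nib.Nifti1Image(atlas.labels.astype(np.int16), atlas.affine)
    nib.save(img, str(nifti_path))
    pd.DataFrame(
        {"id": list(atlas.names), "name": [atlas.names[k] for k in atlas.names]}
    ).to_csv(names_path, sep="\t", index=False)
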