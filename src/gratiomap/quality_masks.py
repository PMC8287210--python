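"""Group white-matter masks, SNR maps and data-quality ROI selection.

NODDI's intracellular volume fraction is biased toward its ceiling
(nu_icvf >= 0.999) in low-SNR regions.  The analysis therefore restricts
itself to (i) a group WM mask (mean of individual WM tissue-probability
maps, thresholded) and (ii) a high-SNR subset of it, obtained by sweeping
an SNR threshold and choosing the value that minimizes the group-mean
ratio of artifactual voxels to mask voxels — a trade-off that removes
unrealistic voxels while retaining as many voxels as possible (ties break
toward the smaller threshold).

The voxel-wise SNR map is (mean_b0 / sigma) * sqrt(n_b0), with sigma a
single scalar noise estimate per subject and n_b0 the number of
non-diffusion-weighted images averaged into mean_b0 (default 12).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .volume_io import LabelAtlas, VolumeMap, require_compatible

__all__ = [
    "SnrMaskConfig",
    "ThresholdSearchResult",
    "snr_map",
    "group_wm_mask",
    "optimize_snr_threshold",
    "high_snr_mask",
    "select_rois",
]

log = logging.getLogger(__name__)


@dataclass
class SnrMaskConfig:
    n_b0: int = 12
    ceiling_cutoff: float = 0.999
    threshold_grid: tuple[float, ...] = tuple(range(1, 81))
    wm_group_threshold: float = 0.95
    roi_overlap_min: float = 0.95

    def __post_init__(self) -> None:
        grid = np.asarray(self.threshold_grid, dtype=float)
        if grid.size == 0 or (np.diff(grid) <= 0).any() or (grid <= 0).any():
            raise ValueError("threshold_grid must be positive and strictly increasing")
        if not (0 < self.ceiling_cutoff <= 1):
            raise ValueError("ceiling_cutoff must be in (0, 1]")


@dataclass
class ThresholdSearchResult:
    """Swept-threshold curve and the chosen (argmin) threshold."""

    table: pd.DataFrame  # columns: threshold, mean_ratio, sd_ratio, n_subjects
    chosen_threshold: float


def snr_map(mean_b0: VolumeMap, sigma: float, n_b0: int = 12) -> VolumeMap:
    """Voxel-wise SNR: (mean_b0 / sigma) * sqrt(n_b0)."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if n_b0 < 1:
        raise ValueError("n_b0 must be >= 1")
    return mean_b0.with_values(mean_b0.values / sigma * np.sqrt(n_b0), unit_label="dimensionless")


def group_wm_mask(tpms: Sequence[VolumeMap], threshold: float = 0.95) -> VolumeMap:
    """Binary group WM mask: mean of individual WM TPMs >= threshold."""
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    require_compatible(*tpms)
    mean_tpm = np.mean([t.values for t in tpms], axis=0)
    mask = (mean_tpm >= threshold).astype(np.float64)
    if not mask.any():
        log.warning("group WM mask is empty at threshold %.3f", threshold)
    return tpms[0].with_values(mask, unit_label="binary")


def optimize_snr_threshold(
    snr_maps: Sequence[VolumeMap],
    nu_icvf_maps: Sequence[VolumeMap],
    wm_mask: VolumeMap | np.ndarray,
    cfg: SnrMaskConfig | None = None,
) -> ThresholdSearchResult:
    """Sweep SNR thresholds; choose the one minimizing the artifact ratio.

    Per subject and candidate t the mask is WM AND (SNR >= t), and the ratio
    is #(nu_icvf >= ceiling_cutoff within mask) / #mask.  The chosen
    threshold is the argmin of the group-mean ratio; ties break toward the
    smallest t.  Candidates that empty every subject's mask are excluded
    with a warning.
    """
    cfg = cfg or SnrMaskConfig()
    if len(snr_maps) != len(nu_icvf_maps) or not snr_maps:
        raise ValueError("need equal, non-empty lists of SNR and nu_icvf maps")
    wm = wm_mask.values > 0.5 if isinstance(wm_mask, VolumeMap) else np.asarray(wm_mask, bool)
    rows = []
    for t in cfg.threshold_grid:
        ratios = []
        for snr, icvf in zip(snr_maps, nu_icvf_maps):
            m = wm & (snr.values >= t)
            n = int(m.sum())
            if n == 0:
                continue
            n_bad = int(np.sum(np.nan_to_num(icvf.values[m], nan=0.0) >= cfg.ceiling_cutoff))
            ratios.append(n_bad / n)
        if not ratios:
            log.warning("threshold %s empties every subject mask; excluded", t)
            continue
        rows.append(
            {
                "threshold": float(t),
                "mean_ratio": float(np.mean(ratios)),
                "sd_ratio": float(np.std(ratios, ddof=1)) if len(ratios) > 1 else 0.0,
                "n_subjects": len(ratios),
            }
        )
    if not rows:
        raise ValueError("no admissible threshold in the grid")
    table = pd.DataFrame(rows)
    # stable argmin: first (smallest) threshold achieving the minimum
    chosen = float(table.loc[table["mean_ratio"].idxmin(), "threshold"])
    return ThresholdSearchResult(table=table, chosen_threshold=chosen)


def high_snr_mask(
    wm_mask: VolumeMap, snr: VolumeMap, threshold: float
) -> VolumeMap:
    """Intersection of the WM mask with SNR >= threshold."""
    require_compatible(wm_mask, snr)
    out = (wm_mask.values > 0.5) & (snr.values >= threshold)
    return wm_mask.with_values(out.astype(np.float64), unit_label="binary")


def select_rois(
    atlas: LabelAtlas,
    wm_mask: VolumeMap | np.ndarray,
    high_snr: VolumeMap | np.ndarray,
    overlap_min: float = 0.95,
) -> tuple[list[int], list[int], pd.DataFrame]:
    """Apply the two ROI-selection rules.

    whole-WM ROIs: every voxel of the ROI inside the WM mask.
    high-SNR ROIs: whole-WM ROIs whose fraction of voxels inside the
    high-SNR mask is at least ``overlap_min`` (a voxel-count fraction of
    the ROI, not a Dice coefficient).

    Returns (whole_wm_ids, high_snr_ids, detail table).
    """
    if not atlas.ids:
        raise ValueError("empty atlas")
    wm = wm_mask.values > 0.5 if isinstance(wm_mask, VolumeMap) else np.asarray(wm_mask, bool)
    hs = high_snr.values > 0.5 if isinstance(high_snr, VolumeMap) else np.asarray(high_snr, bool)
    rows = []
    whole, high = [], []
    for rid in atlas.ids:
        roi = atlas.mask(rid)
        n = int(roi.sum())
        in_wm = bool((roi & wm).sum() == n)
        overlap = float((roi & hs).sum() / n)
        in_high = in_wm and overlap >= overlap_min
        if in_wm:
            whole.append(rid)
        if in_high:
            high.append(rid)
        rows.append(
            {
                "id": rid,
                "name": atlas.names[rid],
                "n_voxels": n,
                "in_whole_wm": in_wm,
                "overlap_frac": overlap,
                "in_high_snr": in_high,
            }
        )
    return whole, high, pd.DataFrame(rows)
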