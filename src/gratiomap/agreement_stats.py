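"""ROI aggregation, dynamic range and Bland-Altman agreement statistics.

Agreement between two sets of per-ROI values (two sessions of one method,
or two correction methods) is summarized the Bland-Altman way:

    delta_i = reference_i - test_i
    bias    = mean(delta_i)
    error   = 1.96 * SD(delta_i)          (sample SD, N-1 denominator)

and both are normalized by the dynamic range of the reference metric across
ROIs — Delta_DR = max_i(mean_i) - min_i(mean_i) — to express them as
percentages of meaningful between-region signal variation:

    relative bias  = 100 * bias  / Delta_DR
    relative error = 100 * error / Delta_DR

The sign convention is reference minus test throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .volume_io import LabelAtlas, VolumeMap, require_compatible

__all__ = [
    "AgreementResult",
    "roi_means",
    "group_roi_means",
    "dynamic_range",
    "bland_altman",
    "test_retest",
]


@dataclass
class AgreementResult:
    delta: np.ndarray          # per-item reference - test
    pair_mean: np.ndarray      # per-item (reference + test) / 2
    bias: float
    error: float               # 1.96 * sample SD of delta
    dynamic_range: float | None = None
    relative_bias_pct: float | None = None
    relative_error_pct: float | None = None

    def as_row(self) -> dict:
        return {
            "bias": self.bias,
            "error": self.error,
            "dynamic_range": self.dynamic_range,
            "relative_bias_pct": self.relative_bias_pct,
            "relative_error_pct": self.relative_error_pct,
        }


def roi_means(
    vol: VolumeMap,
    atlas: LabelAtlas,
    roi_ids: Sequence[int],
    restrict_mask: VolumeMap | np.ndarray | None = None,
) -> pd.Series:
    """Per-ROI mean over defined voxels, optionally within a restriction mask."""
    if restrict_mask is None:
        restrict = np.ones(vol.shape, dtype=bool)
    elif isinstance(restrict_mask, VolumeMap):
        require_compatible(vol, restrict_mask)
        restrict = restrict_mask.values > 0.5
    else:
        restrict = np.asarray(restrict_mask, bool)
    out = {}
    for rid in roi_ids:
        sel = atlas.mask(rid) & restrict
        vals = vol.values[sel]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            raise ValueError(f"ROI {rid} empty (after restriction) or all-undefined")
        out[rid] = float(vals.mean())
    return pd.Series(out, name="mean")


def group_roi_means(tables: Sequence[pd.Series]) -> pd.DataFrame:
    """Group summary across subjects/sessions: per-ROI mean and SD.

    Each element of ``tables`` is one subject/session per-ROI mean series;
    all must share the ROI index.
    """
    df = pd.concat(tables, axis=1)
    if df.isna().any().any():
        raise ValueError("ROI sets differ between tables")
    return pd.DataFrame({"mean": df.mean(axis=1), "sd": df.std(axis=1, ddof=1)})


def dynamic_range(group_means: Sequence[float] | pd.Series) -> float:
    """max - min of the per-ROI group means."""
    arr = np.asarray(group_means, dtype=float)
    if arr.size < 2:
        raise ValueError("dynamic range needs >= 2 ROIs")
    return float(arr.max() - arr.min())


def bland_altman(
    reference: Sequence[float],
    test: Sequence[float],
    dr: float | None = None,
) -> AgreementResult:
    """Bland-Altman bias/error for paired per-ROI (or per-voxel) values.

    ``dr`` is the dynamic range used for the relative percentages; omit it
    to skip them.  Properties: identical inputs give exactly (0, 0);
    swapping reference and test negates every delta and the bias but leaves
    the error unchanged.
    """
    ref = np.asarray(reference, dtype=float)
    tst = np.asarray(test, dtype=float)
    if ref.shape != tst.shape or ref.ndim != 1:
        raise ValueError("reference and test must be equal-length 1-D sequences")
    if ref.size < 2:
        raise ValueError("need >= 2 paired entries")
    delta = ref - tst
    bias = float(delta.mean())
    error = float(1.96 * delta.std(ddof=1))
    rel_b = rel_e = None
    if dr is not None:
        if dr <= 0:
            raise ValueError("dynamic range must be positive for relative values")
        rel_b = 100.0 * bias / dr
        rel_e = 100.0 * error / dr
    return AgreementResult(
        delta=delta,
        pair_mean=(ref + tst) / 2.0,
        bias=bias,
        error=error,
        dynamic_range=dr,
        relative_bias_pct=rel_b,
        relative_error_pct=rel_e,
    )


def test_retest(
    session1: Sequence[pd.Series],
    session2: Sequence[pd.Series],
    dr: float | None = None,
) -> AgreementResult:
    """Session-1 vs session-2 agreement of per-ROI group means.

    Each argument is the list of per-subject ROI-mean series for that
    session; group means are taken per session, then compared ROI-wise with
    reference = session 1.
    """
    g1 = group_roi_means(session1)["mean"]
    g2 = group_roi_means(session2)["mean"]
    if not g1.index.equals(g2.index):
        raise ValueError("session ROI sets differ")
    return bland_altman(g1.to_numpy(), g2.to_numpy(), dr=dr)
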