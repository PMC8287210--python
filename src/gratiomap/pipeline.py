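"""End-to-end orchestration of the g-ratio comparison analysis.

``run_full_analysis`` reproduces the full comparison design on a synthetic
phantom: generate the dataset, calibrate one MT_sat-to-MVF slope per
correction variant (measured-B1 reference, no correction, data-driven
surrogate), compute MVF/AVF/g maps, build the WM and high-SNR masks with
the optimized SNR threshold, select ROIs, and emit ROI statistics,
test-retest and between-method Bland-Altman tables, and the CoV comparison.
Everything is a deterministic function of (config, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .agreement_stats import (
    AgreementResult,
    bland_altman,
    dynamic_range,
    group_roi_means,
    roi_means,
    test_retest,
)
from .cov_analysis import (
    DEFAULT_FWHM_MM,
    DEFAULT_SUPPORT_CUTOFF,
    CovMap,
    cov_bland_altman,
    cov_map,
    tissue_weighted_smooth,
)
from .gratio_maps import GratioVoxelSet, compute_all
from .histology_calibration import calibrate_alpha
from .quality_masks import (
    SnrMaskConfig,
    ThresholdSearchResult,
    group_wm_mask,
    high_snr_mask,
    optimize_snr_threshold,
    select_rois,
    snr_map,
)
from .synthetic_phantom import PhantomConfig, PhantomDataset, generate
from .transmit_correction import B1Map, Variant, correct_mtsat
from .volume_io import VolumeMap

__all__ = [
    "AnalysisConfig",
    "AnalysisReport",
    "run_full_analysis",
    "variant_mtsat",
    "ceiling_fn_from_spec",
]

log = logging.getLogger(__name__)

METRICS = ("g", "avf", "mvf")
VARIANTS = (Variant.REFERENCE_B1, Variant.NONE, Variant.DATA_DRIVEN)


def ceiling_fn_from_spec(spec: dict) -> Callable[[np.ndarray], np.ndarray]:
    """Build a ceiling-probability function from a serializable description.

    ``{"kind": "exp", "scale": s}``    -> exp(-SNR / s)
    ``{"kind": "step", "at": t, "p": p}`` -> p below t, 0 at or above
    ``{"kind": "off"}``                -> 0 everywhere
    """
    kind = spec.get("kind", "exp")
    if kind == "exp":
        scale = float(spec.get("scale", 15.0))
        return lambda snr: np.exp(-np.asarray(snr, float) / scale)
    if kind == "step":
        at, p = float(spec.get("at", 39.0)), float(spec.get("p", 0.5))
        return lambda snr: np.where(np.asarray(snr, float) < at, p, 0.0)
    if kind == "off":
        return lambda snr: np.zeros_like(np.asarray(snr, float))
    raise ValueError(f"unknown ceiling spec kind: {kind}")


@dataclass
class AnalysisConfig:
    """Full-analysis configuration; serializes losslessly to/from YAML."""

    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    ceiling_spec: dict = field(default_factory=lambda: {"kind": "exp", "scale": 15.0})
    C: float = 0.4
    snr_cfg: SnrMaskConfig = field(default_factory=SnrMaskConfig)
    fwhm_mm: float = DEFAULT_FWHM_MM
    support_cutoff: float = DEFAULT_SUPPORT_CUTOFF
    seed: int = 0

    def __post_init__(self) -> None:
        self.phantom.ceiling_prob_fn = ceiling_fn_from_spec(self.ceiling_spec)
        self.phantom.seed = self.seed

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["phantom"].pop("ceiling_prob_fn", None)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        ph = dict(d.pop("phantom", {}))
        ph.pop("ceiling_prob_fn", None)
        rois = ph.pop("rois", None)
        snr_prof = ph.pop("snr_profile", None)
        from .synthetic_phantom import RoiSpec, SnrProfile

        def _box(b):
            return tuple(tuple(int(v) for v in pair) for pair in b)

        kwargs = {}
        for key in ("wm_box", "calib_box"):
            if key in ph:
                ph[key] = _box(ph[key])
        if "grid_shape" in ph:
            ph["grid_shape"] = tuple(int(v) for v in ph["grid_shape"])
        if rois is not None:
            kwargs["rois"] = tuple(
                RoiSpec(int(r["roi_id"]), str(r["name"]), _box(r["box"]),
                        float(r["mvf_true"]), float(r["avf_true"]))
                for r in rois
            )
        if snr_prof is not None:
            ramp = snr_prof.get("ramp_axis")
            kwargs["snr_profile"] = SnrProfile(
                high=float(snr_prof["high"]), low=float(snr_prof["low"]),
                low_box=_box(snr_prof["low_box"]),
                ramp_axis=None if ramp is None else int(ramp),
            )
        phantom = PhantomConfig(**ph, **kwargs)
        snr_cfg = d.pop("snr_cfg", None)
        if snr_cfg is not None:
            snr_cfg = SnrMaskConfig(
                n_b0=int(snr_cfg["n_b0"]),
                ceiling_cutoff=float(snr_cfg["ceiling_cutoff"]),
                threshold_grid=tuple(float(t) for t in snr_cfg["threshold_grid"]),
                wm_group_threshold=float(snr_cfg["wm_group_threshold"]),
                roi_overlap_min=float(snr_cfg["roi_overlap_min"]),
            )
            d["snr_cfg"] = snr_cfg
        return cls(phantom=phantom, **d)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "AnalysisConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        def _canon(x):
            if isinstance(x, dict):
                return {k: _canon(v) for k, v in x.items()}
            if isinstance(x, (list, tuple)):
                return [_canon(v) for v in x]
            if isinstance(x, bool):
                return x
            if isinstance(x, (int, float)):
                return float(x)  # stable across int/float YAML round trips
            return x

        payload = json.dumps(_canon(self.to_dict()), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class AnalysisReport:
    """All tables and derived volumes produced by a full-analysis run."""

    config: AnalysisConfig
    dataset: PhantomDataset
    calibration: pd.DataFrame           # variant, mvf_hist, mean_mtsat, alpha
    maps: dict[tuple[str, int, int], GratioVoxelSet]   # (variant, subject, session)
    wm_mask: VolumeMap
    threshold_search: ThresholdSearchResult
    high_snr: VolumeMap
    roi_selection: pd.DataFrame
    whole_wm_ids: list[int]
    high_snr_ids: list[int]
    roi_stats: dict[tuple[str, str], pd.DataFrame]     # (metric, variant) -> group table
    dynamic_ranges: dict[str, float]                   # per metric, reference variant
    retest: pd.DataFrame
    between_method: pd.DataFrame
    cov_maps: dict[tuple[str, str], CovMap]
    cov_agreement: pd.DataFrame


def variant_mtsat(ds: PhantomDataset, variant: Variant, C: float) -> dict[tuple[int, int], VolumeMap]:
    """Per-(subject, session) MT_sat maps under one correction variant."""
    out = {}
    for (s, t), mt in ds.mtsat_no.items():
        if variant is Variant.NONE:
            out[(s, t)] = mt
        elif variant is Variant.REFERENCE_B1:
            out[(s, t)] = correct_mtsat(mt, B1Map(ds.b1_true[s]), C)
        else:
            out[(s, t)] = correct_mtsat(mt, B1Map(ds.b1_surrogate[s]), C)
    return out


def _metric_map(vs: GratioVoxelSet, metric: str) -> VolumeMap:
    return {"g": vs.g, "avf": vs.avf, "mvf": vs.mvf}[metric]


def run_full_analysis(config: AnalysisConfig, out_dir: str | None = None) -> AnalysisReport:
    """Run the whole comparison design on a phantom; optionally write TSVs."""
    ds = generate(config.phantom, C=config.C)
    keys = ds.keys()

    # --- per-variant calibration: the phantom's known calibration-region MVF
    # plays the role of the histological anchor
    mtsat: dict[str, dict[tuple[int, int], VolumeMap]] = {}
    calib_rows = []
    alphas: dict[str, float] = {}
    for variant in VARIANTS:
        vm = variant_mtsat(ds, variant, config.C)
        mtsat[variant.value] = vm
        res = calibrate_alpha(
            config.phantom.calib_mvf,
            [vm[k] for k in keys],
            ds.calib_mask,
            variant_tag=variant.value,
        )
        alphas[variant.value] = res.alpha  # type: ignore[assignment]
        calib_rows.append(
            {
                "variant": variant.value,
                "mvf_hist": res.mvf_hist,
                "mean_mtsat": res.mean_mtsat_roi,
                "alpha": res.alpha,
            }
        )
    calibration = pd.DataFrame(calib_rows)

    # --- voxel-wise maps
    maps: dict[tuple[str, int, int], GratioVoxelSet] = {}
    for variant in VARIANTS:
        for s, t in keys:
            maps[(variant.value, s, t)] = compute_all(
                mtsat[variant.value][(s, t)],
                alphas[variant.value],
                ds.nu_icvf[(s, t)],
                ds.nu_iso[(s, t)],
                variant_tag=variant.value,
            )

    # --- masks and ROI selection
    wm_mask = group_wm_mask(ds.wm_tpms(), config.snr_cfg.wm_group_threshold)
    snr_maps = [snr_map(ds.mean_b0[k], ds.sigma, config.snr_cfg.n_b0) for k in keys]
    icvf_maps = [ds.nu_icvf[k] for k in keys]
    search = optimize_snr_threshold(snr_maps, icvf_maps, wm_mask, config.snr_cfg)
    mean_snr = snr_maps[0].with_values(np.mean([m.values for m in snr_maps], axis=0))
    hs_mask = high_snr_mask(wm_mask, mean_snr, search.chosen_threshold)
    whole_ids, high_ids, roi_sel = select_rois(
        ds.atlas, wm_mask, hs_mask, config.snr_cfg.roi_overlap_min
    )
    if not high_ids:
        log.warning("no ROI passes the high-SNR overlap rule; falling back to whole-WM set")

    # --- ROI statistics (sessions pooled) per metric and variant
    roi_stats: dict[tuple[str, str], pd.DataFrame] = {}
    per_ss: dict[tuple[str, str], list[pd.Series]] = {}
    roi_ids_for_stats = high_ids if high_ids else whole_ids
    for metric in METRICS:
        for variant in VARIANTS:
            series = [
                roi_means(
                    _metric_map(maps[(variant.value, s, t)], metric),
                    ds.atlas,
                    whole_ids,
                    restrict_mask=wm_mask,
                )
                for s, t in keys
            ]
            per_ss[(metric, variant.value)] = series
            roi_stats[(metric, variant.value)] = group_roi_means(series)

    # --- dynamic ranges of the reference variant over the high-SNR ROI set
    dyn: dict[str, float] = {}
    for metric in METRICS:
        ref_means = roi_stats[(metric, Variant.REFERENCE_B1.value)]["mean"]
        dyn[metric] = dynamic_range(ref_means.loc[roi_ids_for_stats])

    # --- test-retest of the reference variant (high-SNR ROI set)
    retest_rows = []
    n_sess = config.phantom.n_sessions
    for metric in METRICS:
        series = per_ss[(metric, Variant.REFERENCE_B1.value)]
        s1 = [ser.loc[roi_ids_for_stats] for ser, (s, t) in zip(series, keys) if t == 0]
        s2 = [ser.loc[roi_ids_for_stats] for ser, (s, t) in zip(series, keys) if t == 1]
        if n_sess >= 2:
            g1 = group_roi_means(s1)["mean"]
            g2 = group_roi_means(s2)["mean"]
            pair_dr = dynamic_range((g1 + g2) / 2.0)
            res = test_retest(s1, s2, dr=pair_dr)
            retest_rows.append({"metric": metric, **res.as_row()})
    retest = pd.DataFrame(retest_rows)

    # --- between-method comparison against the reference variant
    bm_rows = []
    for metric in METRICS:
        roisets = [("high_snr", roi_ids_for_stats)]
        if metric == "mvf":
            roisets.append(("whole_wm", whole_ids))
        for set_name, ids in roisets:
            ref = roi_stats[(metric, Variant.REFERENCE_B1.value)]["mean"].loc[ids]
            set_dr = dynamic_range(ref)
            for variant in (Variant.NONE, Variant.DATA_DRIVEN):
                tst = roi_stats[(metric, variant.value)]["mean"].loc[ids]
                res = bland_altman(ref.to_numpy(), tst.to_numpy(), dr=set_dr)
                bm_rows.append(
                    {"metric": metric, "variant": variant.value, "roi_set": set_name,
                     **res.as_row()}
                )
    between_method = pd.DataFrame(bm_rows)

    # --- CoV analysis (tissue-weighted smoothing, then voxel-wise CoV)
    cov_maps: dict[tuple[str, str], CovMap] = {}
    for metric in METRICS:
        for variant in VARIANTS:
            smoothed = [
                tissue_weighted_smooth(
                    _metric_map(maps[(variant.value, s, t)], metric),
                    ds.wm_tpm,
                    config.fwhm_mm,
                    config.support_cutoff,
                )
                for s, t in keys
            ]
            cov_maps[(metric, variant.value)] = cov_map(
                smoothed,
                mask=wm_mask,
                metric_tag=metric,
                variant_tag=variant.value,
                fwhm_mm=config.fwhm_mm,
            )
    cov_rows = []
    for metric in METRICS:
        ref = cov_maps[(metric, Variant.REFERENCE_B1.value)]
        for variant in (Variant.NONE, Variant.DATA_DRIVEN):
            res = cov_bland_altman(ref, cov_maps[(metric, variant.value)])
            cov_rows.append({"metric": metric, "variant": variant.value, **res.as_row()})
    cov_agreement = pd.DataFrame(cov_rows)

    report = AnalysisReport(
        config=config,
        dataset=ds,
        calibration=calibration,
        maps=maps,
        wm_mask=wm_mask,
        threshold_search=search,
        high_snr=hs_mask,
        roi_selection=roi_sel,
        whole_wm_ids=whole_ids,
        high_snr_ids=high_ids,
        roi_stats=roi_stats,
        dynamic_ranges=dyn,
        retest=retest,
        between_method=between_method,
        cov_maps=cov_maps,
        cov_agreement=cov_agreement,
    )
    if out_dir is not None:
        write_report(report, out_dir)
    return report


def write_report(report: AnalysisReport, out_dir: str) -> None:
    """Write all report tables as TSV, stamped with the config hash."""
    os.makedirs(out_dir, exist_ok=True)
    h = report.config.config_hash()

    def _dump(df: pd.DataFrame, name: str, index: bool = False) -> None:
        path = os.path.join(out_dir, name)
        with open(path, "w") as fh:
            fh.write(f"# gratiomap {__version__} config_hash={h}\n")
            df.to_csv(fh, sep="\t", index=index, lineterminator="\n")

    _dump(report.calibration, "calibration.tsv")
    _dump(report.threshold_search.table, "threshold_search.tsv")
    _dump(report.roi_selection, "roi_selection.tsv")
    _dump(report.retest, "retest.tsv")
    _dump(report.between_method, "between_method.tsv")
    _dump(report.cov_agreement, "cov_agreement.tsv")
    for (metric, variant), table in report.roi_stats.items():
        _dump(table.rename_axis("roi_id"), f"roi_stats_{metric}_{variant}.tsv", index=True)
    with open(os.path.join(out_dir, "run_log.txt"), "w") as fh:
        fh.write(f"gratiomap {__version__}\nconfig_hash: {h}\n")
        fh.write(f"seed: {report.config.seed}\n")
        fh.write(f"chosen_snr_threshold: {report.threshold_search.chosen_threshold}\n")
        fh.write(f"whole_wm_rois: {report.whole_wm_ids}\n")
        fh.write(f"high_snr_rois: {report.high_snr_ids}\n")
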