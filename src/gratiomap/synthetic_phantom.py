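"""Synthetic multi-subject phantom with known g-ratio ground truth.

The generator emulates the statistical structure the analysis assumes, so
every downstream stage is testable without any imaging data:

* a smooth multiplicative transmit-field (B1+) inhomogeneity, modelled as a
  renormalized low-order 3-D polynomial with spatial mean 1 and amplitude
  about +/-20% of nominal;
* a second, imperfect "data-driven" B1+ source: the true field plus an
  independent smooth error field of smaller amplitude;
* piecewise-constant ground-truth myelin and axon volume fractions on a set
  of box-shaped white-matter ROIs (values in the range reported for human
  WM, MVF ~0.2-0.5, AVF ~0.2-0.45), from which MT_sat, the NODDI fractions
  and the g-ratio follow exactly by the forward model;
* additive zero-mean Gaussian noise on the derived maps, re-drawn per
  session (map-level noise stands in for the out-of-scope raw-signal
  estimation step);
* a low-SNR region in which the intracellular volume fraction exhibits the
  ceiling artifact (nu_icvf >= 0.999) with a probability that decreases
  with SNR.

The full dataset is a pure function of (config, seed): ground truth is
identical across sessions, noise realizations differ.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .volume_io import LabelAtlas, VolumeMap

__all__ = [
    "Box",
    "RoiSpec",
    "SnrProfile",
    "PhantomConfig",
    "PhantomDataset",
    "sample_b1_field",
    "sample_smooth_field",
    "apply_b1_bias",
    "generate",
    "default_ceiling_prob",
]

#: half-open voxel box ((x0, x1), (y0, y1), (z0, z1))
Box = tuple[tuple[int, int], tuple[int, int], tuple[int, int]]


def _box_slices(box: Box) -> tuple[slice, slice, slice]:
    return tuple(slice(lo, hi) for lo, hi in box)  # type: ignore[return-value]


@dataclass(frozen=True)
class RoiSpec:
    roi_id: int
    name: str
    box: Box
    mvf_true: float
    avf_true: float


@dataclass(frozen=True)
class SnrProfile:
    """SNR landscape: a low-SNR box inside a high-SNR background, or — with
    ``ramp_axis`` set — a linear ramp from ``low`` to ``high`` along one axis
    (useful for localizing an SNR threshold)."""

    high: float = 60.0
    low: float = 15.0
    low_box: Box = ((2, 10), (2, 10), (2, 8))
    ramp_axis: int | None = None


def default_ceiling_prob(snr: np.ndarray) -> np.ndarray:
    """Probability of a nu_icvf ceiling artifact; decreasing in SNR."""
    return np.exp(-np.asarray(snr, dtype=float) / 15.0)


def _default_rois() -> tuple[RoiSpec, ...]:
    # six WM tract surrogates spanning the reported MVF/AVF ranges; the last
    # two sit inside the default low-SNR box
    return (
        RoiSpec(1, "tract_a", ((14, 20), (2, 8), (2, 8)), 0.445, 0.315),
        RoiSpec(2, "tract_b", ((14, 20), (10, 16), (2, 8)), 0.419, 0.384),
        RoiSpec(3, "tract_c", ((14, 20), (18, 22), (2, 8)), 0.408, 0.357),
        RoiSpec(4, "tract_d", ((2, 8), (14, 20), (9, 14)), 0.435, 0.321),
        RoiSpec(5, "tract_e", ((3, 9), (3, 9), (3, 7)), 0.425, 0.328),
        RoiSpec(6, "tract_f", ((4, 8), (10, 13), (9, 14)), 0.413, 0.356),
    )


@dataclass
class PhantomConfig:
    """Study conditions for the synthetic dataset.

    Defaults mirror the structure of a two-session multi-subject in-vivo
    study: B1+ amplitude 0.2 (about +/-20% of nominal), a data-driven-B1
    surrogate error of 0.05, MT_sat-to-MVF slope 0.25 p.u.^-1, map noise
    tuned to give ROI-level SDs of a few percent.
    """

    grid_shape: tuple[int, int, int] = (24, 24, 16)
    n_subjects: int = 6
    n_sessions: int = 2
    rois: tuple[RoiSpec, ...] = field(default_factory=_default_rois)
    wm_box: Box = ((1, 23), (1, 23), (1, 15))
    wm_mvf: float = 0.42
    wm_avf: float = 0.34
    calib_box: Box = ((10, 13), (10, 13), (2, 6))
    calib_mvf: float = 0.3623
    calib_avf: float = 0.30
    alpha_true: float = 0.25           # p.u.^-1
    b1_amplitude: float = 0.2          # fraction of nominal
    b1_poly_order: int = 2
    b1_subject_jitter: float = 0.15    # subject-to-subject field variation,
                                       # relative to the shared field's peak
    un_error_amplitude: float = 0.05   # surrogate-B1 error, fraction of nominal
    mtsat_noise_sd: float = 0.05       # p.u., per session
    nu_icvf_noise_sd: float = 0.02
    nu_iso_noise_sd: float = 0.01
    nu_iso_level: float = 0.05         # free-water fraction in WM (<= 0.15)
    n_b0: int = 12
    sigma: float = 50.0                # scalar noise estimate for the SNR map
    snr_profile: SnrProfile = field(default_factory=SnrProfile)
    ceiling_prob_fn: Callable[[np.ndarray], np.ndarray] = default_ceiling_prob
    ceiling_enabled: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.n_sessions < 1 or self.n_subjects < 1:
            raise ValueError("need >= 1 subject and session")
        if not (0 <= self.b1_amplitude < 1):
            raise ValueError("b1_amplitude must be in [0, 1)")
        if self.nu_iso_level > 0.15:
            raise ValueError("nu_iso_level kept small (<= 0.15) by construction")
        occupied = np.zeros(self.grid_shape, dtype=int)
        for spec in self.rois:
            occupied[_box_slices(spec.box)] += 1
        if (occupied > 1).any():
            raise ValueError("ROI boxes must be disjoint")
        for spec in self.regions():
            if not (0 < spec.mvf_true < 1 and 0 < spec.avf_true < 1):
                raise ValueError(f"{spec.name}: fractions must be in (0, 1)")
            if spec.mvf_true + spec.avf_true >= 1:
                raise ValueError(f"{spec.name}: mvf_true + avf_true must be < 1")
            awf = spec.avf_true / (1.0 - spec.mvf_true)
            if awf / (1.0 - self.nu_iso_level) > 1.0:
                raise ValueError(f"{spec.name}: implied nu_icvf exceeds 1")

    def regions(self) -> tuple[RoiSpec, ...]:
        """All truth-bearing regions: labelled ROIs, WM background, calibration."""
        return self.rois + (
            RoiSpec(0, "wm_background", self.wm_box, self.wm_mvf, self.wm_avf),
            RoiSpec(-1, "calibration", self.calib_box, self.calib_mvf, self.calib_avf),
        )


@dataclass
class PhantomDataset:
    """Generated maps keyed by (subject, session), plus shared ground truth."""

    config: PhantomConfig
    # per (subject, session)
    mtsat_no: dict[tuple[int, int], VolumeMap]
    nu_icvf: dict[tuple[int, int], VolumeMap]
    nu_iso: dict[tuple[int, int], VolumeMap]
    odi: dict[tuple[int, int], VolumeMap]
    mean_b0: dict[tuple[int, int], VolumeMap]
    # per subject
    b1_true: dict[int, VolumeMap]
    b1_surrogate: dict[int, VolumeMap]
    # shared
    sigma: float
    atlas: LabelAtlas
    wm_tpm: VolumeMap
    calib_mask: VolumeMap
    wm_mask_array: np.ndarray
    truth: dict[str, VolumeMap]  # mvf, avf, awf, g, mtsat, nu_icvf, snr

    def keys(self) -> list[tuple[int, int]]:
        return sorted(self.mtsat_no)

    def wm_tpms(self) -> list[VolumeMap]:
        """Per-subject WM tissue probability maps (identical by construction)."""
        return [self.wm_tpm for _ in range(self.config.n_subjects)]


def _normalized_coords(shape: Sequence[int]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    axes = [np.linspace(-1.0, 1.0, n) if n > 1 else np.zeros(n) for n in shape]
    return np.meshgrid(*axes, indexing="ij")  # type: ignore[return-value]


def sample_smooth_field(
    shape: Sequence[int], amplitude: float, order: int, rng: np.random.Generator
) -> np.ndarray:
    """Zero-mean smooth polynomial perturbation with max |p| = amplitude.

    Random-coefficient monomials x^i y^j z^k, 1 <= i+j+k <= order, on
    [-1, 1]^3 coordinates; mean-centred then peak-normalized.
    """
    x, y, z = _normalized_coords(shape)
    p = np.zeros(shape, dtype=np.float64)
    for i in range(order + 1):
        for j in range(order + 1 - i):
            for k in range(order + 1 - i - j):
                if i + j + k == 0:
                    continue
                p += rng.normal() * x**i * y**j * z**k
    p -= p.mean()
    peak = np.abs(p).max()
    if peak > 0:
        p *= amplitude / peak
    return p


def sample_b1_field(config: PhantomConfig, rng: np.random.Generator | None = None) -> VolumeMap:
    """Smooth B1+ field with spatial mean 1.0 and max |B1 - 1| = b1_amplitude."""
    if config.b1_amplitude >= 1:
        raise ValueError("b1_amplitude must be < 1")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    p = sample_smooth_field(config.grid_shape, config.b1_amplitude, config.b1_poly_order, rng)
    field_vals = 1.0 + p
    # re-centre the spatial mean exactly on 1.0
    field_vals += 1.0 - field_vals.mean()
    return VolumeMap(field_vals, unit_label="fraction of nominal")


def apply_b1_bias(mtsat_true: VolumeMap, b1: VolumeMap, C: float) -> VolumeMap:
    """Forward model of the transmit-field bias on MT_sat.

    Exact algebraic inverse of the heuristic correction: returns
    MT_sat_uncorr = MT_sat_true * (1 - C*B1) / (1 - C), so correcting the
    output with the same field and C recovers the input.
    """
    if not (0 <= C < 1):
        raise ValueError("C must be in [0, 1)")
    denom = 1.0 - C * b1.values
    if (np.isfinite(denom) & (denom <= 0)).any():
        raise ValueError("1 - C*B1 <= 0 somewhere; field outside admissible range")
    return mtsat_true.with_values(mtsat_true.values * denom / (1.0 - C))


def _truth_maps(config: PhantomConfig) -> dict[str, np.ndarray]:
    shape = config.grid_shape
    mvf = np.full(shape, np.nan)
    avf = np.full(shape, np.nan)
    # paint background WM first, then calibration region, then ROIs on top
    ordered = (
        RoiSpec(0, "wm_background", config.wm_box, config.wm_mvf, config.wm_avf),
        RoiSpec(-1, "calibration", config.calib_box, config.calib_mvf, config.calib_avf),
    ) + config.rois
    for spec in ordered:
        sl = _box_slices(spec.box)
        mvf[sl] = spec.mvf_true
        avf[sl] = spec.avf_true
    awf = avf / (1.0 - mvf)
    nu_icvf = awf / (1.0 - config.nu_iso_level)
    g = np.sqrt(avf / (mvf + avf))
    mtsat = mvf / config.alpha_true
    return {"mvf": mvf, "avf": avf, "awf": awf, "nu_icvf": nu_icvf, "g": g, "mtsat": mtsat}


def _snr_array(config: PhantomConfig) -> np.ndarray:
    prof = config.snr_profile
    if prof.ramp_axis is not None:
        ax = prof.ramp_axis
        n = config.grid_shape[ax]
        ramp = np.linspace(prof.low, prof.high, n)
        shape = [1, 1, 1]
        shape[ax] = n
        return np.broadcast_to(ramp.reshape(shape), config.grid_shape).copy()
    snr = np.full(config.grid_shape, prof.high, dtype=np.float64)
    snr[_box_slices(prof.low_box)] = prof.low
    return snr


def generate(config: PhantomConfig, C: float = 0.4) -> PhantomDataset:
    """Build the full multi-subject, multi-session dataset.

    Background (non-WM) voxels carry plausible filler values (low MT_sat,
    low nu_icvf, raised free water) so that whole-volume operations remain
    well defined; the WM mask excludes them from any analysis.
    """
    config.validate()
    shape = config.grid_shape
    truth = _truth_maps(config)
    snr = _snr_array(config)

    wm = np.zeros(shape, dtype=bool)
    wm[_box_slices(config.wm_box)] = True
    calib = np.zeros(shape, dtype=bool)
    calib[_box_slices(config.calib_box)] = True

    labels = np.zeros(shape, dtype=np.int16)
    names = {}
    for spec in config.rois:
        labels[_box_slices(spec.box)] = spec.roi_id
        names[spec.roi_id] = spec.name
    atlas = LabelAtlas(labels=labels, names=names)

    # filler values outside WM: low myelin, raised free water
    mtsat_true = np.where(wm, truth["mtsat"], 0.4)
    nu_icvf_true = np.where(wm, truth["nu_icvf"], 0.10)
    nu_iso_true = np.where(wm, config.nu_iso_level, 0.60)

    root = np.random.SeedSequence(config.seed)
    common_seq, *subj_seqs = root.spawn(1 + config.n_subjects)
    # the transmit-field pattern is largely coil- and anatomy-determined and
    # therefore shared across subjects; individual heads perturb it mildly
    rng_common = np.random.default_rng(common_seq)
    p_common = sample_smooth_field(shape, 1.0, config.b1_poly_order, rng_common)

    b1_true: dict[int, VolumeMap] = {}
    b1_surr: dict[int, VolumeMap] = {}
    mtsat_no: dict[tuple[int, int], VolumeMap] = {}
    nu_icvf_m: dict[tuple[int, int], VolumeMap] = {}
    nu_iso_m: dict[tuple[int, int], VolumeMap] = {}
    odi_m: dict[tuple[int, int], VolumeMap] = {}
    b0_m: dict[tuple[int, int], VolumeMap] = {}

    mean_b0_vals = snr * config.sigma / np.sqrt(config.n_b0)

    for s, seq in enumerate(subj_seqs):
        field_seq, err_seq, *sess_seqs = seq.spawn(2 + config.n_sessions)
        rng_field = np.random.default_rng(field_seq)
        if config.b1_amplitude == 0:
            b1 = VolumeMap(np.ones(shape), unit_label="fraction of nominal")
        else:
            p = p_common + sample_smooth_field(
                shape, config.b1_subject_jitter, config.b1_poly_order, rng_field
            )
            p -= p.mean()
            peak = np.abs(p).max()
            if peak > 0:
                p *= config.b1_amplitude / peak
            vals = 1.0 + p
            vals += 1.0 - vals.mean()
            b1 = VolumeMap(vals, unit_label="fraction of nominal")
        rng_err = np.random.default_rng(err_seq)
        err = sample_smooth_field(shape, config.un_error_amplitude, config.b1_poly_order, rng_err)
        b1_true[s] = b1
        b1_surr[s] = b1.with_values(b1.values + err)

        biased = apply_b1_bias(VolumeMap(mtsat_true), b1, C).values
        for t, sess_seq in enumerate(sess_seqs):
            rng = np.random.default_rng(sess_seq)
            mt = biased + rng.normal(0.0, config.mtsat_noise_sd, shape) \
                if config.mtsat_noise_sd > 0 else biased.copy()
            icvf = nu_icvf_true + rng.normal(0.0, config.nu_icvf_noise_sd, shape) \
                if config.nu_icvf_noise_sd > 0 else nu_icvf_true.copy()
            iso = nu_iso_true + rng.normal(0.0, config.nu_iso_noise_sd, shape) \
                if config.nu_iso_noise_sd > 0 else nu_iso_true.copy()
            icvf = np.clip(icvf, 0.0, 1.0)
            iso = np.clip(iso, 0.0, 1.0)
            if config.ceiling_enabled:
                prob = np.clip(config.ceiling_prob_fn(snr), 0.0, 1.0)
                hit = rng.random(shape) < prob
                icvf = np.where(hit, 0.999 + 0.001 * rng.random(shape), icvf)
            mtsat_no[(s, t)] = VolumeMap(mt, unit_label="p.u.")
            nu_icvf_m[(s, t)] = VolumeMap(icvf, unit_label="fraction")
            nu_iso_m[(s, t)] = VolumeMap(iso, unit_label="fraction")
            odi_m[(s, t)] = VolumeMap(np.full(shape, 0.3), unit_label="dimensionless")
            b0_m[(s, t)] = VolumeMap(mean_b0_vals.copy(), unit_label="a.u.")

    truth_vols = {k: VolumeMap(np.where(wm, v, np.nan)) for k, v in truth.items()}
    truth_vols["snr"] = VolumeMap(snr, unit_label="dimensionless")

    return PhantomDataset(
        config=config,
        mtsat_no=mtsat_no,
        nu_icvf=nu_icvf_m,
        nu_iso=nu_iso_m,
        odi=odi_m,
        mean_b0=b0_m,
        b1_true=b1_true,
        b1_surrogate=b1_surr,
        sigma=config.sigma,
        atlas=atlas,
        wm_tpm=VolumeMap(wm.astype(np.float64), unit_label="probability"),
        calib_mask=VolumeMap(calib.astype(np.float64)),
        wm_mask_array=wm,
        truth=truth_vols,
    )
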