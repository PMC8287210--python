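# Methods

## Scope and model

`gratiomap` implements the analysis layer of g-ratio weighted imaging: it
assumes spatially aligned, already-estimated parameter maps (MT_sat in
percent units, a B1+ transmit-field map as fraction of nominal, NODDI's
ν_icvf and ν_iso, white-matter tissue probability maps, mean-b0 volumes
with a scalar noise estimate, and an integer ROI atlas) and computes from
them the myelin volume fraction, axon volume fraction and aggregate MR
g-ratio per voxel, plus group-level agreement statistics. Map estimation
from raw signals, registration and segmentation are out of scope by design:
all volumes in one analysis must share one grid, which is checked (affine
agreement within 1e-4 world units by default) and never repaired.

The voxel model is

- MT_sat correction: `MT_sat_corr = MT_sat_uncorr (1−C)/(1−C·B1)` with the
  pulse-specific constant C defaulting to 0.4. C is a parameter everywhere
  because it must be recalibrated for other MT pulses. B1 maps supplied in
  percent-of-nominal are auto-detected (median > 10) and rescaled with a
  warning, since conventions differ between tools.
- `MVF = α·MT_sat` without intercept; `AWF = (1−ν_iso)·ν_icvf`;
  `AVF = (1−MVF)·AWF`; `g = √(AVF/(MVF+AVF))`.
- α is fit per correction variant as MVF_hist divided by the group-average
  MT_sat in a calibration region. The group average is the unweighted mean
  of per-subject/session ROI means (the source texts do not distinguish
  voxel-pooled from subject-mean averaging; the ROI-mean convention is used
  consistently here). By construction the calibration-region group-mean MVF
  then equals MVF_hist for every variant — this normalization is exactly
  why each variant needs its own α.
- MVF_hist comes from fiber tables (inner radius r, myelin thickness m,
  count) via cross-sectional areas, with unmyelinated axons assumed to add
  43% of the myelinated-axon area (the 0.3/(1−0.3) convention for
  "unmyelinated axons are 30% of total axonal volume") and an extracellular
  volume fraction of 25% of the total. Both are parameters.

Undefined voxels are IEEE NaN throughout; zero is a legal data value
(MT_sat near zero occurs in CSF). Noisy MT_sat can push MVF outside [0,1];
such voxels are counted and logged but carried through unclipped — g stays
real whenever MVF, AVF ≥ 0 — with an opt-in `clip` mode that clamps the
constituent fractions first. ROI statistics always average voxel-wise g,
never the g of averaged fractions (the two differ because g is concave).

## Data-quality masking

The group WM mask thresholds the mean of individual WM tissue-probability
maps at 0.95. The SNR map is `(mean_b0/σ)·√n_b0` with n_b0 = 12 by
default; σ is accepted as a precomputed scalar (raw-DWI noise estimation
is out of scope). The SNR threshold is chosen by sweeping a grid (integers
1–80 by default) and minimizing the group-mean ratio of ν_icvf ceiling
voxels (ν_icvf ≥ 0.999) to mask voxels; ties break toward the smaller
threshold, retaining as many voxels as possible, and candidates that empty
every subject's mask are excluded with a warning. Whole-WM ROIs must lie
100% inside the WM mask; high-SNR ROIs additionally need ≥ 95% of their
voxels inside the high-SNR mask (voxel-count fractions, not Dice).

## Agreement statistics

For paired per-ROI (or per-voxel) values, δ_i = reference − test,
bias = mean(δ), error = 1.96·SD(δ) with the N−1 sample SD, and both are
expressed as percentages of the dynamic range Δ_DR = max−min of the
reference metric's per-ROI group means. Sign convention is reference minus
test. For test-retest comparisons Δ_DR is computed from the per-ROI means
of the two-session averages; for between-method comparisons it is the
reference variant's Δ_DR over the same ROI set (recomputed per ROI set,
since a whole-WM Δ_DR is not otherwise defined).

CoV maps are 100·SD/mean across subjects and sessions (N−1 SD), defined
where at least two inputs are finite and the mean is positive, computed
after tissue-weighted smoothing `G∗(map·tpm)/G∗(tpm)` with a 6-mm-FWHM
Gaussian (per-axis sigma from the affine's voxel sizes, reflective
boundaries) and a smoothed-support cutoff of 0.05 below which voxels become
undefined. CoV map pairs are compared voxel-wise by Bland-Altman; the
relative values are normalized by the mask-mean of the reference CoV (the
choice of summary is not dictated by any source; mask-mean is used and
reported). When the reference CoV is identically zero (degenerate
noiseless input) the relatives are undefined and omitted.

The embedded reference tables (`gratiomap.reference_tables`) carry the
published 21-ROI group means and Bland-Altman absolutes for the
B1-corrected method; the test suite verifies that dynamic ranges, summary
statistics and all relative percentages reproduce from them through this
module's arithmetic. One published relative bias (g, data-driven variant,
printed 30.44) differs in the last digit from the quotient of its printed
absolute and dynamic range (30.43) because the absolute was rounded before
printing; the table marks that row and the identity test excludes it.
Recomputed SDs of the ROI means can likewise differ from published SDs by
up to one rounding step of the 3-decimal inputs.

## The synthetic phantom

The generator emulates the statistical structure the analysis assumes, not
MR physics. Defaults (chosen once as the study conditions for all tests):

- grid 24×24×16 voxels, 6 subjects × 2 sessions;
- six box-shaped WM "tracts" with MVF 0.41–0.45 and AVF 0.31–0.38
  (the ranges reported for human WM ROIs), a WM background (MVF 0.42,
  AVF 0.34) and a calibration box with MVF 0.3623 — the histological
  anchor value — so calibration against the planted truth mirrors the
  real procedure;
- α_true = 0.25 p.u.⁻¹, so WM MT_sat ≈ 1.6–1.8 p.u.;
- B1+ field: a renormalized second-order 3-D polynomial with spatial mean
  exactly 1 and peak deviation b1_amplitude = 0.2 (~±20% of nominal).
  Low-order polynomials are the minimal model of a smooth transmit field.
  The field pattern is shared across subjects up to a small smooth
  per-subject jitter (15% of the shared peak), reflecting that transmit
  inhomogeneity is largely coil- and geometry-determined — this is what
  makes omitting the correction a *systematic* group-level bias rather
  than noise;
- the data-driven-correction surrogate is the true field plus an
  independent smooth error field of amplitude 0.05: the comparison only
  needs a second, imperfect B1+ source, not a re-implementation of any
  particular estimation algorithm, and its error structure is a free knob,
  not an estimate;
- additive zero-mean Gaussian noise per session on the derived maps
  (MT_sat SD 0.05 p.u., ν_icvf 0.02, ν_iso 0.01 — map-level noise stands
  in for the out-of-scope raw-signal estimation and yields ROI-level SDs
  of a few per cent), with ν maps clipped to [0,1] as bounded model
  outputs would be;
- an SNR landscape (60 high / 15 low in a box, or a linear ramp for
  threshold-localization experiments) realized through mean-b0 =
  SNR·σ/√n_b0, so the SNR operation reproduces it exactly; in low-SNR
  voxels ν_icvf is replaced by a value ≥ 0.999 with probability
  exp(−SNR/15) by default (any monotone-decreasing function, e.g. a step,
  can be supplied);
- ODI is emitted as a flat filler volume (it is only used for
  registration, which is out of scope).

Everything is a pure function of (config, seed): ground truth is identical
across sessions, noise differs, and identical configs give byte-identical
output tables (the config hash is stamped into every TSV).

What the phantom does **not** emulate — and hence what passing tests do not
show about real data: Rician signal statistics, registration and
segmentation errors, anatomical tissue geometry, between-subject truth
variation, and the actual error structure of data-driven B1+ estimation.
Phantom-derived magnitudes (e.g. the factor by which the data-driven
correction reduces bias) therefore depend on the configured field shapes;
only the qualitative ordering is asserted.

## Numerical choices and degenerate inputs

- The forward bias model is the exact algebraic inverse of the correction,
  so bias-then-correct round-trips to machine precision; tests assert
  rtol ≤ 1e-13.
- Correction denominators 1−C·B1 ≤ 0 abort with the offending voxel count;
  implausible B1 values are never silently clipped.
- g at MVF = AVF = 0 is undefined (NaN); the ratio AVF/(MVF+AVF) is clamped
  to [0,1] before the square root purely to guard float round-off.
- Threshold-search ties break to the smallest threshold; the argmin is
  taken over the group-mean ratio (the group SD is reported alongside).
- Masked means ignore NaN voxels; empty masks and all-NaN selections are
  errors, empty group-WM masks only a warning.
- Problem sizes in tests and the acceptance script (24×24×16 grids, 2–6
  subjects) are the package's default study conditions; they keep exact
  recoveries exact while exercising every stage.

## Known limitations

- No registration/resampling: misaligned inputs are rejected, not fixed.
- The calibration accepts any fiber table but ships none; the histological
  anchor used on phantoms is the planted calibration-region truth.
- Published CoV-comparison magnitudes cannot be checked without the
  original cohort's data (the reference denominators are not published);
  the CoV machinery is validated by construction-level oracles instead.
- The SNR threshold search assumes a shared threshold across subjects, as
  in the original design; per-subject thresholds are not implemented.
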