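# gratiomap

Quantitative-MRI pipeline for **g-ratio weighted imaging**: voxel-wise maps
of myelin volume fraction (MVF), axon volume fraction (AVF) and the
aggregate MR g-ratio, with explicit handling of the radio-frequency
transmit-field (B1+) bias in magnetization-transfer saturation (MT_sat)
maps — and the statistical machinery to quantify what omitting or
approximating that correction costs.

It is written for quantitative-MRI researchers who combine a myelin marker
(MT_sat, in percent units) with NODDI diffusion parameters (ν_icvf, ν_iso)
and want a tested, scriptable implementation of the full chain from aligned
parameter maps to group-level agreement tables.

## The model

The g-ratio of a myelinated axon is the ratio of inner to outer radius; its
voxel-level aggregate is computed from volume fractions:

```
MT_sat_corr = MT_sat_uncorr · (1 − C) / (1 − C·B1)      heuristic B1+ correction, C = 0.4
MVF  = α · MT_sat                                        calibrated myelin proxy
AWF  = (1 − ν_iso) · ν_icvf                              axonal water fraction
AVF  = (1 − MVF) · AWF
g    = √( AVF / (MVF + AVF) )                            0 = no axon … 1 = no myelin
```

B1 is the transmit field as a fraction of nominal flip angle; the slope α
(p.u.⁻¹) is anchored per correction variant by equating the group-mean
MT_sat in a calibration region (medullary pyramids) with a histological
myelin volume fraction computed from fiber tables:

```
TAV_m = Σ count·π·r²          TMV = Σ count·π·(r+m)² − TAV_m
TAV_u = 0.43·TAV_m            TV  = (TAV_m + TAV_u + TMV) / (1 − 0.25)
MVF_hist = TMV / TV
```

Three correction variants are carried through the whole analysis — measured
reference B1+ field, no correction, and a data-driven B1+ estimate — and
compared by Bland-Altman statistics (bias = mean paired difference, error =
1.96·SD) normalized by the dynamic range of per-ROI group means. Data
quality is handled by a group white-matter mask, a voxel-wise SNR map
(mean-b0/σ·√n_b0), and an SNR threshold chosen to minimize the rate of
ν_icvf ceiling artifacts (ν_icvf ≥ 0.999).

Because studies of this kind rarely deposit raw data, the package includes
a first-class synthetic phantom (`gratiomap.synthetic_phantom`) with known
ground truth, smooth polynomial B1+ fields, per-session noise and planted
low-SNR ceiling artifacts; every stage is tested against it.

## Worked example

```python
from gratiomap.pipeline import AnalysisConfig, run_full_analysis

report = run_full_analysis(AnalysisConfig(seed=0))
print(report.calibration)
print(report.between_method.query("roi_set == 'high_snr'"))
```

prints (see `examples/07_full_analysis.py`):

```
   variant  mvf_hist  mean_mtsat  alpha
        b1    0.3623      1.4510 0.2497
      none    0.3623      1.5049 0.2408
datadriven    0.3623      1.4499 0.2499

metric    variant   bias  error  relative_bias_pct  relative_error_pct
     g       none -0.009  0.013            -19.646              28.249
     g datadriven -0.000  0.001             -0.326               2.155
   avf       none -0.007  0.010            -10.856              15.049
   avf datadriven -0.000  0.001             -0.190               1.181
   mvf       none  0.012  0.017             33.313              47.593
   mvf datadriven  0.000  0.001              0.559               3.648
```

Each row compares one variant against the measured-field reference across
the high-SNR ROIs: omitting the correction biases g by ~20% of its
between-region dynamic range on this phantom, while the imperfect
data-driven correction stays under 1% — the qualitative effect the design
exists to demonstrate. The `examples/` directory holds one short script per
capability (phantom, correction, calibration, maps, masking, agreement,
full analysis), each printing what it computes and what the numbers mean.

A thin CLI mirrors the pipeline stages:

```
gratiomap simulate --seed 1 --out ds/
gratiomap correct --mtsat ds/sub-01/ses-1/mtsat_no.nii.gz --b1 ds/sub-01/b1_true.nii.gz --out mtsat_b1.nii.gz
gratiomap full-analysis --seed 0 --out report/
```

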