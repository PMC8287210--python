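"""Voxel-wise MVF/AVF/g maps and exact recovery on a clean phantom.

g = sqrt(AVF / (MVF + AVF)) ranges from 0 (no axon) to 1 (no myelin); on a
noiseless phantom with nominal transmit field the pipeline reproduces the
planted per-tract values exactly.
"""

import numpy as np

from gratiomap import compute_all, generate, roi_means
from gratiomap.synthetic_phantom import PhantomConfig

cfg = PhantomConfig(
    mtsat_noise_sd=0, nu_icvf_noise_sd=0, nu_iso_noise_sd=0,
    ceiling_enabled=False, b1_amplitude=0.0, un_error_amplitude=0.0, n_subjects=1,
)
ds = generate(cfg)
vs = compute_all(ds.mtsat_no[(0, 0)], cfg.alpha_true, ds.nu_icvf[(0, 0)], ds.nu_iso[(0, 0)])

means = {
    name: roi_means(vol, ds.atlas, ds.atlas.ids)
    for name, vol in (("mvf", vs.mvf), ("avf", vs.avf), ("g", vs.g))
}
print("roi  name      MVF      AVF      g        g_true")
for spec in cfg.rois:
    g_true = np.sqrt(spec.avf_true / (spec.mvf_true + spec.avf_true))
    print(
        f"{spec.roi_id:>3}  {spec.name:<8}  {means['mvf'][spec.roi_id]:.4f}   "
        f"{means['avf'][spec.roi_id]:.4f}   {means['g'][spec.roi_id]:.5f}  {g_true:.5f}"
    )
wm = ds.wm_mask_array
err = np.abs(vs.g.values[wm] - ds.truth["g"].values[wm]).max()
print(f"\nmax voxel-wise |g - g_true| in WM: {err:.2e}")
print("ROI means equal the planted tract values; recovery is exact.")
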