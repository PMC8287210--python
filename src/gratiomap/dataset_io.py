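"""Write a generated phantom dataset as a NIfTI directory tree + manifest."""

from __future__ import annotations

import os

import pandas as pd

from .synthetic_phantom import PhantomDataset
from .volume_io import write_atlas, write_volume

__all__ = ["write_dataset"]


def write_dataset(ds: PhantomDataset, out_dir: str) -> str:
    """Write one folder per subject/session plus shared ground truth.

    Returns the path of the manifest TSV listing every written volume with
    its subject, session and kind.
    """
    os.makedirs(out_dir, exist_ok=True)
    rows = []

    def _put(vol, rel, subject=None, session=None, kind=None):
        path = os.path.join(out_dir, rel)
        os.makedirs(os.path.dirname(path), exist_ok=True)
        write_volume(vol, path)
        rows.append({"subject": subject, "session": session, "kind": kind, "path": rel})

    for (s, t) in ds.keys():
        base = f"sub-{s + 1:02d}/ses-{t + 1}"
        _put(ds.mtsat_no[(s, t)], f"{base}/mtsat_no.nii.gz", s, t, "mtsat_no")
        _put(ds.nu_icvf[(s, t)], f"{base}/nu_icvf.nii.gz", s, t, "nu_icvf")
        _put(ds.nu_iso[(s, t)], f"{base}/nu_iso.nii.gz", s, t, "nu_iso")
        _put(ds.odi[(s, t)], f"{base}/odi.nii.gz", s, t, "odi")
        _put(ds.mean_b0[(s, t)], f"{base}/mean_b0.nii.gz", s, t, "mean_b0")
    for s in sorted(ds.b1_true):
        _put(ds.b1_true[s], f"sub-{s + 1:02d}/b1_true.nii.gz", s, None, "b1_true")
        _put(ds.b1_surrogate[s], f"sub-{s + 1:02d}/b1_surrogate.nii.gz", s, None, "b1_surrogate")
    _put(ds.wm_tpm, "shared/wm_tpm.nii.gz", kind="wm_tpm")
    _put(ds.calib_mask, "shared/calib_mask.nii.gz", kind="calib_mask")
    for name, vol in ds.truth.items():
        _put(vol, f"shared/truth_{name}.nii.gz", kind=f"truth_{name}")
    write_atlas(
        ds.atlas,
        os.path.join(out_dir, "shared/atlas.nii.gz"),
        os.path.join(out_dir, "shared/atlas_names.tsv"),
    )
    rows.append({"subject": None, "session": None, "kind": "atlas", "path": "shared/atlas.nii.gz"})
    manifest = os.path.join(out_dir, "manifest.tsv")
    df = pd.DataFrame(rows)
    df["sigma"] = ds.sigma
    df.to_csv(manifest, sep="\t", index=False)
    return manifest
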