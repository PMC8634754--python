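"""Readers and writers for the standard on-disk formats.

DWI series are NIfTI-1 images paired with FSL-style gradient files (``.bval``:
one whitespace-separated row of b-values; ``.bvec``: three rows holding the
x, y and z components). Cohorts are CSV with a fixed schema. Tensor fields,
label maps and derived maps are written as NIfTI volumes.
"""

import os
import warnings

import nibabel as nib
import numpy as np
import pandas as pd

from .gradients import GradientTable, UNIT_NORM_TOL
from .synthetic import Phantom, COHORT_COLUMNS
from .tensor import DWIVolume, TensorField

__all__ = [
    "read_dwi",
    "write_dwi",
    "read_gradient_files",
    "write_gradient_files",
    "read_cohort_csv",
    "write_cohort_csv",
    "write_phantom",
    "write_tensor_maps",
]


def read_gradient_files(path_bval, path_bvec) -> GradientTable:
    """Read FSL bval/bvec text files into a validated gradient table."""
    bvals = np.loadtxt(path_bval, ndmin=1)
    if bvals.ndim != 1:
        raise ValueError(f"{path_bval}: expected a single row of b-values")
    bvecs = np.loadtxt(path_bvec, ndmin=2)
    if bvecs.shape[0] == 3:
        bvecs = bvecs.T
    elif bvecs.shape[1] != 3:
        raise ValueError(f"{path_bvec}: expected 3 rows (x, y, z components)")
    if bvals.shape[0] != bvecs.shape[0]:
        raise ValueError(
            f"gradient mismatch: {bvals.shape[0]} b-values vs "
            f"{bvecs.shape[0]} directions"
        )
    if np.any(bvals < 0):
        raise ValueError(f"{path_bval}: negative b-value")
    dw = bvals > 0
    norms = np.linalg.norm(bvecs[dw], axis=1)
    if np.any(norms == 0):
        raise ValueError(f"{path_bvec}: zero-length direction with b > 0")
    if np.any(np.abs(norms - 1.0) > UNIT_NORM_TOL):
        warnings.warn(
            f"bvec norms deviate up to {np.abs(norms - 1.0).max():.2g} from 1; "
            "re-normalizing", stacklevel=2
        )
        bvecs = bvecs.copy()
        bvecs[dw] /= norms[:, None]
    return GradientTable(bvals, bvecs)


def write_gradient_files(gtab: GradientTable, path_bval, path_bvec) -> None:
    np.savetxt(path_bval, gtab.bvals[None, :], fmt="%.6g")
    np.savetxt(path_bvec, gtab.bvecs.T, fmt="%.8f")


def read_dwi(path_nii, path_bval, path_bvec):
    """Load a DWI series + gradient table; returns (DWIVolume, GradientTable).

    The number of 4th-dimension volumes must equal the gradient-table length.
    """
    img = nib.load(path_nii)
    data = np.asarray(img.dataobj, dtype=float)
    gtab = read_gradient_files(path_bval, path_bvec)
    if data.ndim != 4:
        raise ValueError(f"{path_nii}: expected 4D data, got shape {data.shape}")
    if data.shape[3] != len(gtab):
        raise ValueError(
            f"volume-count mismatch: image has {data.shape[3]} volumes but "
            f"gradient table has {len(gtab)} entries"
        )
    return DWIVolume(data=data, affine=img.affine), gtab


def write_dwi(dwi: DWIVolume, gtab: GradientTable, path_nii, path_bval, path_bvec):
    nib.save(nib.Nifti1Image(dwi.data, dwi.affine), path_nii)
    write_gradient_files(gtab, path_bval, path_bvec)


def write_phantom(phantom: Phantom, out_dir, stem="phantom"):
    """Write a phantom bundle: DWI + gradients + labels + ground-truth tensors."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "dwi": os.path.join(out_dir, f"{stem}_dwi.nii.gz"),
        "bval": os.path.join(out_dir, f"{stem}.bval"),
        "bvec": os.path.join(out_dir, f"{stem}.bvec"),
        "labels": os.path.join(out_dir, f"{stem}_labels.nii.gz"),
        "tensors": os.path.join(out_dir, f"{stem}_truth_tensor.nii.gz"),
    }
    nib.save(nib.Nifti1Image(phantom.dwi, phantom.affine), paths["dwi"])
    write_gradient_files(phantom.gtab, paths["bval"], paths["bvec"])
    nib.save(
        nib.Nifti1Image(phantom.labels.astype(np.int16), phantom.affine),
        paths["labels"],
    )
    nib.save(nib.Nifti1Image(phantom.tensors, phantom.affine), paths["tensors"])
    return paths


def write_tensor_maps(tf: TensorField, out_dir, stem="tensor"):
    """Write fitted tensor, FA, color-FA, diagonal-diffusivity and QC maps."""
    from .tensor import color_fa

    os.makedirs(out_dir, exist_ok=True)
    paths = {}

    def save(name, arr):
        p = os.path.join(out_dir, f"{stem}_{name}.nii.gz")
        nib.save(nib.Nifti1Image(np.asarray(arr), tf.affine), p)
        paths[name] = p

    save("coeffs", tf.lower_triangular)
    save("fa", tf.fa)
    save("color_fa", color_fa(tf))
    save("dxx", tf.Dxx)
    save("dyy", tf.Dyy)
    save("dzz", tf.Dzz)
    save("qc_flags", tf.flag_mask.astype(np.uint8))
    return paths


def append_alps_csv(result, path, subject_id="") -> None:
    """Append one AlpsResult as a row of a running per-subject CSV."""
    row = {
        "subject_id": subject_id,
        "alps": result.alps_index,
        "Dxx_proj": result.Dxx_proj, "Dyy_proj": result.Dyy_proj,
        "Dzz_proj": result.Dzz_proj, "Dxx_assoc": result.Dxx_assoc,
        "Dyy_assoc": result.Dyy_assoc, "Dzz_assoc": result.Dzz_assoc,
        "n_voxels_proj": result.n_voxels_proj,
        "n_voxels_assoc": result.n_voxels_assoc,
        "roi_proj_center": "{:.3f};{:.3f};{:.3f}".format(*result.roi_proj.center),
        "roi_assoc_center": "{:.3f};{:.3f};{:.3f}".format(*result.roi_assoc.center),
        "method": result.method,
    }
    header = not os.path.exists(path)
    pd.DataFrame([row]).to_csv(path, mode="a", header=header, index=False)


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    missing = [c for c in COHORT_COLUMNS if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    cohort[COHORT_COLUMNS].to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    bad = df.loc[~df["group"].isin(["NC", "ePD", "lPD"]), "group"].unique()
    if len(bad):
        raise ValueError(f"{path}: unknown group labels {list(bad)}")
    return df
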