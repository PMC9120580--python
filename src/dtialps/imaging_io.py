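"""Readers and writers for the formats the pipeline touches.

NIfTI-1 volumes (via nibabel), FSL-style bval/bvec text files, and cohort
CSV tables.  The pipeline operates in voxel space; the world affine from
the NIfTI header is carried through but never used for resampling.
"""

from __future__ import annotations

import os
from typing import List, Optional, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .types import (
    COMPONENT_NAMES,
    DWIVolume,
    FormatError,
    GradientScheme,
    SubjectRecord,
    TensorField,
    ValidationError,
)

#: on-disk names of the six component maps, matching COMPONENT_NAMES order
COMPONENT_FILENAMES = ("Dxx", "Dyy", "Dzz", "Dxy", "Dxz", "Dyz")

_GROUP_ALIASES = {"osa": "OSA", "control": "control", "ctrl": "control", "con": "control"}
_SEX_ALIASES = {
    "m": "male",
    "male": "male",
    "0": "male",
    "f": "female",
    "female": "female",
    "1": "female",
}

_OPTIONAL_NUMERIC = (
    "bmi",
    "heart_rate",
    "systolic_bp",
    "diastolic_bp",
    "ahi",
    "sao2_nadir",
    "sao2_baseline",
    "psqi",
    "ess",
)


def read_bvals_bvecs(bval_path, bvec_path, transposed: bool = False):
    """Read FSL-layout gradient files (bvals one row; bvecs 3 rows x N cols).

    With ``transposed=True`` a column-per-frame bvec layout (N rows x 3
    cols) is accepted; 3x3 files are always interpreted as FSL rows.
    """
    bvals = np.loadtxt(bval_path, dtype=float).ravel()
    bvecs = np.atleast_2d(np.loadtxt(bvec_path, dtype=float))
    if bvecs.ndim != 2 or 3 not in bvecs.shape:
        raise FormatError(f"bvec file {bvec_path} is not 3xN or Nx3: shape {bvecs.shape}")
    if transposed:
        if bvecs.shape[1] != 3:
            bvecs = bvecs.T
    else:
        if bvecs.shape[0] == 3:
            bvecs = bvecs.T
    if len(bvals) != len(bvecs):
        raise FormatError(
            f"frame count mismatch between {bval_path} ({len(bvals)} b-values) "
            f"and {bvec_path} ({len(bvecs)} directions)"
        )
    return GradientScheme(bvals=bvals, bvecs=bvecs)


def read_dwi(nifti_path, bval_path, bvec_path, transposed_bvec: bool = False) -> DWIVolume:
    """Load a 4-D DWI NIfTI with its FSL-style gradient table."""
    img = nib.load(str(nifti_path))
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim != 4:
        raise FormatError(f"{nifti_path} is not 4-D (shape {data.shape})")
    scheme = read_bvals_bvecs(bval_path, bvec_path, transposed=transposed_bvec)
    if data.shape[3] != scheme.n_frames:
        raise FormatError(
            f"frame count mismatch: {nifti_path} has {data.shape[3]} frames but "
            f"the gradient table has {scheme.n_frames}"
        )
    voxel_size = np.asarray(img.header.get_zooms()[:3], dtype=float)
    return DWIVolume(
        data=data, scheme=scheme, voxel_size=voxel_size, affine=np.asarray(img.affine)
    )


def write_dwi(vol: DWIVolume, nifti_path, bval_path, bvec_path) -> None:
    """Write a DWIVolume as NIfTI + FSL bval/bvec text files."""
    img = nib.Nifti1Image(vol.data.astype(np.float32), vol.affine)
    img.header.set_zooms(tuple(vol.voxel_size) + (1.0,))
    nib.save(img, str(nifti_path))
    np.savetxt(bval_path, vol.scheme.bvals[None, :], fmt="%.6g")
    np.savetxt(bvec_path, vol.scheme.bvecs.T, fmt="%.8f")


def write_scalar_map(array: np.ndarray, affine: np.ndarray, path) -> str:
    img = nib.Nifti1Image(np.asarray(array, dtype=np.float32), affine)
    nib.save(img, str(path))
    return str(path)


def write_component_maps(field: TensorField, out_dir) -> List[str]:
    """Write the six diffusivity maps (mm^2/s) as Dxx..Dyz NIfTI files.

    Out-of-mask voxels are written as 0.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths = []
    for k, name in enumerate(COMPONENT_FILENAMES):
        comp = np.where(field.mask, field.components[..., k], 0.0)
        path = os.path.join(str(out_dir), f"{name}.nii.gz")
        paths.append(write_scalar_map(comp, field.affine, path))
    return paths


def _norm_group(raw) -> str:
    key = str(raw).strip().lower()
    if key not in _GROUP_ALIASES:
        raise ValidationError(f"unknown group label: {raw!r} (expected OSA or control)")
    return _GROUP_ALIASES[key]


def _norm_sex(raw) -> str:
    key = str(raw).strip().lower()
    if key not in _SEX_ALIASES:
        raise ValidationError(f"unknown sex label: {raw!r} (expected male or female)")
    return _SEX_ALIASES[key]


def _opt_float(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    if isinstance(value, str) and not value.strip():
        return None
    return float(value)


def read_cohort_table(csv_path) -> List[SubjectRecord]:
    """Read a cohort CSV into typed subject records.

    Required columns: id, group, age, sex.  Optional clinical columns may
    be absent or blank; blanks become explicit missing markers (None).
    """
    df = pd.read_csv(csv_path)
    required = {"id", "group", "age", "sex"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"cohort table {csv_path} lacks columns: {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        try:
            age = float(row["age"])
        except (TypeError, ValueError) as exc:
            raise ValidationError(
                f"non-numeric age {row['age']!r} for subject {row['id']!r}"
            ) from exc
        kwargs = {}
        for name in _OPTIONAL_NUMERIC:
            if name in df.columns:
                kwargs[name] = _opt_float(row[name])
        records.append(
            SubjectRecord(
                id=str(row["id"]),
                group=_norm_group(row["group"]),
                age=age,
                sex=_norm_sex(row["sex"]),
                **kwargs,
            )
        )
    return records


def cohort_frame(records: Sequence[SubjectRecord]) -> pd.DataFrame:
    """Flatten subject records (and any ALPS results) into a tidy table."""
    rows = []
    for rec in records:
        row = {
            "id": rec.id,
            "group": rec.group,
            "age": rec.age,
            "sex": rec.sex,
            "bmi": rec.bmi,
            "heart_rate": rec.heart_rate,
            "systolic_bp": rec.systolic_bp,
            "diastolic_bp": rec.diastolic_bp,
            "ahi": rec.ahi,
            "sao2_nadir": rec.sao2_nadir,
            "sao2_baseline": rec.sao2_baseline,
            "delta_sao2": rec.delta_sao2,
            "psqi": rec.psqi,
            "ess": rec.ess,
        }
        if rec.alps is not None:
            row.update(rec.alps.to_row())
        rows.append(row)
    return pd.DataFrame(rows)


def write_cohort_table(records: Sequence[SubjectRecord], csv_path) -> str:
    cohort_frame(records).to_csv(csv_path, index=False)
    return str(csv_path)
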