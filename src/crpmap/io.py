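"""File formats: subject tables (TSV), volumes (NIfTI-1), configs (YAML)."""

from __future__ import annotations

import json
import pathlib

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "read_subject_table",
    "write_subject_table",
    "read_nifti",
    "write_nifti",
    "load_config",
    "read_region_table",
]

NA_VALUES = ["", "NA", "NaN", "nan", "."]

_NUMERIC = ("crp", "crp_z", "age", "sex", "education", "fd", "bmi")


def read_subject_table(path) -> pd.DataFrame:
    """Read a per-subject TSV with typed columns and unit checks.

    Requires ``subject_id`` and ``group``; any of the standard covariate
    columns present are coerced to float (standard missing-value codes are
    honored).  Raises on malformed rows, reporting the 1-based data line.
    """
    path = pathlib.Path(path)
    df = pd.read_csv(path, sep="\t", na_values=NA_VALUES, keep_default_na=True)
    for required in ("subject_id", "group"):
        if required not in df.columns:
            raise ValueError(f"{path}: missing column '{required}'")
    for col in df.columns:
        if col in ("subject_id", "group"):
            continue
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError):
            bad = pd.to_numeric(df[col], errors="coerce")
            line = int(np.where(bad.isna() & df[col].notna())[0][0]) + 2
            raise ValueError(
                f"{path}: non-numeric value in column '{col}' at line {line}")
    if "crp" in df.columns and (df["crp"].dropna() < 0).any():
        raise ValueError(f"{path}: CRP must be >= 0 mg/L")
    return df


def write_subject_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_nifti(path):
    """Load a NIfTI volume; returns (data array, affine)."""
    img = nib.load(str(path))
    return np.asarray(img.dataobj), img.affine


def write_nifti(data: np.ndarray, path, affine: np.ndarray | None = None,
                voxel_size: float = 1.0) -> None:
    if affine is None:
        affine = np.diag([voxel_size] * 3 + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(data), affine), str(path))


def read_region_table(path, index_col: str = "region_id") -> pd.DataFrame:
    """Region-level TSV (annotation maps, expression, gray-matter prob)."""
    return pd.read_csv(path, sep="\t", index_col=index_col)


def load_config(path) -> dict:
    path = pathlib.Path(path)
    with open(path) as fh:
        if path.suffix in (".yaml", ".yml"):
            return yaml.safe_load(fh)
        return json.load(fh)
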