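"""File formats: trial tables and motion as TSV, images as NIfTI-1,
configuration as YAML, reports as JSON."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "TRIAL_COLUMNS", "read_trial_table", "write_trial_table",
    "read_motion", "write_motion", "load_nifti", "save_nifti",
    "load_yaml", "save_yaml", "save_json", "load_json",
]

TRIAL_COLUMNS = [
    "subject_id", "task", "block", "trial", "cond_id", "exposure_ms",
    "masked", "hemifield", "n_targets", "n_distractors", "score",
    "target1_reported", "target2_reported",
]


class SchemaError(ValueError):
    """A table does not match the expected schema; names the offender."""


def read_trial_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"trial table {path} missing columns: {missing}")
    bad_task = set(df["task"]) - {"whole", "partial"}
    if bad_task:
        raise SchemaError(f"trial table {path}: unknown task values {bad_task}")
    return df


def write_trial_table(df: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"trial table missing columns: {missing}")
    df.to_csv(path, sep="\t", index=False, columns=TRIAL_COLUMNS)


def write_motion(motion: np.ndarray, path: str | Path) -> None:
    cols = ["trans_x_mm", "trans_y_mm", "trans_z_mm",
            "rot_x_deg", "rot_y_deg", "rot_z_deg"]
    pd.DataFrame(np.asarray(motion), columns=cols).to_csv(
        path, sep="\t", index=False)


def read_motion(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] != 6:
        raise SchemaError(f"motion table {path} must have 6 columns, "
                          f"has {df.shape[1]}")
    return df.to_numpy(float)


def save_nifti(data: np.ndarray, path: str | Path,
               tr: float | None = None) -> None:
    """Write a 3D/4D array as NIfTI-1 with identity affine (voxel space)."""
    img = nib.Nifti1Image(np.asarray(data), affine=np.eye(4))
    if tr is not None and data.ndim == 4:
        zooms = list(img.header.get_zooms())
        zooms[3] = tr
        img.header.set_zooms(zooms)
        img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))


def load_nifti(path: str | Path) -> tuple[np.ndarray, float | None]:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    tr = float(img.header.get_zooms()[3]) if data.ndim == 4 else None
    return data, tr


def _to_jsonable(obj):
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def save_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_to_jsonable(obj), indent=2) + "\n")


def load_json(path: str | Path):
    return json.loads(Path(path).read_text())


def save_yaml(obj, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(_to_jsonable(obj), sort_keys=False))


def load_yaml(path: str | Path):
    return yaml.safe_load(Path(path).read_text())
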