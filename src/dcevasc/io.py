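"""File formats: NIfTI-1 volumes and 4-D series with BIDS-style JSON
sidecars for frame timing, CSV cohort tables with schema validation,
two-column AIF CSVs and YAML configs.

Conventions: arrays are written in (x, y, z[, t]) order with the voxel
spacing in the NIfTI affine/zooms; frame times (seconds) live in a JSON
sidecar next to the image (``series.nii.gz`` ↔ ``series.json``, key
``FrameTimes``).  World orientation is not used by any algorithm.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence, Union

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .containers import AIF, DCESeries, VolumeImage

__all__ = [
    "FormatError",
    "read_dce", "write_dce",
    "read_volume", "write_volume",
    "read_table", "write_table",
    "read_aif", "write_aif",
    "load_config", "save_config",
    "DEFAULT_ARMS", "DEFAULT_TIMEPOINTS",
]

DEFAULT_ARMS = ("chemo", "chemo+bev")
DEFAULT_TIMEPOINTS = ("baseline", "1w", "12w", "25w")

TABLE_COLUMNS = ["subject", "arm", "timepoint", "metric", "value"]


class FormatError(ValueError):
    """A file does not follow the expected on-disk convention."""


def _sidecar_path(path: Union[str, Path]) -> Path:
    p = Path(path)
    name = p.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return p.with_name(name[: -len(suffix)] + ".json")
    return p.with_suffix(".json")


def _affine(spacing) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def write_dce(series: DCESeries, path: Union[str, Path]) -> Path:
    """Write a 4-D series as NIfTI plus a JSON sidecar with frame times."""
    path = Path(path)
    img = nib.Nifti1Image(series.data, _affine(series.voxel_spacing))
    dt = np.diff(series.frame_times)
    img.header.set_zooms(series.voxel_spacing + (float(dt[0]),))
    nib.save(img, path)
    sidecar = {"FrameTimes": [float(t) for t in series.frame_times],
               "meta": _jsonable(series.meta)}
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def read_dce(path: Union[str, Path]) -> DCESeries:
    """Read a 4-D series; frame times come from the JSON sidecar, or from a
    uniform repetition interval in the NIfTI header as fallback."""
    path = Path(path)
    img = nib.load(path)
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise FormatError(
            f"{path}: expected a 4-D series, got {data.ndim}-D data")
    zooms = img.header.get_zooms()
    spacing = tuple(float(z) for z in zooms[:3])
    sidecar = _sidecar_path(path)
    meta = {}
    if sidecar.exists():
        payload = json.loads(sidecar.read_text())
        if "FrameTimes" not in payload:
            raise FormatError(
                f"{sidecar}: sidecar lacks the 'FrameTimes' key")
        times = np.asarray(payload["FrameTimes"], dtype=float)
        meta = payload.get("meta", {})
    elif len(zooms) > 3 and zooms[3] > 0:
        times = np.arange(data.shape[3]) * float(zooms[3])
    else:
        raise FormatError(
            f"{path}: no frame timing found; provide a JSON sidecar "
            f"({sidecar.name}) with a 'FrameTimes' list in seconds, or a "
            f"positive repetition interval in the NIfTI header")
    return DCESeries(data=data, frame_times=times, voxel_spacing=spacing,
                     meta=meta)


def write_volume(vol: VolumeImage, path: Union[str, Path]) -> Path:
    path = Path(path)
    data = vol.data.astype(np.uint8) if vol.role == "mask" else vol.data
    img = nib.Nifti1Image(data, _affine(vol.voxel_spacing))
    img.header.set_zooms(vol.voxel_spacing)
    nib.save(img, path)
    sidecar = {"role": vol.role, "meta": _jsonable(vol.meta)}
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def read_volume(path: Union[str, Path], role: Optional[str] = None) -> VolumeImage:
    path = Path(path)
    img = nib.load(path)
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3-D volume, got {data.ndim}-D")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    sidecar = _sidecar_path(path)
    meta = {}
    if role is None:
        role = "parameter_map"
        if sidecar.exists():
            payload = json.loads(sidecar.read_text())
            role = payload.get("role", role)
            meta = payload.get("meta", {})
    return VolumeImage(data=data, voxel_spacing=spacing, role=role, meta=meta)


def write_table(table: pd.DataFrame, path: Union[str, Path]) -> Path:
    """Write a cohort table CSV, preserving float precision to 1e-12."""
    _validate_table(table, arms=None, timepoints=None)
    path = Path(path)
    table.to_csv(path, index=False, float_format="%.17g")
    return path


def read_table(
    path: Union[str, Path],
    arms: Sequence[str] = DEFAULT_ARMS,
    timepoints: Sequence[str] = DEFAULT_TIMEPOINTS,
) -> pd.DataFrame:
    """Read and validate a cohort table CSV.

    Rows with arm or timepoint labels outside the configured vocabularies
    are rejected with an error listing the offending rows.
    """
    table = pd.read_csv(path)
    _validate_table(table, arms=arms, timepoints=timepoints)
    return table


def _validate_table(table: pd.DataFrame, arms, timepoints):
    missing = [c for c in TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"cohort table lacks columns {missing}")
    if not np.issubdtype(pd.to_numeric(table["value"], errors="coerce").dtype,
                         np.number) or table["value"].isna().any():
        bad = table.index[pd.to_numeric(table["value"],
                                        errors="coerce").isna()].tolist()
        raise FormatError(f"non-numeric 'value' in rows {bad}")
    for column, allowed in (("arm", arms), ("timepoint", timepoints)):
        if allowed is None:
            continue
        bad = table.index[~table[column].isin(allowed)].tolist()
        if bad:
            labels = sorted(table.loc[bad, column].unique())
            raise FormatError(
                f"unknown {column} label(s) {labels} in rows {bad}; "
                f"allowed: {list(allowed)}")
    dup = table.duplicated(subset=["subject", "timepoint", "metric"])
    if dup.any():
        raise FormatError(
            f"duplicate (subject, timepoint, metric) rows at "
            f"{table.index[dup].tolist()}")


def write_aif(aif: AIF, path: Union[str, Path]) -> Path:
    """Two-column CSV: time_s, cp_mM."""
    path = Path(path)
    pd.DataFrame({"time_s": aif.times, "cp_mM": aif.cp}).to_csv(
        path, index=False, float_format="%.17g")
    return path


def read_aif(path: Union[str, Path]) -> AIF:
    df = pd.read_csv(path)
    for col in ("time_s", "cp_mM"):
        if col not in df.columns:
            raise FormatError(f"{path}: AIF CSV needs columns time_s, cp_mM")
    return AIF(times=df["time_s"].to_numpy(), cp=df["cp_mM"].to_numpy())


def load_config(path: Union[str, Path]) -> dict:
    with open(path) as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise FormatError(f"{path}: config must be a YAML mapping")
    return config


def save_config(config: dict, path: Union[str, Path]) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(config, sort_keys=False))
    return path


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
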