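"""Reading and writing volumes, masks, manifests and feature tables.

Conventions (used by every module):

* arrays are ``(z, y, x)`` with ``z = 0`` the most superficial slice,
  z increasing into the skin;
* voxel spacing is ``(dz, dy, dx)`` in micrometres and is always explicit —
  a scan without spacing metadata is an error, never a silent assumption;
* amplitudes stay in the device's arbitrary units (A.U.); no SI conversion.

On-disk layout per subject: one single-channel TIFF stack per wavelength
(``<stem>_575nm.tif`` …) plus a JSON sidecar ``<stem>_meta.json`` with spacing
and wavelength list.  Boolean masks go to NRRD.  Cohort manifests and feature
tables are plain CSV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import SimpleITK as sitk
import tifffile
import yaml

from .grid import VoxelGrid

__all__ = [
    "MultiwavelengthScan",
    "write_scan",
    "read_scan",
    "write_mask_nrrd",
    "read_mask_nrrd",
    "FEATURE_COLUMNS",
    "write_feature_table",
    "read_feature_table",
    "validate_feature_table",
    "write_manifest",
    "read_manifest",
    "load_yaml_config",
]


@dataclass
class MultiwavelengthScan:
    """Per-wavelength 3D amplitude volumes sharing one voxel grid.

    ``volumes`` maps wavelength (nm) to a non-negative float array in
    arbitrary units.  All volumes must share one shape; spacing is µm.
    """

    volumes: dict[float, np.ndarray]
    spacing_um: tuple[float, float, float]
    subject_id: str = ""

    def __post_init__(self) -> None:
        if not self.volumes:
            raise ValueError("scan must contain at least one wavelength volume")
        shapes = {v.shape for v in self.volumes.values()}
        if len(shapes) != 1:
            raise ValueError(f"volumes disagree on shape: {shapes}")
        for wl, v in self.volumes.items():
            if v.ndim != 3:
                raise ValueError(f"{wl} nm volume is not 3D (shape {v.shape})")
            if not np.all(np.isfinite(v)):
                raise ValueError(f"{wl} nm volume contains non-finite amplitudes")
        if len(self.spacing_um) != 3 or any(s <= 0 for s in self.spacing_um):
            raise ValueError(f"spacing must be three positive floats, got {self.spacing_um}")
        self.spacing_um = tuple(float(s) for s in self.spacing_um)
        self.volumes = {float(k): v for k, v in self.volumes.items()}

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.volumes.values())).shape

    @property
    def wavelengths_nm(self) -> tuple[float, ...]:
        return tuple(sorted(self.volumes))

    @property
    def grid(self) -> VoxelGrid:
        return VoxelGrid(shape=self.shape, spacing_um=self.spacing_um)

    def volume(self, wavelength_nm: float) -> np.ndarray:
        """Volume at a wavelength; KeyError naming the missing wavelength."""
        key = float(wavelength_nm)
        for wl, v in self.volumes.items():
            if abs(wl - key) < 0.5:
                return v
        raise KeyError(
            f"scan '{self.subject_id}' has no {wavelength_nm} nm volume "
            f"(available: {self.wavelengths_nm})"
        )

    def has_wavelength(self, wavelength_nm: float) -> bool:
        return any(abs(wl - float(wavelength_nm)) < 0.5 for wl in self.volumes)


# ---------------------------------------------------------------------------
# scan I/O


def write_scan(scan: MultiwavelengthScan, directory: str | Path, stem: str) -> dict:
    """Write one TIFF stack per wavelength + a JSON metadata sidecar.

    Returns the manifest fragment: a dict with per-wavelength paths and the
    sidecar path.  Float volumes are stored as float32 (bit-exact round-trip
    for float32 inputs); integer volumes keep their dtype.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    for wl in scan.wavelengths_nm:
        vol = scan.volume(wl)
        if np.issubdtype(vol.dtype, np.floating):
            vol = vol.astype(np.float32)
        fname = directory / f"{stem}_{int(round(wl))}nm.tif"
        tifffile.imwrite(fname, vol)
        paths[f"path_{int(round(wl))}"] = str(fname)
    meta = {
        "subject_id": scan.subject_id,
        "spacing_um": list(scan.spacing_um),
        "wavelengths_nm": list(scan.wavelengths_nm),
    }
    meta_path = directory / f"{stem}_meta.json"
    meta_path.write_text(json.dumps(meta, indent=1))
    paths["meta_path"] = str(meta_path)
    return paths


def read_scan(row: Mapping[str, object]) -> MultiwavelengthScan:
    """Load a scan from a manifest row.

    The row must provide ``meta_path`` (JSON sidecar with ``spacing_um`` and
    ``wavelengths_nm``) and ``path_<wl>`` entries for each wavelength; absent
    or empty path columns are skipped, so partial scans (e.g. 575+650 without
    586) load fine and the stages that need the missing wavelength refuse
    later with a clear error.
    """
    meta_path = row.get("meta_path")
    if not meta_path or (isinstance(meta_path, float) and np.isnan(meta_path)):
        raise ValueError("manifest row lacks 'meta_path'; spacing metadata is required")
    meta = json.loads(Path(str(meta_path)).read_text())
    if "spacing_um" not in meta:
        raise ValueError(f"metadata {meta_path} lacks 'spacing_um'")
    volumes: dict[float, np.ndarray] = {}
    for key, value in row.items():
        if not str(key).startswith("path_") or key == "path_truth":
            continue
        if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
            continue
        wl = float(str(key).split("_", 1)[1])
        path = Path(str(value))
        try:
            vol = tifffile.imread(path)
        except Exception as exc:  # surface the offending file
            raise IOError(f"failed to read TIFF {path}: {exc}") from exc
        volumes[wl] = np.asarray(vol)
    if not volumes:
        raise ValueError("manifest row has no readable path_<wavelength> entries")
    shapes = {v.shape for v in volumes.values()}
    if len(shapes) != 1:
        detail = {f"{wl} nm": volumes[wl].shape for wl in volumes}
        raise ValueError(f"wavelength stacks disagree on shape: {detail}")
    return MultiwavelengthScan(
        volumes=volumes,
        spacing_um=tuple(meta["spacing_um"]),
        subject_id=str(row.get("subject_id", meta.get("subject_id", ""))),
    )


# ---------------------------------------------------------------------------
# masks (NRRD)


def write_mask_nrrd(
    mask: np.ndarray, spacing_um: tuple[float, float, float], path: str | Path
) -> None:
    """Write a boolean mask as uint8 NRRD with spacing metadata (µm)."""
    img = sitk.GetImageFromArray(mask.astype(np.uint8))
    # SimpleITK spacing is (x, y, z) for a (z, y, x) array
    img.SetSpacing(tuple(float(s) for s in spacing_um[::-1]))
    sitk.WriteImage(img, str(path), useCompression=False)


def read_mask_nrrd(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = sitk.ReadImage(str(path))
    mask = sitk.GetArrayFromImage(img).astype(bool)
    spacing = tuple(float(s) for s in img.GetSpacing()[::-1])
    return mask, spacing


# ---------------------------------------------------------------------------
# feature tables

FEATURE_COLUMNS = [
    "subject_id",
    "age",
    "layer",
    "mean_thickness_um",
    "total_volume_voxels",
    "branch_count",
    "mean_so2",
    "melanin_volume_voxels",
]


def validate_feature_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the per-subject × per-layer feature table contract.

    One row per subject × layer (layers 1 and 2); volumes and branch counts
    non-negative integers; mean SO2 in [0, 1] or missing.  Returns the table
    with columns in the canonical order.
    """
    missing = [c for c in FEATURE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"feature table missing columns: {missing}")
    if len(table):
        if not table["layer"].isin([1, 2]).all():
            raise ValueError("layer must be 1 or 2")
        for col in ("total_volume_voxels", "branch_count", "melanin_volume_voxels"):
            vals = table[col].dropna()
            if (vals < 0).any():
                raise ValueError(f"{col} must be non-negative")
            if not np.allclose(vals, np.round(vals)):
                raise ValueError(f"{col} must be integer voxel counts")
        so2 = table["mean_so2"].dropna()
        if ((so2 < 0) | (so2 > 1)).any():
            raise ValueError("mean_so2 must lie in [0, 1] or be missing")
        dup = table.duplicated(subset=["subject_id", "layer"])
        if dup.any():
            raise ValueError("duplicate subject × layer rows")
    return table[FEATURE_COLUMNS]


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    validate_feature_table(table).to_csv(path, index=False)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    return validate_feature_table(table)


# ---------------------------------------------------------------------------
# cohort manifest

MANIFEST_COLUMNS = ["subject_id", "age", "path_575", "path_586", "path_650", "meta_path", "path_truth"]


def write_manifest(rows: list[dict], path: str | Path) -> None:
    df = pd.DataFrame(rows)
    for col in MANIFEST_COLUMNS:
        if col not in df.columns:
            df[col] = ""
    df[MANIFEST_COLUMNS].to_csv(path, index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "subject_id" not in df.columns:
        raise ValueError(f"manifest {path} lacks a subject_id column")
    return df


# ---------------------------------------------------------------------------
# YAML config


def load_yaml_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a YAML mapping")
    return cfg
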