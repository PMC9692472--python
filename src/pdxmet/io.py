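"""File I/O: NIfTI volumes, JSON sidecars, YAML config snapshots.

Volumes are written as uncompressed NIfTI-1 with a diagonal affine built
from the voxel spacing; masks are 0/1 uint8 volumes. Dynamic metabolic
grids are stored as 4-D NIfTI ``(x, y, metabolite, time)`` with metabolite
index 0 = pyruvate, 1 = lactate, plus a JSON timing sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .containers import DWISeries, DynamicMetaboliteGrid, ImageVolume, ROISet

__all__ = [
    "save_volume", "load_volume", "save_mask", "load_mask",
    "save_dwi", "load_dwi", "save_dynamic_grid", "load_dynamic_grid",
    "write_json", "read_json", "write_yaml", "read_yaml",
]


def _affine(spacing) -> np.ndarray:
    aff = np.diag(list(spacing[:3]) + [1.0])
    return aff


def save_volume(path: str | Path, data: np.ndarray,
                spacing=(1.0, 1.0, 1.0)) -> None:
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), _affine(spacing))
    nib.save(img, str(path))


def load_volume(path: str | Path) -> ImageVolume:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return ImageVolume(np.asarray(img.dataobj, dtype=float), spacing)


def save_mask(path: str | Path, mask: np.ndarray,
              spacing=(1.0, 1.0, 1.0)) -> None:
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), _affine(spacing))
    nib.save(img, str(path))


def load_mask(path: str | Path) -> np.ndarray:
    img = nib.load(str(path))
    return np.asarray(img.dataobj) > 0


def load_rois(tumor_path: str | Path, kidney_path: str | Path) -> ROISet:
    return ROISet(tumor=load_mask(tumor_path), kidney=load_mask(kidney_path))


def save_dwi(path: str | Path, series: DWISeries) -> None:
    """Write the 4-D series plus a ``<stem>.bvals.json`` sidecar."""
    path = Path(path)
    img = nib.Nifti1Image(series.signal.astype(np.float64),
                          _affine(series.spacing))
    nib.save(img, str(path))
    write_json(path.with_suffix("").with_suffix(".bvals.json"),
               {"bvalues_s_per_mm2": [float(b) for b in series.bvalues]})


def load_dwi(path: str | Path) -> DWISeries:
    path = Path(path)
    img = nib.load(str(path))
    sidecar = read_json(path.with_suffix("").with_suffix(".bvals.json"))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return DWISeries(signal=np.asarray(img.dataobj, dtype=float),
                     bvalues=np.asarray(sidecar["bvalues_s_per_mm2"]),
                     spacing=spacing)


def save_dynamic_grid(path: str | Path, grid: DynamicMetaboliteGrid) -> None:
    path = Path(path)
    stacked = np.stack([grid.pyruvate, grid.lactate], axis=2)  # (x, y, met, t)
    img = nib.Nifti1Image(stacked.astype(np.float64), np.eye(4))
    nib.save(img, str(path))
    write_json(path.with_suffix("").with_suffix(".timing.json"),
               {"times_s": [float(t) for t in grid.times],
                "noise_sd": float(grid.noise_sd),
                "metabolite_axis": ["pyruvate", "lactate"]})


def load_dynamic_grid(path: str | Path) -> DynamicMetaboliteGrid:
    path = Path(path)
    data = np.asarray(nib.load(str(path)).dataobj, dtype=float)
    sidecar = read_json(path.with_suffix("").with_suffix(".timing.json"))
    return DynamicMetaboliteGrid(pyruvate=data[:, :, 0, :],
                                 lactate=data[:, :, 1, :],
                                 times=np.asarray(sidecar["times_s"]),
                                 noise_sd=float(sidecar.get("noise_sd", 0.0)))


def write_json(path: str | Path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def write_yaml(path: str | Path, payload: dict) -> None:
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


def read_yaml(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())
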