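"""In-memory image containers and NIfTI-1 I/O.

A :class:`BoldImage` is one subject's 4D BOLD acquisition (3D voxel grid x
time); an :class:`AmplitudeMap` is any derived 3D scalar map (PerAF %, ALFF,
fALFF, or a t-statistic) that shares the grid and affine of its source.
Volumes are read and written with :mod:`nibabel`; map metadata travels in a
JSON sidecar next to the ``.nii.gz``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import ValidationError

#: Recognised metric names for AmplitudeMap.metric.
METRICS = ("PerAF", "mPerAF", "ALFF", "fALFF", "t")


def _check_affine(affine: np.ndarray) -> np.ndarray:
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise ValidationError(f"affine must be 4x4, got {affine.shape}")
    return affine


def voxel_sizes_mm(affine: np.ndarray) -> np.ndarray:
    """Per-axis voxel edge lengths in mm (norms of the affine columns)."""
    return np.sqrt((np.asarray(affine)[:3, :3] ** 2).sum(axis=0))


@dataclass
class BoldImage:
    """A 4D BOLD volume: ``data[x, y, z, t]`` plus timing and geometry.

    Parameters
    ----------
    data : 4D array of signal intensities.
    affine : 4x4 voxel-to-reference-space (mm) transform.
    tr_s : repetition time in seconds.
    meta : free-form provenance (preprocessing steps applied, clip/shift
        policy of the simulator, ...).
    """

    data: np.ndarray
    affine: np.ndarray
    tr_s: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValidationError(f"BOLD data must be 4D, got {self.data.ndim}D")
        self.affine = _check_affine(self.affine)
        if not self.tr_s > 0:
            raise ValidationError(f"tr_s must be positive, got {self.tr_s}")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]

    def to_nifti(self) -> nib.Nifti1Image:
        img = nib.Nifti1Image(self.data, self.affine)
        img.header.set_zooms((*voxel_sizes_mm(self.affine), self.tr_s))
        img.header.set_xyzt_units("mm", "sec")
        return img

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        nib.save(self.to_nifti(), str(path))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "BoldImage":
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        if data.ndim != 4:
            raise ValidationError(f"{path}: expected a 4D BOLD image, got {data.ndim}D")
        zooms = img.header.get_zooms()
        tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
        return cls(data=data, affine=img.affine, tr_s=tr,
                   meta={"source": str(path)})


@dataclass
class AmplitudeMap:
    """A 3D scalar map defined on a binary mask.

    Values are finite exactly on mask voxels; voxels outside the mask hold
    the sentinel 0 and are excluded from every statistic computed downstream.
    """

    data: np.ndarray
    affine: np.ndarray
    metric: str
    mask: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValidationError(f"map data must be 3D, got {self.data.ndim}D")
        self.affine = _check_affine(self.affine)
        if self.metric not in METRICS:
            raise ValidationError(
                f"unknown metric {self.metric!r}; expected one of {METRICS}")
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.shape != self.data.shape:
            raise ValidationError(
                f"mask shape {self.mask.shape} != data shape {self.data.shape}")
        if not np.all(np.isfinite(self.data[self.mask])):
            raise ValidationError("non-finite values inside the map mask")
        # enforce the sentinel outside the mask
        self.data = np.where(self.mask, self.data, 0.0)

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def masked_values(self) -> np.ndarray:
        return self.data[self.mask]

    def save(self, path: str | Path) -> Path:
        """Write the map as NIfTI plus a JSON sidecar with metric metadata."""
        path = Path(path)
        img = nib.Nifti1Image(self.data.astype(np.float32), self.affine)
        img.header.set_zooms(tuple(voxel_sizes_mm(self.affine)))
        nib.save(img, str(path))
        sidecar = {
            "metric": self.metric,
            "n_mask_voxels": int(self.mask.sum()),
            "mask_checksum": int(np.flatnonzero(self.mask.ravel()).sum()),
            **{k: v for k, v in self.meta.items()
               if isinstance(v, (str, int, float, bool, list))},
        }
        side_path = path.with_suffix("").with_suffix("")  # strip .nii.gz / .nii
        side_path = side_path.parent / (side_path.name + ".json")
        side_path.write_text(json.dumps(sidecar, indent=2, sort_keys=True))
        return path

    @classmethod
    def load(cls, path: str | Path, metric: str = "PerAF",
             mask: np.ndarray | None = None) -> "AmplitudeMap":
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj).astype(float)
        if data.ndim != 3:
            raise ValidationError(f"{path}: expected a 3D map, got {data.ndim}D")
        if mask is None:
            mask = np.isfinite(data)
        return cls(data=np.nan_to_num(data), affine=img.affine, metric=metric,
                   mask=mask, meta={"source": str(path)})


def save_mask(mask: np.ndarray, affine: np.ndarray, path: str | Path) -> Path:
    """Write a binary mask as uint8 NIfTI."""
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), _check_affine(affine))
    nib.save(img, str(path))
    return path


def load_mask(path: str | Path) -> np.ndarray:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValidationError(f"{path}: expected a 3D mask, got {data.ndim}D")
    return data > 0
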