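"""Voxel-volume container with a fixed anatomical axis convention.

All 3D grids in this package share one convention:

* axis 0 = anterior-posterior (AP; out of the DXA image plane),
* axis 1 = superior-inferior (SI; vertical in the DXA image),
* axis 2 = neck axis (the long axis of the femoral-neck VOI).

Label volumes use ``0 = background``, ``1 = cortical bone``,
``2 = trabecular bone``.  Volumes round-trip through NIfTI (nibabel) with
isotropic or per-axis spacing recorded in the affine.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

AX_AP, AX_SI, AX_NECK = 0, 1, 2

BACKGROUND, CORTICAL, TRABECULAR = 0, 1, 2

#: Edge length (mm) of the reference nano-CT voxel that BMC voxel counts are
#: expressed in.  A bone volume of 1 mm^3 equals (1 / 0.027)^3 reference voxels.
REFERENCE_VOXEL_MM = 0.027


class VolumeError(ValueError):
    """Invalid voxel volume or incompatible volume operation."""


@dataclass
class VoxelVolume:
    """A 3D scalar grid (labels, raw intensity, or Hounsfield units).

    Parameters
    ----------
    data
        3D array indexed (AP, SI, neck).
    spacing
        Voxel edge lengths in mm per axis.
    origin
        Physical coordinate of voxel (0, 0, 0) in mm.
    kind
        One of ``"label"``, ``"intensity"``, ``"hu"``, ``"mask"``.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    kind: str = "label"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise VolumeError(f"volume must be 3D, got ndim={self.data.ndim}")
        if min(self.data.shape) < 1:
            raise VolumeError(f"every axis needs >= 1 voxel, got shape {self.data.shape}")
        if np.isscalar(self.spacing):
            self.spacing = (float(self.spacing),) * 3  # type: ignore[assignment]
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise VolumeError(f"spacing must be three positive lengths, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)  # type: ignore[assignment]
        if self.kind not in ("label", "intensity", "hu", "mask"):
            raise VolumeError(f"unknown volume kind {self.kind!r}")

    # -- geometry -----------------------------------------------------------
    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def is_isotropic(self) -> bool:
        return max(self.spacing) - min(self.spacing) < 1e-9

    # -- label helpers ------------------------------------------------------
    def bone_mask(self) -> np.ndarray:
        """Boolean mask of all bone voxels (labels or binary masks)."""
        return self.data > 0

    def label_mask(self, label: int) -> np.ndarray:
        return self.data == label

    def with_data(self, data: np.ndarray, kind: str | None = None) -> "VoxelVolume":
        return replace(self, data=data, kind=kind or self.kind)

    # -- I/O ----------------------------------------------------------------
    def save_nifti(self, path: str | Path) -> Path:
        """Write to NIfTI with spacing in the affine diagonal."""
        path = Path(path)
        affine = np.diag(list(self.spacing) + [1.0])
        affine[:3, 3] = self.origin
        data = self.data
        if self.kind in ("label", "mask"):
            data = data.astype(np.uint8)
        img = nib.Nifti1Image(data, affine)
        img.header.set_zooms(self.spacing)
        nib.save(img, str(path))
        return path

    @classmethod
    def load_nifti(cls, path: str | Path, kind: str = "label") -> "VoxelVolume":
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
        origin = tuple(float(v) for v in img.affine[:3, 3])
        return cls(data=data, spacing=zooms, origin=origin, kind=kind)
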