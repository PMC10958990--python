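"""Bone segmentation and cortical/trabecular partitioning.

Bone-from-background is a recorded global threshold (fixed HU value or Otsu)
on the calibrated volume.  The cortical-from-trabecular partition is a
deterministic morphological procedure: the periosteal envelope is the filled
morphological closing of the bone mask; the endosteal region is the largest
connected component of the closed interior pore space; bone between the two
surfaces is cortical and bone inside the endosteal region is trabecular.
The Dice coefficient quantifies agreement between masks.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import ball

from .volume import CORTICAL, TRABECULAR, VoxelVolume

DEFAULT_THRESHOLD_HU = 800.0
DEFAULT_CLOSING_RADIUS_MM = 1.0


class SegmentationError(ValueError):
    """Invalid input to a segmentation operation."""


def segment_bone(
    volume: VoxelVolume, method: str = "fixed", threshold_hu: float = DEFAULT_THRESHOLD_HU
) -> tuple[VoxelVolume, float]:
    """Threshold a calibrated volume into a binary bone mask.

    Voxels *strictly above* the threshold are bone (ties go to background).
    Returns the mask volume and the threshold actually applied so it can be
    recorded in the run manifest.
    """
    if volume.data.size == 0:
        raise SegmentationError("empty volume")
    if method == "fixed":
        thr = float(threshold_hu)
    elif method == "otsu":
        thr = float(threshold_otsu(volume.data))
    else:
        raise SegmentationError(f"unknown segmentation method {method!r}")
    mask = volume.data > thr
    return volume.with_data(mask, kind="mask"), thr


def partition_cortical_trabecular(
    mask: VoxelVolume, closing_radius_mm: float = DEFAULT_CLOSING_RADIUS_MM
) -> VoxelVolume:
    """Partition a bone mask into cortical and trabecular labels.

    Three deterministic morphological steps:

    1. *Periosteal region*: the bone mask closed with a ball of the given
       radius, then hole-filled.
    2. *Endosteal region*: the pore space inside the periosteal region,
       closed with the same ball; its largest connected component is the
       trabecular cavity.
    3. *Solid-core test*: bone voxels in a one-voxel band around the
       endosteal region that do not survive a one-voxel opening (i.e. are
       not part of the solid cortical plate) are reassigned trabecular,
       which recovers trabecular struts abutting the endosteal surface.

    Bone inside the (extended) endosteal region is trabecular, the rest
    cortical — an exhaustive, exclusive partition of the mask.
    """
    data = mask.bone_mask()
    if not data.any():
        raise SegmentationError("bone mask is empty")
    h = min(mask.spacing)
    r_vox = int(round(closing_radius_mm / h))
    if closing_radius_mm < h or r_vox < 1:
        raise SegmentationError(
            f"closing radius {closing_radius_mm} mm is below the voxel size {h} mm"
        )
    selem = ball(r_vox)
    pad = r_vox + 1
    padded = np.pad(data, pad)
    closed = ndimage.binary_closing(padded, structure=selem)
    periosteal = ndimage.binary_fill_holes(closed)
    pores = periosteal & ~padded
    pores_closed = ndimage.binary_closing(pores, structure=selem) & periosteal
    cc, n_cc = ndimage.label(pores_closed)
    if n_cc > 0:
        sizes = ndimage.sum_labels(np.ones_like(cc), cc, index=np.arange(1, n_cc + 1))
        endosteal = cc == (1 + int(np.argmax(sizes)))
    else:
        endosteal = np.zeros_like(padded)
    opened = ndimage.binary_opening(padded, structure=ball(1))
    endo_band = ndimage.binary_dilation(endosteal, structure=ball(1))
    trabecular = padded & (endosteal | (endo_band & ~opened))
    sl = tuple(slice(pad, -pad) for _ in range(3))
    trabecular = trabecular[sl]

    labels = np.zeros(data.shape, dtype=np.uint8)
    labels[data & ~trabecular] = CORTICAL
    labels[data & trabecular] = TRABECULAR
    return mask.with_data(labels, kind="label")


def dice(mask_a: np.ndarray | VoxelVolume, mask_b: np.ndarray | VoxelVolume) -> float:
    """Dice overlap 2|A n B| / (|A| + |B|); 1.0 when both masks are empty."""
    a = mask_a.bone_mask() if isinstance(mask_a, VoxelVolume) else np.asarray(mask_a, dtype=bool)
    b = mask_b.bone_mask() if isinstance(mask_b, VoxelVolume) else np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise SegmentationError(f"shape mismatch: {a.shape} vs {b.shape}")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


def labels_to_intensity(
    labels: VoxelVolume,
    bone_hu: float = 1500.0,
    background_hu: float = -200.0,
    noise_sd: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> VoxelVolume:
    """Render a label volume as a two-level HU volume with optional noise.

    Used to exercise the threshold-and-partition route on volumes whose
    ground-truth labels are known.
    """
    hu = np.where(labels.bone_mask(), bone_hu, background_hu).astype(np.float64)
    if noise_sd > 0:
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        hu += rng.normal(0.0, noise_sd, size=hu.shape)
    return labels.with_data(hu, kind="hu")
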