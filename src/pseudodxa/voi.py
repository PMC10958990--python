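"""Intensity calibration, anteversion rotation, and FN VOI extraction.

Raw CT grayscale volumes are mapped to Hounsfield units with a two-point
linear calibration anchored on the scan's phantom readings (air -> -1000 HU,
water -> 0 HU); the hydroxyapatite reading is kept as a drift-monitoring QC
value only.  Volumes are then rotated to account for femoral anteversion and
a fixed-width slab perpendicular to the neck axis is extracted as the FN
volume of interest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import AX_AP, AX_NECK, AX_SI, VoxelVolume


class CalibrationError(ValueError):
    """Phantom readings unusable for HU calibration."""


class VOIBoundsError(ValueError):
    """Requested VOI does not fit inside the volume."""


@dataclass(frozen=True)
class PhantomReadings:
    """Mean intensities of the calibration phantom regions."""

    air: float
    water: float
    hydroxyapatite: float

    def validate(self) -> None:
        if not (self.air < self.water < self.hydroxyapatite):
            raise CalibrationError(
                f"phantom readings must satisfy air < water < hydroxyapatite, got "
                f"({self.air}, {self.water}, {self.hydroxyapatite})"
            )


@dataclass
class FNVOISpec:
    """FN VOI: slab width along the neck axis, anteversion, and placement.

    ``center_mm`` is the slab center along the neck axis in physical units;
    ``None`` centers the slab in the volume (the natural placement for
    synthetic prismatic volumes, where 'adjacent to the greater trochanter'
    reduces to slab centering).
    """

    width_mm: float = 15.0
    anteversion_deg: float = 15.0
    center_mm: float | None = None

    def validate(self) -> None:
        if self.width_mm <= 0:
            raise ValueError(f"VOI width must be > 0, got {self.width_mm}")
        if not (-90.0 < self.anteversion_deg < 90.0):
            raise ValueError(f"anteversion must be in (-90, 90), got {self.anteversion_deg}")


def calibrate_to_hu(volume: VoxelVolume, phantom: PhantomReadings) -> VoxelVolume:
    """Two-point linear map of raw intensities to HU.

    Air maps to -1000 HU and water to 0 HU; the map is affine and
    order-preserving.  The hydroxyapatite reading does not enter the map.
    """
    phantom.validate()
    scale = 1000.0 / (phantom.water - phantom.air)
    hu = (volume.data.astype(np.float64) - phantom.water) * scale
    return volume.with_data(hu, kind="hu")


_ROTATION_PLANES = {"x": (AX_SI, AX_NECK), "y": (AX_AP, AX_NECK), "z": (AX_AP, AX_SI)}


def rotate_volume(
    volume: VoxelVolume,
    angle_deg: float,
    axis: str = "y",
    interpolation: str | None = None,
) -> VoxelVolume:
    """Rigid rotation about one grid axis through the volume center.

    Label/mask volumes default to nearest-neighbor resampling, intensity
    volumes to trilinear.  The output grid is enlarged to contain the rotated
    bounding box and padded with background.  Multiples of 90 degrees take a
    lattice-exact path.
    """
    if axis not in _ROTATION_PLANES:
        raise ValueError(f"unknown rotation axis {axis!r}; expected x, y, or z")
    plane = _ROTATION_PLANES[axis]
    if interpolation is None:
        interpolation = "nearest" if volume.kind in ("label", "mask") else "trilinear"
    if interpolation not in ("nearest", "trilinear"):
        raise ValueError(f"unknown interpolation {interpolation!r}")
    s = volume.spacing
    if abs(s[plane[0]] - s[plane[1]]) > 1e-9:
        raise ValueError("rotation requires equal spacing on the two in-plane axes")

    if angle_deg % 360 == 0:
        return volume.with_data(volume.data.copy())
    if angle_deg % 90 == 0:
        k = int(round(angle_deg / 90.0))
        return volume.with_data(np.rot90(volume.data, k=k, axes=plane))

    order = 0 if interpolation == "nearest" else 1
    # Enlarge to the rotated bounding box by symmetric, parity-preserving
    # padding and rotate in place (reshape=False): the rotation center then
    # coincides exactly with the grid center, avoiding the half-voxel shift
    # (and one-face voxel loss) a parity change would introduce.
    theta = np.deg2rad(angle_deg)
    i, j = plane
    ni, nj = volume.data.shape[i], volume.data.shape[j]
    new_i = int(np.ceil(abs(ni * np.cos(theta)) + abs(nj * np.sin(theta))))
    new_j = int(np.ceil(abs(ni * np.sin(theta)) + abs(nj * np.cos(theta))))
    pads = [(0, 0)] * 3
    for ax, n_old, n_new in ((i, ni, new_i), (j, nj, new_j)):
        grow = max(n_new - n_old, 0)
        grow += (grow % 2)  # keep parity: equal padding on both sides
        pads[ax] = (grow // 2, grow // 2)
    padded = np.pad(volume.data, pads)
    rotated = ndimage.rotate(
        padded,
        angle_deg,
        axes=plane,
        reshape=False,
        order=order,
        mode="constant",
        cval=0,
        prefilter=False,
    )
    if volume.kind in ("label", "mask"):
        rotated = rotated.astype(volume.data.dtype)
    return volume.with_data(rotated)


def extract_fn_voi(volume: VoxelVolume, spec: FNVOISpec) -> VoxelVolume:
    """Extract the FN VOI slab perpendicular to the neck axis.

    The slab spans ``round_half_up(width / spacing)`` consecutive slices
    centered at ``spec.center_mm`` (volume center when unset).  Raises
    :class:`VOIBoundsError` when the slab does not fit.
    """
    spec.validate()
    dz = volume.spacing[AX_NECK]
    nz = volume.data.shape[AX_NECK]
    n_slices = int(math.floor(spec.width_mm / dz + 0.5))
    if n_slices < 1:
        raise VOIBoundsError(f"VOI width {spec.width_mm} mm is below one slice at {dz} mm")
    if spec.center_mm is None:
        center_idx = nz / 2.0
    else:
        center_idx = spec.center_mm / dz
    start = int(round(center_idx - n_slices / 2.0))
    stop = start + n_slices
    if start < 0 or stop > nz:
        raise VOIBoundsError(
            f"VOI slices [{start}, {stop}) exceed volume extent {nz} along the neck axis"
        )
    return volume.with_data(volume.data[:, :, start:stop].copy())


def prepare_fn_voi(
    volume: VoxelVolume, spec: FNVOISpec, rotation_axis: str = "y"
) -> VoxelVolume:
    """Anteversion rotation followed by VOI extraction."""
    rotated = rotate_volume(volume, spec.anteversion_deg, axis=rotation_axis)
    return extract_fn_voi(rotated, spec)
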