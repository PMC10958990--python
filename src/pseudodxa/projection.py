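"""PseudoDXA projection: collapse the 3D VOI onto the DXA image plane.

Every bone voxel is projected along the AP axis onto a 2D grid indexed
(neck axis, SI).  Pixel values are projected bone-voxel counts, so the sum
over the image equals the compartment's voxel count exactly.  From the
projected image we read off the DXA-style parameters: projected bone area
(the silhouette), BMC (total bone voxels), aBMD (BMC / area), and the
average and minimum femoral-neck widths.

BMC is expressed in units of 10^6 reference (27 um) voxels so that values
are comparable across rendering resolutions: a count at voxel size ``h`` mm
is scaled by ``(h / 0.027)^3``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np

from . import morphometry
from .volume import AX_AP, CORTICAL, REFERENCE_VOXEL_MM, TRABECULAR, VoxelVolume

COMPARTMENTS = ("total", "cortical", "trabecular")


class ProjectionError(ValueError):
    """Invalid input to a pseudoDXA projection operation."""


@dataclass
class PseudoDXAImage:
    """2D projected bone-voxel count map, indexed (neck axis, SI)."""

    pixels: np.ndarray
    pixel_spacing: tuple[float, float]  # mm along (neck, SI)
    compartment: str = "total"
    projection_axis: str = "AP"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ProjectionError("pseudoDXA image must be 2D")
        if (self.pixels < 0).any():
            raise ProjectionError("projected counts must be non-negative")

    @property
    def pixel_area_cm2(self) -> float:
        return self.pixel_spacing[0] * self.pixel_spacing[1] / 100.0

    def save_tiff(self, path: str | Path) -> Path:
        import tifffile

        path = Path(path)
        arr = self.pixels
        dtype = np.uint16 if arr.max() < 2**16 else np.uint32
        tifffile.imwrite(str(path), arr.astype(dtype))
        return path


def project(voi: VoxelVolume, compartment: str = "total") -> PseudoDXAImage:
    """Project one compartment of a label VOI along the AP ray.

    Pixel (z, y) counts the compartment voxels along AP at that (neck, SI)
    position; the pixel sum equals the compartment voxel count exactly.
    """
    if compartment == "total":
        sel = voi.data > 0
    elif compartment == "cortical":
        sel = voi.data == CORTICAL
    elif compartment == "trabecular":
        sel = voi.data == TRABECULAR
    else:
        raise ProjectionError(f"unknown compartment {compartment!r}; expected one of {COMPARTMENTS}")
    counts = sel.sum(axis=AX_AP).T  # (SI, neck) -> (neck, SI)
    return PseudoDXAImage(
        pixels=counts.astype(np.int64),
        pixel_spacing=(voi.spacing[2], voi.spacing[1]),
        compartment=compartment,
    )


def roi_params(image: PseudoDXAImage) -> tuple[float, int, float]:
    """(area_cm2, BMC_voxels, aBMD) from a projected image.

    Area is the bone silhouette (pixels with any projected bone) times the
    pixel area; BMC the raw projected voxel count; aBMD their ratio in
    voxels per cm^2.
    """
    bmc = int(image.pixels.sum())
    if bmc == 0:
        raise ProjectionError("empty pseudoDXA image: aBMD undefined")
    area = float((image.pixels > 0).sum()) * image.pixel_area_cm2
    return area, bmc, bmc / area


def fn_widths(image: PseudoDXAImage) -> tuple[float, float]:
    """(FNW_avg, FNW_min) in cm from the total-bone pseudoDXA image.

    Per column along the neck axis the width is the SI extent of nonzero
    pixels.  A column without bone means the VOI is misplaced.
    """
    si_spacing_cm = image.pixel_spacing[1] / 10.0
    widths = []
    for z in range(image.pixels.shape[0]):
        (nz_idx,) = np.nonzero(image.pixels[z])
        if nz_idx.size == 0:
            raise ProjectionError(f"neck-axis column {z} contains no bone (misplaced VOI)")
        widths.append((nz_idx.max() - nz_idx.min() + 1) * si_spacing_cm)
    w = np.asarray(widths)
    return float(w.mean()), float(w.min())


# ---------------------------------------------------------------------------
# the per-donor structural readout bundle
# ---------------------------------------------------------------------------

@dataclass
class FNParams:
    """All structural readouts of one femoral-neck VOI.

    BMC values are in 10^6 reference (27 um) voxels; areas in cm^2, volumes
    in cm^3, widths in cm, moments in cm^4.
    """

    area_cm2: float
    bmc: float
    abmd: float
    bmc_cortical: float
    bmc_trabecular: float
    pct_cortical: float
    fnw_avg_cm: float
    fnw_min_cm: float
    tt_ar_cm2: float
    ct_ar_cm2: float
    tt_vol_cm3: float
    bvtv: float
    i_si_cm4: float
    i_ap_cm4: float
    circularity: float
    bmc_per_fnw: float = np.nan
    bmc_per_area15: float = np.nan
    bmc_per_ttar: float = np.nan
    n_bone_voxels: int = 0
    n_cortical_voxels: int = 0
    n_trabecular_voxels: int = 0
    voxel_size_mm: float = np.nan

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def validate(self) -> None:
        if not np.isclose(self.abmd, self.bmc / self.area_cm2):
            raise ProjectionError("aBMD != BMC / area")
        if not np.isclose(self.bmc, self.bmc_cortical + self.bmc_trabecular):
            raise ProjectionError("BMC != cortical + trabecular BMC")
        if self.fnw_min_cm > self.fnw_avg_cm + 1e-12:
            raise ProjectionError("FNW_min > FNW_avg")


def mvox(count: int | float, voxel_size_mm: float) -> float:
    """Convert a voxel count at ``voxel_size_mm`` to 10^6 reference voxels."""
    return count * (voxel_size_mm / REFERENCE_VOXEL_MM) ** 3 / 1e6


def compute_fn_params(voi: VoxelVolume) -> FNParams:
    """Full pseudoDXA + 3D morphometry readout of one label VOI."""
    if not voi.is_isotropic:
        raise ProjectionError("FN parameter extraction expects isotropic voxels")
    h = voi.spacing[0]

    img_total = project(voi, "total")
    img_ct = project(voi, "cortical")
    img_tb = project(voi, "trabecular")
    area, bmc_raw, _ = roi_params(img_total)
    bmc = mvox(bmc_raw, h)
    bmc_ct = mvox(int(img_ct.pixels.sum()), h)
    bmc_tb = mvox(int(img_tb.pixels.sum()), h)
    fnw_avg, fnw_min = fn_widths(img_total)

    section = morphometry.section_properties(voi)
    volume = morphometry.volume_properties(voi, section)

    params = FNParams(
        area_cm2=area,
        bmc=bmc,
        abmd=bmc / area,
        bmc_cortical=bmc_ct,
        bmc_trabecular=bmc_tb,
        pct_cortical=volume.pct_cortical,
        fnw_avg_cm=fnw_avg,
        fnw_min_cm=fnw_min,
        tt_ar_cm2=section.tt_ar_cm2,
        ct_ar_cm2=section.ct_ar_cm2,
        tt_vol_cm3=volume.tt_vol_cm3,
        bvtv=volume.bvtv,
        i_si_cm4=section.i_si_cm4,
        i_ap_cm4=section.i_ap_cm4,
        circularity=section.circularity,
        n_bone_voxels=volume.n_bone,
        n_cortical_voxels=volume.n_cortical,
        n_trabecular_voxels=volume.n_trabecular,
        voxel_size_mm=h,
    )
    params.bmc_per_fnw = morphometry.size_adjusted_bmc(params, "fnw")
    params.bmc_per_area15 = morphometry.size_adjusted_bmc(params, "area1.5")
    params.bmc_per_ttar = morphometry.size_adjusted_bmc(params, "ttar")
    return params
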