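"""3D structural measures of the femoral-neck VOI.

Cross-sectional properties (Tt.Ar, Ct.Ar, second moments of area about the
centroidal SI and AP axes, widths, circularity) are computed slice-by-slice
perpendicular to the neck axis and reported per slice and slice-averaged.
Closed-form elliptical-annulus expressions serve both as generator ground
truth and as independent oracles for the voxel code, and power the
idealized-geometry fit-and-predict experiment relating a BMC gain of a
circular over an elliptical cross-section to its bending-strength gains.

Percent differences throughout use the percent-of-mean convention
``100 * (a - b) / ((a + b) / 2)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize

from .volume import AX_AP, AX_NECK, AX_SI, CORTICAL, TRABECULAR, VoxelVolume

MM2_PER_CM2 = 100.0
MM3_PER_CM3 = 1000.0
MM4_PER_CM4 = 10000.0


class MorphometryError(ValueError):
    """Degenerate input to a morphometric computation."""


@dataclass
class SectionProps:
    """Per-slice and slice-averaged cross-sectional properties (cm units)."""

    tt_ar_cm2: float
    ct_ar_cm2: float
    i_si_cm4: float
    i_ap_cm4: float
    si_width_cm: float
    ap_width_cm: float
    circularity: float
    n_slices: int
    per_slice: dict[str, np.ndarray] = field(repr=False, default_factory=dict)


@dataclass
class VolumeProps:
    """Volumetric measures of the VOI."""

    tt_vol_cm3: float
    bvtv: float
    pct_cortical: float
    n_cortical: int
    n_trabecular: int
    n_bone: int
    n_interior: int


def _filled_silhouette(bone2d: np.ndarray) -> np.ndarray:
    """Periosteal envelope of one cross-section: bone with interior pores filled."""
    return ndimage.binary_fill_holes(bone2d)


def section_properties(voi: VoxelVolume) -> SectionProps:
    """Cross-sectional properties per slice perpendicular to the neck axis.

    Per slice: Tt.Ar is the filled periosteal silhouette area; Ct.Ar the
    cortical-voxel area; second moments are taken over *bone* voxels about
    the centroid of the filled silhouette, with I_AP using SI distances and
    I_SI using AP distances; widths are silhouette extents.  Slices without
    bone are excluded with a warning.
    """
    labels = voi.data
    s_ap, s_si, s_z = voi.spacing
    pix_area_mm2 = s_ap * s_si

    nz = labels.shape[AX_NECK]
    tt, ct, isi, iap, wsi, wap = ([] for _ in range(6))
    kept = []
    for k in range(nz):
        sl = labels[:, :, k]
        bone = sl > 0
        if not bone.any():
            continue
        kept.append(k)
        filled = _filled_silhouette(bone)
        tt.append(filled.sum() * pix_area_mm2)
        ct.append((sl == CORTICAL).sum() * pix_area_mm2)

        ix, iy = np.nonzero(filled)
        # centroid of the filled silhouette, physical mm
        cx = (ix.mean() + 0.5) * s_ap
        cy = (iy.mean() + 0.5) * s_si
        bx, by = np.nonzero(bone)
        x = (bx + 0.5) * s_ap
        y = (by + 0.5) * s_si
        iap.append(((y - cy) ** 2).sum() * pix_area_mm2)  # distances SI
        isi.append(((x - cx) ** 2).sum() * pix_area_mm2)  # distances AP
        wsi.append((iy.max() - iy.min() + 1) * s_si)
        wap.append((ix.max() - ix.min() + 1) * s_ap)

    if not kept:
        raise MorphometryError("no slice of the VOI contains bone")
    if len(kept) < nz:
        warnings.warn(
            f"{nz - len(kept)} of {nz} slices contained no bone and were excluded",
            stacklevel=2,
        )

    tt = np.asarray(tt) / MM2_PER_CM2
    ct = np.asarray(ct) / MM2_PER_CM2
    isi = np.asarray(isi) / MM4_PER_CM4
    iap = np.asarray(iap) / MM4_PER_CM4
    wsi = np.asarray(wsi) / 10.0
    wap = np.asarray(wap) / 10.0
    circ = wap / wsi
    return SectionProps(
        tt_ar_cm2=float(tt.mean()),
        ct_ar_cm2=float(ct.mean()),
        i_si_cm4=float(isi.mean()),
        i_ap_cm4=float(iap.mean()),
        si_width_cm=float(wsi.mean()),
        ap_width_cm=float(wap.mean()),
        circularity=float(circ.mean()),
        n_slices=len(kept),
        per_slice={
            "slice": np.asarray(kept),
            "tt_ar_cm2": tt,
            "ct_ar_cm2": ct,
            "i_si_cm4": isi,
            "i_ap_cm4": iap,
            "si_width_cm": wsi,
            "ap_width_cm": wap,
            "circularity": circ,
        },
    )


def volume_properties(voi: VoxelVolume, section: SectionProps | None = None) -> VolumeProps:
    """Volumetric measures: Tt.Vol, BV/TV, percent cortical, voxel counts.

    Tt.Vol integrates the per-slice Tt.Ar over slice thickness.  BV/TV is
    trabecular bone over the endosteal (interior) volume, the interior being
    everything inside the periosteal envelope that is not cortical.
    """
    labels = voi.data
    if not (labels > 0).any():
        raise MorphometryError("empty volume")
    if section is None:
        section = section_properties(voi)
    n_ct = int((labels == CORTICAL).sum())
    n_tb = int((labels == TRABECULAR).sum())
    n_bone = n_ct + n_tb
    slice_thickness_cm = voi.spacing[AX_NECK] / 10.0
    tt_vol = float(section.per_slice["tt_ar_cm2"].sum() * slice_thickness_cm)
    pix_area_cm2 = voi.spacing[AX_AP] * voi.spacing[AX_SI] / MM2_PER_CM2
    n_filled = int(round(section.per_slice["tt_ar_cm2"].sum() / pix_area_cm2))
    n_interior = n_filled - n_ct
    bvtv = n_tb / n_interior if n_interior > 0 else 0.0
    return VolumeProps(
        tt_vol_cm3=tt_vol,
        bvtv=float(bvtv),
        pct_cortical=100.0 * n_ct / n_bone,
        n_cortical=n_ct,
        n_trabecular=n_tb,
        n_bone=n_bone,
        n_interior=n_interior,
    )


# ---------------------------------------------------------------------------
# closed-form elliptical annulus
# ---------------------------------------------------------------------------

def annulus_section_props(a_si: float, b_ap: float, t: float) -> tuple[float, float, float]:
    """Closed-form (Ct.Ar, I_AP, I_SI) of a uniform-thickness elliptical annulus.

    Parameters are in cm: ``a_si``/``b_ap`` the outer SI/AP semi-axes and
    ``t`` the wall thickness.  The inner boundary is the ellipse with both
    semi-axes reduced by ``t`` (solid section when ``t == min(a_si, b_ap)``).
    I_AP uses SI distances, I_SI uses AP distances, both about centroidal
    axes.  Returns areas in cm^2 and moments in cm^4.
    """
    if not (0 < t <= min(a_si, b_ap) + 1e-12):
        raise MorphometryError(f"thickness t={t} outside (0, min(a_si, b_ap)={min(a_si, b_ap)}]")
    ai = max(a_si - t, 0.0)
    bi = max(b_ap - t, 0.0)
    ct_ar = np.pi * (a_si * b_ap - ai * bi)
    i_ap = np.pi / 4.0 * (b_ap * a_si**3 - bi * ai**3)
    i_si = np.pi / 4.0 * (a_si * b_ap**3 - ai * bi**3)
    return float(ct_ar), float(i_ap), float(i_si)


def pct_of_mean(a: float, b: float) -> float:
    """Percent difference of ``a`` over ``b`` relative to their mean."""
    return 200.0 * (a - b) / (a + b)


_FIG6_KEYS = ("bmc", "ixx", "iyy")


def _shape_gains(q: float, tau: float) -> dict[str, float]:
    """Percent-of-mean gains of a circular over an elliptical section.

    Both sections share the SI outer width (normalized to semi-axis 1) and the
    wall thickness ``tau``; the ellipse has AP/SI outer-width ratio ``q``.
    ``ixx`` is the moment about the horizontal (AP) axis, i.e. SI distances;
    ``iyy`` about the vertical (SI) axis, i.e. AP distances.
    """
    a_c, i_c_ap, i_c_si = annulus_section_props(1.0, 1.0, tau)
    a_e, i_e_ap, i_e_si = annulus_section_props(1.0, q, min(tau, q))
    return {
        "bmc": pct_of_mean(a_c, a_e),
        "ixx": pct_of_mean(i_c_ap, i_e_ap),
        "iyy": pct_of_mean(i_c_si, i_e_si),
    }


def fig6_fit_predict(known: dict[str, float], predict: str) -> float:
    """Fit the two-section annulus model to two percent gains, predict the third.

    ``known`` maps two of {"bmc", "ixx", "iyy"} to the percent-of-mean gains
    of the circular section over the elliptical one; the returned value is
    the model-implied gain for ``predict``.  The fit solves for the ellipse
    AP/SI ratio and the relative wall thickness to a residual below 1e-6.
    """
    if predict not in _FIG6_KEYS:
        raise ValueError(f"predict must be one of {_FIG6_KEYS}")
    if set(known) != set(_FIG6_KEYS) - {predict} or len(known) != 2:
        raise ValueError("known must supply exactly the two gains not being predicted")
    keys = sorted(known)
    targets = np.array([known[k] for k in keys])
    if np.allclose(targets, 0.0, atol=1e-12):
        return 0.0  # identical shapes; thickness is indeterminate and irrelevant

    def residual(params: np.ndarray) -> np.ndarray:
        q, tau = params
        g = _shape_gains(q, tau)
        return np.array([g[k] for k in keys]) - targets

    best = None
    for q0 in (0.9, 0.8, 0.6, 0.4):
        for tau0 in (0.1, 0.3, 0.6):
            sol = optimize.least_squares(
                residual,
                x0=[q0, tau0],
                bounds=([1e-3, 1e-3], [1.0, 0.999]),
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
            )
            if best is None or sol.cost < best.cost:
                best = sol
            if sol.cost < 1e-14:
                break
        if best is not None and best.cost < 1e-14:
            break
    assert best is not None
    if np.abs(best.fun).max() > 1e-6:
        raise MorphometryError(
            f"no elliptical-annulus geometry reproduces gains {known} "
            f"(best residual {np.abs(best.fun).max():.3g})"
        )
    q, tau = best.x
    return float(_shape_gains(q, tau)[predict])


# ---------------------------------------------------------------------------
# size-adjusted BMC
# ---------------------------------------------------------------------------

SIZE_ADJUST_MODES = ("fnw", "area1.5", "ttar")


def size_adjusted_bmc(params, mode: str, area_exponent: float = 1.5) -> float:
    """BMC divided by a bone-size measure.

    Modes: ``fnw`` -> BMC / average FN width (cm); ``area1.5`` -> BMC /
    (projected area)^exponent (default 1.5); ``ttar`` -> BMC / slice-averaged
    Tt.Ar.  ``params`` is an FNParams (or anything exposing the same fields);
    BMC is in 10^6 reference voxels.
    """
    if mode == "fnw":
        denom = params.fnw_avg_cm
    elif mode == "area1.5":
        denom = params.area_cm2**area_exponent
    elif mode == "ttar":
        denom = params.tt_ar_cm2
    else:
        raise ValueError(f"unknown size-adjustment mode {mode!r}; expected one of {SIZE_ADJUST_MODES}")
    if denom <= 0:
        raise MorphometryError(f"non-positive denominator for mode {mode!r}")
    return params.bmc / denom
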