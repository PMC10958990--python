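"""Section properties vs closed forms, the shape-gain fit, size-adjusted BMC."""

import numpy as np
import pytest
from dataclasses import replace

from pseudodxa.cohort import (
    GeometrySpec,
    analytic_fn_params,
    build_fn_volume,
    default_cohort_spec,
    sample_cohort_params,
)
from pseudodxa.morphometry import (
    MorphometryError,
    annulus_section_props,
    fig6_fit_predict,
    pct_of_mean,
    section_properties,
    size_adjusted_bmc,
    volume_properties,
)
from pseudodxa.projection import FNParams


def numerical_annulus(a_si, b_ap, t, n=4000):
    """2D midpoint-integration oracle for the annulus closed forms."""
    x = (np.arange(n) + 0.5) / n * 2 * b_ap - b_ap
    y = (np.arange(n) + 0.5) / n * 2 * a_si - a_si
    X, Y = np.meshgrid(x, y, indexing="ij")
    outer = (X / b_ap) ** 2 + (Y / a_si) ** 2 <= 1
    ai, bi = a_si - t, b_ap - t
    inner = ((X / bi) ** 2 + (Y / ai) ** 2 <= 1) if min(ai, bi) > 0 else np.zeros_like(outer)
    ring = outer & ~inner
    dA = (2 * b_ap / n) * (2 * a_si / n)
    return ring.sum() * dA, (Y[ring] ** 2).sum() * dA, (X[ring] ** 2).sum() * dA


class TestAnnulusClosedForms:
    def test_solid_circle_textbook(self):
        ct, iap, isi = annulus_section_props(1.0, 1.0, 1.0)
        assert ct == pytest.approx(np.pi)
        assert iap == pytest.approx(np.pi / 4) and isi == pytest.approx(np.pi / 4)

    def test_circular_annulus_vs_numerical_oracle(self):
        ct, iap, isi = annulus_section_props(1.0, 1.0, 0.5)
        assert ct == pytest.approx(np.pi * 0.75, rel=1e-12)
        assert iap == pytest.approx(np.pi / 4 * (1 - 0.5**4), rel=1e-12)
        num_ct, num_iap, num_isi = numerical_annulus(1.0, 1.0, 0.5)
        assert ct == pytest.approx(num_ct, rel=2e-3)
        assert iap == pytest.approx(num_iap, rel=2e-3)
        assert isi == pytest.approx(num_isi, rel=2e-3)

    def test_elliptical_annulus_vs_numerical_oracle(self):
        ct, iap, isi = annulus_section_props(1.2, 0.8, 0.3)
        num_ct, num_iap, num_isi = numerical_annulus(1.2, 0.8, 0.3)
        assert ct == pytest.approx(num_ct, rel=2e-3)
        assert iap == pytest.approx(num_iap, rel=2e-3)
        assert isi == pytest.approx(num_isi, rel=2e-3)

    def test_equal_axes_reduce_to_circle(self):
        assert annulus_section_props(0.9, 0.9, 0.2) == pytest.approx(
            annulus_section_props(0.9, 0.9 + 1e-15, 0.2)
        )

    def test_thickness_out_of_range(self):
        with pytest.raises(MorphometryError):
            annulus_section_props(1.0, 0.5, 0.6)


class TestVoxelSectionProperties:
    def test_matches_closed_form_at_50um(self):
        geom = GeometrySpec(neck_length=2.0, si_outer_diameter=20.0, ap_si_ratio=1.0,
                            cortical_thickness=2.0, trabecular_bvtv_target=0.0)
        sp = section_properties(build_fn_volume(geom, 0.05, 1))
        ct, iap, isi = annulus_section_props(1.0, 1.0, 0.2)
        assert sp.ct_ar_cm2 == pytest.approx(ct, rel=0.01)
        assert sp.i_ap_cm4 == pytest.approx(iap, rel=0.01)
        assert sp.i_si_cm4 == pytest.approx(isi, rel=0.01)
        assert sp.i_si_cm4 == pytest.approx(sp.i_ap_cm4, rel=0.005)
        assert sp.circularity == pytest.approx(1.0, abs=0.01)

    def test_error_contracts_with_refinement(self):
        geom = GeometrySpec(neck_length=1.0, si_outer_diameter=20.0, ap_si_ratio=1.0,
                            cortical_thickness=2.0, trabecular_bvtv_target=0.0)
        _, iap_ref, _ = annulus_section_props(1.0, 1.0, 0.2)
        errs = [
            abs(section_properties(build_fn_volume(geom, h, 1)).i_ap_cm4 / iap_ref - 1)
            for h in (0.2, 0.1)
        ]
        assert errs[1] < errs[0]

    def test_ellipse_orderings(self):
        geom = GeometrySpec(neck_length=2.0, si_outer_diameter=20.0, ap_si_ratio=0.75,
                            cortical_thickness=2.0, trabecular_bvtv_target=0.0)
        sp = section_properties(build_fn_volume(geom, 0.1, 1))
        assert sp.circularity < 1.0
        assert sp.i_si_cm4 < sp.i_ap_cm4
        assert sp.ct_ar_cm2 <= sp.tt_ar_cm2


class TestVolumeProperties:
    def test_shell_only_is_all_cortical(self, circular_geom):
        props = volume_properties(build_fn_volume(circular_geom, 0.2, 1))
        assert props.pct_cortical == 100.0

    def test_bvtv_round_trip(self, realistic_geom):
        props = volume_properties(build_fn_volume(realistic_geom, 0.3, 6))
        assert abs(props.bvtv - 0.14) < 0.01

    def test_prism_volume_identity(self, realistic_volume):
        sp = section_properties(realistic_volume)
        props = volume_properties(realistic_volume, sp)
        length_cm = realistic_volume.data.shape[2] * realistic_volume.spacing[2] / 10
        assert props.tt_vol_cm3 == pytest.approx(sp.tt_ar_cm2 * length_cm, rel=1e-12)


class TestShapeGainFit:
    def test_predict_each_of_the_triple(self):
        assert fig6_fit_predict({"bmc": 12.0, "ixx": 18.0}, "iyy") == pytest.approx(54.0, abs=1.0)
        assert fig6_fit_predict({"bmc": 12.0, "iyy": 54.0}, "ixx") == pytest.approx(18.0, abs=1.0)
        assert fig6_fit_predict({"ixx": 18.0, "iyy": 54.0}, "bmc") == pytest.approx(12.0, abs=1.0)

    def test_degenerate_zero_gains(self):
        assert fig6_fit_predict({"bmc": 0.0, "ixx": 0.0}, "iyy") == 0.0

    def test_round_trip_through_known_geometry(self):
        from pseudodxa.morphometry import _shape_gains

        g = _shape_gains(0.72, 0.25)
        assert fig6_fit_predict({"bmc": g["bmc"], "ixx": g["ixx"]}, "iyy") == pytest.approx(
            g["iyy"], abs=1e-4
        )

    def test_infeasible_gains_raise(self):
        with pytest.raises((MorphometryError, ValueError)):
            fig6_fit_predict({"bmc": 5.0, "ixx": 500.0}, "iyy")


class TestSizeAdjustedBmc:
    params = FNParams(
        area_cm2=4.0, bmc=100.0, abmd=25.0, bmc_cortical=60.0, bmc_trabecular=40.0,
        pct_cortical=60.0, fnw_avg_cm=2.0, fnw_min_cm=1.9, tt_ar_cm2=5.0,
        ct_ar_cm2=1.0, tt_vol_cm3=7.5, bvtv=0.2, i_si_cm4=1.0, i_ap_cm4=1.2,
        circularity=0.9,
    )

    def test_arithmetic(self):
        assert size_adjusted_bmc(self.params, "area1.5") == pytest.approx(100.0 / 8.0)
        assert size_adjusted_bmc(self.params, "fnw") == pytest.approx(50.0)
        assert size_adjusted_bmc(self.params, "ttar") == pytest.approx(20.0)

    def test_area_exponent_one_is_abmd(self):
        assert size_adjusted_bmc(self.params, "area1.5", area_exponent=1.0) == pytest.approx(
            self.params.abmd
        )

    def test_unknown_mode(self):
        with pytest.raises(ValueError):
            size_adjusted_bmc(self.params, "volume")

    def test_ttar_and_ttvol_adjustments_equivalent(self):
        """BMC/Tt.Ar and BMC/Tt.Vol correlate > 0.99 on a synthetic cohort."""
        spec = default_cohort_spec(150, 150)
        vals = []
        for _, geom in sample_cohort_params(spec, 23):
            p = analytic_fn_params(geom)
            vals.append((p.bmc / p.tt_ar_cm2, p.bmc / p.tt_vol_cm3))
        arr = np.asarray(vals)
        assert np.corrcoef(arr[:, 0], arr[:, 1])[0, 1] > 0.99

    def test_paired_phantoms_circular_stronger(self):
        """Equal SI width and thickness: the more circular shape has higher
        BMC, aBMD, and I_SI at equal projected area."""
        ell = GeometrySpec(neck_length=15.0, si_outer_diameter=30.0, ap_si_ratio=0.7,
                           cortical_thickness=2.0, trabecular_bvtv_target=0.0)
        circ = replace(ell, ap_si_ratio=1.0)
        pe, pc = analytic_fn_params(ell), analytic_fn_params(circ)
        assert pc.area_cm2 == pytest.approx(pe.area_cm2)
        assert pc.bmc > pe.bmc and pc.abmd > pe.abmd and pc.i_si_cm4 > pe.i_si_cm4


class TestPctOfMean:
    def test_sign_and_zero(self):
        assert pct_of_mean(3.0, 3.0) == 0.0
        assert pct_of_mean(4.0, 2.0) == pytest.approx(200.0 / 3.0)
        assert pct_of_mean(2.0, 4.0) == pytest.approx(-200.0 / 3.0)
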