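"""Constitutive laws: elastic distension, collapsible tube, under-cuff rescale."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cuffwave import (
    MMHG_TO_PA,
    DrzewieckiLaw,
    TubeLawError,
    VesselSegment,
    calibrate_law_to_elastic,
    drzewiecki_area,
    elastic_area,
    elastic_compliance,
    elastic_pressure,
    rescale_under_cuff,
    wave_speed,
)
from cuffwave.wall import segment_area0, segment_beta


@pytest.fixture()
def radial_like() -> VesselSegment:
    """A muscular-artery segment of radial-artery proportions."""
    return VesselSegment(id="r", name="radial", length=0.15, r_prox=0.0019,
                         r_dist=0.0016, under_cuff=True)


class TestElasticLaw:
    def test_reference_state_has_zero_transmural_pressure(self, radial_like):
        a0 = segment_area0(radial_like, 0.05)
        assert elastic_pressure(a0, radial_like, 0.05) == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_matches_direct_formula(self, radial_like):
        # PT = beta (sqrt(A/A0) - 1): at A = 1.21 A0 the law gives 0.1 beta
        x = 0.05
        beta = segment_beta(radial_like, x)
        a0 = segment_area0(radial_like, x)
        assert elastic_pressure(1.21 * a0, radial_like, x) == pytest.approx(
            0.1 * beta, rel=1e-12)
        assert elastic_area(0.1 * beta, radial_like, x) == pytest.approx(
            1.21 * a0, rel=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(a_rel=st.floats(0.05, 4.0), b_rel=st.floats(0.05, 4.0))
    def test_strictly_monotone_in_area(self, a_rel, b_rel):
        radial_like = VesselSegment(id="r", name="radial", length=0.15,
                                    r_prox=0.0019, r_dist=0.0016)
        x = 0.075
        a0 = segment_area0(radial_like, x)
        p1 = elastic_pressure(a_rel * a0, radial_like, x)
        p2 = elastic_pressure(b_rel * a0, radial_like, x)
        if a_rel < b_rel:
            assert p1 < p2
        elif a_rel > b_rel:
            assert p1 > p2

    def test_non_positive_area_rejected(self, radial_like):
        with pytest.raises(TubeLawError):
            elastic_pressure(0.0, radial_like, 0.05)

    def test_wave_speed_scales_with_quarter_power_of_area(self, radial_like):
        x, rho = 0.05, 1050.0
        a0 = segment_area0(radial_like, x)
        c0 = wave_speed(a0, radial_like, x, rho)
        assert wave_speed(16 * a0, radial_like, x, rho) == pytest.approx(
            2 * c0, rel=1e-12)
        # c0^2 = (2/3)(Eh/r0)/rho for the linearized law
        ehr = radial_like.stiffness.eh_over_r0(radial_like.radius(x))
        assert c0**2 == pytest.approx((2.0 / 3.0) * ehr / rho, rel=1e-12)


class TestCollapsibleLaw:
    def test_direct_evaluation_oracle_at_100_mmhg(self):
        law = DrzewieckiLaw()
        pt = 100.0 * MMHG_TO_PA
        expected = law.d * math.log(law.a * pt + law.b) \
            / (1.0 + math.exp(-law.c * pt))
        assert drzewiecki_area(pt, law) == pytest.approx(expected, rel=1e-12)

    def test_deep_collapse_limit(self):
        # near the admissible floor the sigmoid has shrunk the area by >10^3
        law = DrzewieckiLaw()
        deep = -250.0 * MMHG_TO_PA
        assert deep > law.pt_min
        assert law.area(deep) < 1e-3 * law.area(100.0 * MMHG_TO_PA)

    def test_below_admissible_range_rejected(self):
        law = DrzewieckiLaw()
        with pytest.raises(TubeLawError, match="admissible"):
            law.area(law.pt_min - 1.0)

    def test_compliance_peaks_within_10_mmhg_of_zero(self):
        law = DrzewieckiLaw()
        pts = np.linspace(-150, 150, 1201) * MMHG_TO_PA
        comp = np.array([law.compliance(p) for p in pts])
        peak = pts[np.argmax(comp)] / MMHG_TO_PA
        assert abs(peak) < 10.0
        # unimodal: strictly increasing before, decreasing after (coarse check)
        imax = int(np.argmax(comp))
        assert np.all(np.diff(comp[:imax:40]) > 0)
        assert np.all(np.diff(comp[imax + 20::40]) < 0)

    @settings(derandomize=True, max_examples=30)
    @given(pt=st.floats(-200.0, 200.0))
    def test_monotone_non_decreasing(self, pt):
        law = DrzewieckiLaw()
        p = pt * MMHG_TO_PA
        if p <= law.pt_min + 1.0:
            return
        assert law.compliance(p) >= 0.0


class TestRescale:
    PT0 = 92.0 * MMHG_TO_PA

    def test_zero_cuff_pressure_is_exact_noop(self, radial_like):
        law = calibrate_law_to_elastic(radial_like, 0.075, self.PT0)
        out = rescale_under_cuff(radial_like, 0.0, self.PT0, law)
        # value and slope of the rescaled elastic law reproduce the original
        a_orig = elastic_area(self.PT0, radial_like, 0.075)
        c_orig = elastic_compliance(self.PT0, radial_like, 0.075)
        assert elastic_area(self.PT0, out, 0.075) == pytest.approx(
            a_orig, rel=1e-6)
        assert elastic_compliance(self.PT0, out, 0.075) == pytest.approx(
            c_orig, rel=1e-6)

    @pytest.mark.parametrize("p_cuff_mmhg", [60.0, 95.0, 130.0, 150.0])
    def test_matching_residuals_by_construction(self, radial_like, p_cuff_mmhg):
        p_cuff = p_cuff_mmhg * MMHG_TO_PA
        law = calibrate_law_to_elastic(
            radial_like, 0.075, self.PT0, pt_min_required=self.PT0 - p_cuff)
        out = rescale_under_cuff(radial_like, p_cuff, self.PT0, law)
        pt_star = self.PT0 - p_cuff
        x_mid = radial_like.length / 2.0
        assert elastic_area(pt_star, out, x_mid) == pytest.approx(
            law.area(pt_star), rel=1e-8)
        assert elastic_compliance(pt_star, out, x_mid) == pytest.approx(
            law.compliance(pt_star), rel=1e-8)

    def test_suprasystolic_rescale_collapses_area(self, radial_like):
        # at PT* far below zero the matched law's area is a small fraction
        # of the baseline area, and its buckling pressure is finite
        p_cuff = 150.0 * MMHG_TO_PA
        law = calibrate_law_to_elastic(
            radial_like, 0.075, self.PT0, pt_min_required=self.PT0 - p_cuff)
        out = rescale_under_cuff(radial_like, p_cuff, self.PT0, law)
        x_mid = radial_like.length / 2.0
        a_star = elastic_area(self.PT0 - p_cuff, out, x_mid)
        a_base = elastic_area(self.PT0, radial_like, x_mid)
        assert a_star < 0.2 * a_base

    def test_non_cuff_segment_untouched(self, radial_like):
        seg = VesselSegment(id="o", name="other", length=0.1, r_prox=0.002,
                            r_dist=0.002, under_cuff=False)
        law = calibrate_law_to_elastic(radial_like, 0.075, self.PT0)
        assert rescale_under_cuff(seg, 1e4, self.PT0, law) is seg

    def test_rescaled_compliance_bounded_by_law_maximum(self, radial_like):
        p_cuff = 120.0 * MMHG_TO_PA
        law = calibrate_law_to_elastic(
            radial_like, 0.075, self.PT0, pt_min_required=self.PT0 - p_cuff)
        out = rescale_under_cuff(radial_like, p_cuff, self.PT0, law)
        pts = np.linspace(law.pt_min + 100.0, 150 * MMHG_TO_PA, 2000)
        comp_max = max(law.compliance(p) for p in pts)
        x_mid = radial_like.length / 2.0
        assert elastic_compliance(self.PT0 - p_cuff, out, x_mid) <= comp_max * (1 + 1e-9)
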