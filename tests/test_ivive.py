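"""Retrograde intrinsic clearance, well-stirred liver and renal scaling."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from selpbpk.compounds import builtin_compounds, builtin_schemes
from selpbpk.errors import ValidationError
from selpbpk.ivive import (RetrogradeInput, extraction_ratio, retrograde_clint,
                           retrograde_residual_clint, scale_renal_clearance,
                           scale_to_whole_liver, well_stirred_hepatic_clearance)

HEALTHY_ABUNDANCE = {"CYP1A2": 52.0, "CYP2A6": 42.0, "CYP2B6": 17.0,
                     "CYP2C8": 24.0, "CYP2C9": 73.0, "CYP2C18": 2.5,
                     "CYP2C19": 14.0, "CYP2D6": 8.0, "CYP2E1": 61.0,
                     "CYP3A4": 137.0}


def _retrograde_input(name):
    spec = builtin_compounds()[name]
    scheme = builtin_schemes()[name]
    pct = {}
    for p in scheme.pathways:
        pct[p.enzyme] = pct.get(p.enzyme, 0.0) + p.percent_contribution
    if not pct:
        pct = {"CYP3A4": 100.0}         # attribute all hepatic clearance
    return RetrogradeInput(
        cl_iv=spec.cl_iv, cl_renal=spec.cl_renal, fu=spec.fu_plasma,
        blood_plasma_ratio=spec.blood_plasma_ratio, hepatic_blood_flow=89.30,
        percent_hepatic_by_enzyme=pct, liver_weight=1650.0, mppgl=40.0,
        abundance_by_enzyme=HEALTHY_ABUNDANCE)


class TestRetrograde:
    @pytest.mark.parametrize("name", ["SEL", "MAP", "DMS", "AMP"])
    def test_round_trip_recovers_hepatic_clearance(self, name):
        """Retrograde -> whole-liver -> well-stirred is an algebraic identity."""
        inp = _retrograde_input(name)
        clint = retrograde_clint(inp, basis="plasma")
        total = scale_to_whole_liver(clint, inp.abundance_by_enzyme, inp.mppgl,
                                     inp.liver_weight) \
            + retrograde_residual_clint(inp, basis="plasma")
        cl_h = well_stirred_hepatic_clearance(total, inp.fu, inp.hepatic_blood_flow)
        assert cl_h == pytest.approx(inp.cl_iv - inp.cl_renal, rel=1e-9)

    def test_blood_basis_round_trip_recovers_blood_clearance(self):
        inp = _retrograde_input("SEL")
        clint = retrograde_clint(inp, basis="blood")
        total = scale_to_whole_liver(clint, inp.abundance_by_enzyme, inp.mppgl,
                                     inp.liver_weight) \
            + retrograde_residual_clint(inp, basis="blood")
        cl_b = well_stirred_hepatic_clearance(total, inp.fu / inp.blood_plasma_ratio,
                                              inp.hepatic_blood_flow)
        expected = (inp.cl_iv - inp.cl_renal) / inp.blood_plasma_ratio
        assert cl_b == pytest.approx(expected, rel=1e-9)

    def test_zero_percent_enzyme_gets_zero_clint(self):
        inp = _retrograde_input("SEL")
        pct = dict(inp.percent_hepatic_by_enzyme)
        pct["CYP2E1"] = 0.0
        inp2 = RetrogradeInput(cl_iv=inp.cl_iv, cl_renal=inp.cl_renal, fu=inp.fu,
                               blood_plasma_ratio=inp.blood_plasma_ratio,
                               hepatic_blood_flow=inp.hepatic_blood_flow,
                               percent_hepatic_by_enzyme=pct,
                               abundance_by_enzyme=HEALTHY_ABUNDANCE)
        assert retrograde_clint(inp2)["CYP2E1"] == 0.0

    def test_per_pmol_clint_inverse_in_abundance(self):
        inp = _retrograde_input("DMS")
        doubled = {e: 2 * v for e, v in HEALTHY_ABUNDANCE.items()}
        inp2 = RetrogradeInput(cl_iv=inp.cl_iv, cl_renal=inp.cl_renal, fu=inp.fu,
                               blood_plasma_ratio=inp.blood_plasma_ratio,
                               hepatic_blood_flow=inp.hepatic_blood_flow,
                               percent_hepatic_by_enzyme=inp.percent_hepatic_by_enzyme,
                               abundance_by_enzyme=doubled)
        a = retrograde_clint(inp)
        b = retrograde_clint(inp2)
        for enzyme in a:
            assert b[enzyme] == pytest.approx(a[enzyme] / 2, rel=1e-12)

    def test_infeasible_systemic_clearance_rejected(self):
        with pytest.raises(ValidationError, match="well-stirred"):
            retrograde_clint(RetrogradeInput(
                cl_iv=95.0, cl_renal=0.0, fu=0.5, blood_plasma_ratio=1.0,
                hepatic_blood_flow=89.3,
                percent_hepatic_by_enzyme={"CYP3A4": 100.0},
                abundance_by_enzyme=HEALTHY_ABUNDANCE))


class TestWholeLiverScaling:
    def test_poor_metabolizer_zero_abundance_gives_zero(self):
        assert scale_to_whole_liver({"CYP2D6": 5.0}, {"CYP2D6": 0.0},
                                    40.0, 1650.0) == 0.0

    def test_unit_arithmetic(self):
        # 1 uL/min/pmol * 8 pmol/mg * 40 mg/g * 1650 g * 60e-6 = 31.68 L/h
        assert scale_to_whole_liver({"CYP2D6": 1.0}, {"CYP2D6": 8.0},
                                    40.0, 1650.0) == pytest.approx(31.68)

    def test_linear_in_liver_weight(self):
        base = scale_to_whole_liver({"CYP3A4": 1.0}, {"CYP3A4": 137.0}, 40.0, 1000.0)
        assert scale_to_whole_liver({"CYP3A4": 1.0}, {"CYP3A4": 137.0},
                                    40.0, 2000.0) == pytest.approx(2 * base)


class TestWellStirred:
    @pytest.mark.parametrize("clint, fu, qh, expected", [
        (24217.92, 0.10, 89.30, 86.11),     # healthy parent
        (27.70, 1.00, 89.30, 21.14),        # healthy methamphetamine
    ])
    def test_reference_forward_clearances(self, clint, fu, qh, expected):
        assert well_stirred_hepatic_clearance(clint, fu, qh) == pytest.approx(
            expected, abs=0.015)

    def test_perfusion_limit(self):
        assert well_stirred_hepatic_clearance(1e12, 0.5, 89.3) == pytest.approx(
            89.3, rel=1e-9)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(clint=st.floats(1.0, 1e5), dclint=st.floats(0.1, 1e4))
    def test_increasing_concave_and_bounded(self, clint, dclint):
        f = lambda c: well_stirred_hepatic_clearance(c, 0.1, 89.3)
        lo, mid, hi = f(clint), f(clint + dclint), f(clint + 2 * dclint)
        assert lo < mid < hi < 89.3
        assert mid - lo > hi - mid          # concavity


class TestExtractionRatio:
    def test_limits_and_dms_classification(self):
        assert extraction_ratio(0.0, 89.3) == 0.0
        assert extraction_ratio(89.3, 89.3) == 1.0
        assert round(extraction_ratio(35.36, 89.3), 1) == 0.4

    def test_extraction_classes_across_compounds(self):
        # parent perfusion-limited, metabolites capacity-limited
        assert extraction_ratio(86.11, 89.3) > 0.9
        assert extraction_ratio(21.14, 89.3) < 0.3
        assert extraction_ratio(16.79, 89.3) < 0.3

    def test_superunity_rejected(self):
        with pytest.raises(ValidationError):
            extraction_ratio(90.0, 89.3)


class TestRenalScaling:
    def test_anuric_limit(self):
        assert scale_renal_clearance(0.34, 0.0) == 0.0

    @pytest.mark.parametrize("cl_healthy, ratio, expected", [
        (0.34, 0.16, 0.055),        # parent in severe renal impairment
        (8.6526, 0.16, 1.398),      # methamphetamine
    ])
    def test_proportional_gfr_scaling(self, cl_healthy, ratio, expected):
        assert scale_renal_clearance(cl_healthy, ratio) == pytest.approx(
            expected, abs=1e-3)
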