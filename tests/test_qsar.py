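"""Dermal absorption QSARs: golden values and structural properties."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from selpbpk.compounds import builtin_compounds
from selpbpk.errors import ConfigurationError, InputError
from selpbpk.qsar import (SEL_OVERRIDES, assemble_dermal_parameters,
                          binding_correction, dermis_blood, diffusion_sc_lipid,
                          diffusion_ve, diffusion_ve_free, keratin_binding,
                          molecular_radius, octanol_water, sc_lipid_vehicle,
                          sebum_vehicle)

SEL = builtin_compounds()["SEL"]


class TestPartitionCoefficients:
    @pytest.mark.parametrize("logp, expected", [(0, 1.0), (2.7, 501.187), (-1, 0.1)])
    def test_octanol_water(self, logp, expected):
        assert octanol_water(logp) == pytest.approx(expected, rel=1e-3)

    @pytest.mark.parametrize("logp, expected", [
        (0.0, 1.32),         # unit argument
        (2.7, 85.03),        # selegiline reference estimate
        (2.07, 32.2),        # methamphetamine
    ])
    def test_sc_lipid_vehicle(self, logp, expected):
        assert sc_lipid_vehicle(octanol_water(logp)) == pytest.approx(expected, rel=2e-3)

    @pytest.mark.parametrize("logp, expected", [(0.0, 21.38), (2.7, 915.9)])
    def test_sebum_vehicle(self, logp, expected):
        assert sebum_vehicle(logp) == pytest.approx(expected, rel=1e-3)

    def test_viable_epidermis_sebum_quotient(self):
        ratio = sc_lipid_vehicle(octanol_water(2.7)) / sebum_vehicle(2.7)
        assert ratio == pytest.approx(0.0928, abs=1e-3)

    @pytest.mark.parametrize("k_ow, expected", [
        (1.0, 0.9937),
        (octanol_water(2.7), 2.44),
    ])
    def test_dermis_blood(self, k_ow, expected):
        assert dermis_blood(k_ow) == pytest.approx(expected, abs=5e-3)

    def test_dermis_blood_lipophilic_asymptote(self):
        assert dermis_blood(1e9) == pytest.approx(0.02 / 0.007, rel=1e-2)

    def test_nonpositive_kow_rejected(self):
        for fn in (sc_lipid_vehicle, dermis_blood):
            with pytest.raises(InputError):
                fn(0.0)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(logp=st.floats(-2, 6), dlogp=st.floats(0.01, 2))
    def test_partitioning_monotone_in_lipophilicity(self, logp, dlogp):
        assert sc_lipid_vehicle(octanol_water(logp + dlogp)) \
            > sc_lipid_vehicle(octanol_water(logp))
        assert sebum_vehicle(logp + dlogp) > sebum_vehicle(logp)
        if octanol_water(logp) > 1:
            assert dermis_blood(octanol_water(logp + dlogp)) \
                > dermis_blood(octanol_water(logp))


class TestDiffusionCoefficients:
    def test_molecular_radius_inverts_unit_sphere(self):
        mw_unit = 4.0 / 3.0 * math.pi * 6.02214076e23 * 1e-24   # 1 A sphere
        assert molecular_radius(mw_unit) == pytest.approx(1.0, rel=1e-9)

    def test_selegiline_radius_and_cube_root_scaling(self):
        r = molecular_radius(187.28)
        assert r == pytest.approx(4.20, abs=0.01)
        assert molecular_radius(8 * 187.28) == pytest.approx(2 * r, rel=1e-9)

    def test_sc_lipid_diffusivity_limits(self):
        assert diffusion_sc_lipid(1e3) == pytest.approx(3600 * 3e-9, rel=1e-6)
        assert diffusion_sc_lipid(1e-9) == pytest.approx(0.072 + 1.08e-5, rel=1e-4)

    def test_selegiline_sc_lipid_diffusivity_within_1pc_of_reference(self):
        d = diffusion_sc_lipid(molecular_radius(187.28))
        assert d == pytest.approx(3.22e-5, rel=0.01)

    def test_free_aqueous_diffusivity(self):
        assert diffusion_ve_free(187.28) == pytest.approx(2.73e-6, rel=5e-3)

    def test_binding_correction_floor(self):
        # fu=1, no unionized lipid binding: divisor floor is 0.7*(0.68+0.32)
        d = diffusion_ve(187.28, fu=1.0, fni_ve=1e-12, k_lip_vehicle=1e-12)
        assert d == pytest.approx(3600 * diffusion_ve_free(187.28) / 0.7, rel=1e-6)

    def test_selegiline_ve_diffusivity_within_factor_two_of_reference(self):
        d = diffusion_ve(187.28, fu=0.1, fni_ve=0.4770, k_lip_vehicle=85.03)
        assert 0.002 / 2 <= d <= 0.002 * 2

    def test_zero_fu_rejected(self):
        with pytest.raises(InputError):
            diffusion_ve(187.28, fu=0.0, fni_ve=0.5, k_lip_vehicle=85.0)


class TestKeratinBinding:
    def test_kb_at_neutral_logd(self):
        kb, _, _ = keratin_binding(0.0)
        assert kb == pytest.approx(10 ** 1.26, rel=1e-9)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(logd=st.floats(-3, 4))
    def test_on_off_detailed_balance(self, logd):
        kb, kon, koff = keratin_binding(logd)
        assert kon == pytest.approx(koff * kb, rel=1e-12)

    def test_selegiline_override_values(self):
        ps = assemble_dermal_parameters(SEL, overrides=SEL_OVERRIDES)
        assert ps.keratin_kon == 78.8
        assert ps.keratin_koff == 0.93

    def test_default_qsar_reproduces_override_within_1pc(self):
        # at stratum-corneum surface pH 6.8 the keratin QSAR lands on the
        # reference on-rate without any override
        ps = assemble_dermal_parameters(SEL)
        assert ps.keratin_kon == pytest.approx(78.8, rel=0.01)


class TestAssembly:
    def test_selegiline_defaults_match_reference_estimates(self):
        ps = assemble_dermal_parameters(SEL)
        assert ps.k_lip_vehicle == pytest.approx(85.03, rel=1e-3)
        assert ps.k_sebum_vehicle == pytest.approx(915.9, rel=1e-3)
        assert ps.k_dermis_blood == pytest.approx(2.44, abs=5e-3)
        assert ps.k_sc_ve == pytest.approx(24.8, rel=2e-3)
        assert ps.k_dermis_ve == 1.0
        assert ps.k_subcutis_dermis == 1e-6
        assert ps.k_subcutis_blood == 1.0

    def test_override_stored_verbatim_with_provenance(self):
        ps = assemble_dermal_parameters(SEL, overrides={"k_sc_ve": 24.8})
        assert ps.k_sc_ve == 24.8
        assert ps.provenance["k_sc_ve"] == "override"
        assert ps.provenance["k_lip_vehicle"] == "qsar"

    def test_kb_only_override_keeps_detailed_balance_bitwise(self):
        ps = assemble_dermal_parameters(SEL, overrides={"keratin_kb": 50.0})
        assert ps.keratin_kon == ps.keratin_koff * 50.0

    def test_all_override_bypasses_qsars(self):
        fields = {"k_lip_vehicle": 1.0, "k_sebum_vehicle": 2.0, "k_sc_ve": 3.0,
                  "k_ve_sebum": 0.5, "k_dermis_ve": 1.0, "k_subcutis_dermis": 1e-6,
                  "k_dermis_blood": 2.0, "k_subcutis_blood": 1.0,
                  "d_sc_lipid": 1e-5, "d_ve": 1e-3, "d_dermis": 1e-3,
                  "d_sebum": 1e-4, "keratin_kb": 10.0, "keratin_koff": 1.0,
                  "keratin_kon": 10.0, "molecular_radius": 4.0}
        ps = assemble_dermal_parameters(SEL, overrides=fields)
        for name, value in fields.items():
            assert getattr(ps, name) == value
            assert ps.provenance[name] == "override"

    def test_unknown_override_rejected(self):
        with pytest.raises(ConfigurationError):
            assemble_dermal_parameters(SEL, overrides={"nonexistent": 1.0})

    def test_missing_layer_ph_rejected(self):
        with pytest.raises(ConfigurationError):
            assemble_dermal_parameters(SEL, site_ph={"surface": None})

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(logp=st.floats(-2, 6), mw=st.floats(50, 600))
    def test_every_qsar_output_positive_and_finite(self, logp, mw):
        k_ow = octanol_water(logp)
        values = [sc_lipid_vehicle(k_ow), sebum_vehicle(logp), dermis_blood(k_ow),
                  molecular_radius(mw), diffusion_sc_lipid(molecular_radius(mw)),
                  diffusion_ve(mw, 0.5, 0.5, sc_lipid_vehicle(k_ow)),
                  binding_correction(0.5, 0.5, sc_lipid_vehicle(k_ow))]
        assert all(math.isfinite(v) and v > 0 for v in values)
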