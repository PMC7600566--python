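"""Whole-body PBPK engine: analytic identities, conservation, linearity."""

from dataclasses import replace

import numpy as np
import pytest

from selpbpk.compounds import (MetabolismScheme, builtin_compounds,
                               builtin_schemes, mg_to_nmol)
from selpbpk.dermal import PatchProduct
from selpbpk.engine import (CompoundModelSet, DoseRegimen, SolverSettings,
                            assemble_system, derive_individual_parameters,
                            metabolite_parent_auc_ratio, simulate)
from selpbpk.errors import ConfigurationError, ValidationError

IV = DoseRegimen(route="iv_infusion", dose=8.37, duration=24.0)
PATCH = PatchProduct(drug_load=20.0, area=20.0, wear_duration=24.0)
TD = DoseRegimen(route="transdermal", dose=20.0, duration=24.0, patch=PATCH)
COARSE = SolverSettings(grid_step=0.25)


@pytest.fixture(scope="module")
def iv_result(model, healthy_subject):
    system = assemble_system(healthy_subject, model, IV)
    return simulate(system, duration=400.0, settings=COARSE), system


class TestAnalyticIdentities:
    def test_iv_auc_equals_dose_over_clearance(self, iv_result, model,
                                               healthy_subject):
        result, system = iv_result
        params = system.params["SEL"]
        cl = params.cl_hepatic + params.cl_renal
        dose = mg_to_nmol(8.37, 187.28)
        auc = np.trapezoid(result.conc("SEL"), result.times)
        assert auc == pytest.approx(dose / cl * 187.28, rel=1e-3)

    @pytest.mark.parametrize("metabolite", ["MAP", "DMS"])
    def test_primary_metabolite_auc_identity(self, iv_result, model, metabolite):
        """AUC_met = fm_eff * Dose_molar / CL_met, molar-corrected to pg/mL."""
        result, system = iv_result
        sel = system.params["SEL"]
        met = system.params[metabolite]
        fm = sum(s for (_, prod), s in sel.fm_shares.items() if prod == metabolite)
        cl_sel = sel.cl_hepatic + sel.cl_renal
        fm_eff = fm * sel.cl_hepatic / cl_sel
        dose = mg_to_nmol(8.37, 187.28)
        mw = builtin_compounds()[metabolite].molecular_weight
        expected = fm_eff * dose / (met.cl_hepatic + met.cl_renal) * mw
        auc = np.trapezoid(result.conc(metabolite), result.times)
        assert auc == pytest.approx(expected, rel=5e-3)

    def test_urinary_fraction_is_renal_share_of_clearance(self, iv_result):
        result, system = iv_result
        p = system.params["SEL"]
        dose = mg_to_nmol(8.37, 187.28)
        expected = 100.0 * p.cl_renal / (p.cl_renal + p.cl_hepatic)
        fe = 100.0 * result.profiles["SEL"].urine_nmol[-1] / dose
        assert fe == pytest.approx(expected, rel=5e-3)
        assert fe == pytest.approx(0.54, abs=0.02)

    def test_metabolite_parent_ratio_near_analytic_value(self, iv_result):
        result, _ = iv_result
        assert metabolite_parent_auc_ratio(result, "MAP", "SEL") == pytest.approx(
            2.61, abs=0.05)


class TestConservation:
    def test_iv_molar_balance(self, iv_result):
        result, _ = iv_result
        assert result.mass_balance_error.max() < 1e-6

    def test_transdermal_molar_balance(self, model, healthy_subject):
        result = simulate(assemble_system(healthy_subject, model, TD),
                          duration=72.0, settings=COARSE)
        assert result.mass_balance_error.max() < 1e-6

    def test_multidose_patch_balance_with_replacement(self, model, healthy_subject):
        reg = DoseRegimen(route="transdermal", dose=20.0, duration=24.0,
                          interval=24.0, n_doses=3, patch=PATCH)
        result = simulate(assemble_system(healthy_subject, model, reg),
                          duration=96.0, settings=COARSE)
        assert result.mass_balance_error.max() < 1e-6
        assert result.discarded_patch_nmol > 0          # residual is ledgered

    def test_hydroxyamphetamine_sink_is_ledger_tracked(self, iv_result):
        result, system = iv_result
        map_paths = result.profiles["MAP"].metabolized_by_pathway_nmol
        total_hep = result.profiles["MAP"].hepatic_eliminated_nmol[-1]
        assert map_paths[("CYP2D6", "OHAMP")][-1] == pytest.approx(
            0.6 * total_hep, rel=1e-9)


class TestLinearityAndSuperposition:
    def test_dose_linearity_exact(self, model, healthy_subject):
        lo = simulate(assemble_system(healthy_subject, model, IV),
                      duration=48.0, settings=COARSE)
        hi_reg = DoseRegimen(route="iv_infusion", dose=2 * 8.37, duration=24.0)
        hi = simulate(assemble_system(healthy_subject, model, hi_reg),
                      duration=48.0, settings=COARSE)
        for name in ("SEL", "MAP", "DMS", "AMP"):
            np.testing.assert_allclose(hi.conc(name), 2 * lo.conc(name),
                                       rtol=1e-6, atol=1e-9)

    def test_last_interval_auc_matches_single_dose_auc_inf(self, model,
                                                           healthy_subject):
        amp = builtin_compounds()["AMP"]
        m = CompoundModelSet(compounds={"AMP": amp},
                             schemes={"AMP": builtin_schemes()["AMP"]})
        single = DoseRegimen(route="iv_infusion", dose=5.0, duration=0.5)
        r1 = simulate(assemble_system(healthy_subject, m, single,
                                      dosed_compound="AMP"),
                      duration=400.0, settings=COARSE)
        auc_inf = np.trapezoid(r1.conc("AMP"), r1.times)
        multi = DoseRegimen(route="iv_infusion", dose=5.0, duration=0.5,
                            interval=24.0, n_doses=8)
        rn = simulate(assemble_system(healthy_subject, m, multi,
                                      dosed_compound="AMP"),
                      duration=192.0, settings=COARSE)
        mask = (rn.times >= 168.0) & (rn.times <= 192.0)
        auc_last = np.trapezoid(rn.conc("AMP")[mask], rn.times[mask])
        assert auc_last == pytest.approx(auc_inf, rel=0.01)

    def test_one_compartment_accumulation_matches_theory(self, model,
                                                         healthy_subject):
        amp = builtin_compounds()["AMP"]
        m = CompoundModelSet(compounds={"AMP": amp},
                             schemes={"AMP": builtin_schemes()["AMP"]})
        reg = DoseRegimen(route="iv_infusion", dose=5.0, duration=0.5,
                          interval=24.0, n_doses=8)
        r = simulate(assemble_system(healthy_subject, m, reg,
                                     dosed_compound="AMP"),
                     duration=192.0, settings=COARSE)
        p = derive_individual_parameters(healthy_subject, m)["AMP"]
        cl = p.cl_hepatic + p.cl_renal
        v = amp.vss * healthy_subject.body_weight
        t_half = np.log(2) * v / cl
        ar_theory = 1.0 / (1.0 - 2.0 ** (-24.0 / t_half))
        t, c = r.times, r.conc("AMP")
        first = np.trapezoid(c[(t >= 0) & (t <= 24)], t[(t >= 0) & (t <= 24)])
        last = np.trapezoid(c[(t >= 168) & (t <= 192)], t[(t >= 168) & (t <= 192)])
        assert last / first == pytest.approx(ar_theory, rel=0.02)


class TestAccumulationOrdering:
    def test_metabolites_accumulate_more_than_parent(self, model, healthy_subject):
        """Repeated daily patches: metabolite accumulation exceeds the parent's.

        Under the first-pass-free metabolite formation convention the secondary
        metabolite shows the strongest accumulation (two sequential
        conversions make its first-day exposure smallest), followed by the
        primary metabolites, then the parent.
        """
        reg = DoseRegimen(route="transdermal", dose=20.0, duration=24.0,
                          interval=24.0, n_doses=10, patch=PATCH)
        result = simulate(assemble_system(healthy_subject, model, reg),
                          duration=264.0, settings=COARSE)
        ar = {}
        t = result.times
        for name in ("SEL", "MAP", "DMS", "AMP"):
            c = result.conc(name)
            first = np.trapezoid(c[t <= 24], t[t <= 24])
            mask = (t >= 216) & (t <= 240)
            ar[name] = np.trapezoid(c[mask], t[mask]) / first
        assert ar["MAP"] > ar["DMS"] > ar["SEL"] > 1.0
        assert ar["AMP"] > ar["DMS"]

    def test_steady_state_trough_matches_superposition_by_day_10(
            self, model, healthy_subject):
        reg = DoseRegimen(route="transdermal", dose=20.0, duration=24.0,
                          interval=24.0, n_doses=10, patch=PATCH)
        multi = simulate(assemble_system(healthy_subject, model, reg),
                         duration=240.0, settings=COARSE)
        single = simulate(assemble_system(healthy_subject, model, TD),
                          duration=240.0, settings=COARSE)
        t, c1 = single.times, single.conc("SEL")
        superposed = sum(np.interp(240.0 - k * 24.0, t, c1) for k in range(10))
        trough = multi.conc("SEL")[np.searchsorted(multi.times, 240.0)]
        assert trough == pytest.approx(superposed, rel=0.05)


class TestStructure:
    def test_iv_regimen_has_no_dermal_states(self, model, healthy_subject):
        system = assemble_system(healthy_subject, model, IV)
        assert system.dermal is None

    def test_no_metabolism_yields_parent_only_kinetics(self, model,
                                                       healthy_subject):
        sel = builtin_compounds()["SEL"]
        m = CompoundModelSet(
            compounds=builtin_compounds(),
            schemes={**builtin_schemes(), "SEL": MetabolismScheme(parent="SEL")})
        result = simulate(assemble_system(healthy_subject, m, IV),
                          duration=48.0, settings=COARSE)
        for name in ("MAP", "DMS", "AMP"):
            assert np.all(result.conc(name) == 0.0)
        assert result.conc("SEL").max() > 0

    def test_transdermal_without_patch_rejected(self):
        with pytest.raises(ConfigurationError):
            DoseRegimen(route="transdermal", dose=20.0, duration=24.0)

    def test_duration_must_cover_first_dose(self, model, healthy_subject):
        with pytest.raises(ConfigurationError):
            simulate(assemble_system(healthy_subject, model, IV), duration=10.0)
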