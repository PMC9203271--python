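"""Unit and property tests for the vesicle ion-transport model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

from mpresolve.constants import FARADAY as F, GAS_CONSTANT as R
from mpresolve.vesicle_model import (ScenarioSpec, TransporterParams,
                                     VesicleState, asor_open_fraction,
                                     clc_cycle_flux, clc_reversal_potential,
                                     conductive_flux, make_scenario,
                                     nernst_potential, pump_flux,
                                     scan_copy_number, simulate,
                                     step_derivatives)


def _state(Na=150.0, K=5.0, Cl=159.0, pH=7.2, U=0.0, r_um=1.0):
    """Hand-built state at given concentrations (mM) and potential (mV)."""
    V = 4.0 / 3.0 * math.pi * (r_um * 1e-6) ** 3 * 1e3
    A = 4.0 * math.pi * (r_um * 1e-6) ** 2
    mol = V * 1e-3
    return VesicleState(t=0.0, n_Na=Na * mol, n_K=K * mol, n_Cl=Cl * mol,
                        n_X=0.0, n_A=0.0, n_Hbound=0.0, pH_lum=pH,
                        V=V, U=U, A_mem=A)


class TestNernst:
    def test_tenfold_sodium_gradient_is_about_minus_60mV(self):
        assert nernst_potential(+1, 150.0, 15.0, 310.15) == pytest.approx(-61.5, abs=0.1)

    def test_equal_concentrations_zero(self):
        assert nernst_potential(+1, 100.0, 100.0, 295.0) == 0.0

    def test_chloride_gradient_closed_form(self):
        assert nernst_potential(-1, 159.0, 40.0, 310.15) == pytest.approx(36.9, abs=0.05)

    @given(st.floats(1.0, 500.0), st.floats(1.0, 500.0))
    @settings(max_examples=50, deadline=None)
    def test_antisymmetric_under_swap(self, a, b):
        assert nernst_potential(+1, a, b) == pytest.approx(
            -nernst_potential(+1, b, a), abs=1e-9)

    def test_nonpositive_concentration_rejected(self):
        with pytest.raises(ValueError):
            nernst_potential(+1, 0.0, 10.0)
        with pytest.raises(ValueError):
            nernst_potential(0, 10.0, 10.0)


class TestAsorGating:
    def test_half_activation_near_stated_midpoint(self):
        p = TransporterParams()
        assert asor_open_fraction(-120.0, 5.3, p) == pytest.approx(0.5, abs=0.01)

    def test_closed_at_neutral_pH(self):
        p = TransporterParams()
        assert asor_open_fraction(-120.0, 7.2, p) < 3e-6

    def test_closed_at_lumen_positive_voltage(self):
        p = TransporterParams()
        assert asor_open_fraction(+70.0, 4.8, p) < 1e-3

    @given(st.floats(-150, 150), st.floats(3.5, 8.5), st.floats(0.01, 1.0))
    @settings(max_examples=60, deadline=None)
    def test_strictly_decreasing_in_pH_and_U(self, U, ph, step):
        p = TransporterParams()
        assert asor_open_fraction(U, ph + step, p) < asor_open_fraction(U, ph, p)
        assert asor_open_fraction(U + step, ph, p) < asor_open_fraction(U, ph, p)

    def test_half_activation_solves_to_printed_ph(self):
        p = TransporterParams()
        ph = brentq(lambda x: asor_open_fraction(-120.0, x, p) - 0.5, 3.0, 8.0)
        assert round(ph, 1) == 5.3


class TestClc:
    def test_zero_flux_at_reversal(self):
        p = TransporterParams()
        st_ = _state(pH=6.5, U=0.0)
        u_rev = clc_reversal_potential(st_.conc_mM("Cl"), p.Cl_c, 6.5, p.pH_cyt)
        st_.U = u_rev
        assert abs(clc_cycle_flux(st_, p)) < 1e-30

    def test_zero_flux_without_gradients(self):
        p = TransporterParams()
        st_ = _state(Cl=p.Cl_c, pH=p.pH_cyt, U=0.0)
        assert clc_cycle_flux(st_, p) == pytest.approx(0.0, abs=1e-30)

    def test_forward_acidifying_at_high_luminal_chloride(self):
        # 159 mM lumen vs 40 mM cytosol at -60 mV: cycle free energy < 0
        p = TransporterParams()
        st_ = _state(Cl=159.0, pH=6.5, U=-60.0)
        assert clc_cycle_flux(st_, p) > 0


class TestPump:
    def test_stalls_at_large_pmf(self):
        p = TransporterParams()
        st_ = _state(pH=4.0, U=100.0)  # pmf far above the stall value
        assert pump_flux(st_, p) == 0.0

    def test_bafilomycin_preset_never_pumps(self):
        spec = make_scenario("bafilomycin")
        st_ = _state(pH=5.0, U=-80.0)
        assert pump_flux(st_, spec.params) == 0.0

    def test_linear_between_zero_and_stall(self):
        p = TransporterParams()
        st_ = _state(pH=p.pH_cyt, U=p.pmf_stall / 2.0)  # pmf = stall/2 exactly
        expected = p.J_pump_max * st_.A_mem / 2.0
        assert pump_flux(st_, p) == pytest.approx(expected, rel=1e-12)


class TestConductive:
    def test_zero_at_reversal_potential(self):
        p = TransporterParams()
        st_ = _state(Na=150.0)
        st_.U = nernst_potential(+1, 150.0, p.Na_c, p.T)
        assert conductive_flux("Na", st_, p) == pytest.approx(0.0, abs=1e-25)

    def test_knockout_preset_has_no_asor_flux(self):
        spec = make_scenario("TMEM206_KO")
        st_ = _state(pH=5.0, U=-60.0)
        assert conductive_flux("Cl", st_, spec.params) == 0.0

    def test_chloride_leaves_lumen_when_hyperpolarized(self):
        p = TransporterParams()
        st_ = _state(Cl=159.0, pH=4.8, U=-100.0)  # far below E_Cl = +36.9
        assert conductive_flux("Cl", st_, p) < 0

    def test_unknown_species_rejected(self):
        with pytest.raises(ValueError):
            conductive_flux("Ca", _state(), TransporterParams())


class TestDerivatives:
    def test_closed_system_is_static(self):
        p = TransporterParams(g_TPC=0, g_ASOR=0, k_CLC=0, g_H=0, J_pump_max=0)
        d = step_derivatives(_state(U=-50.0, pH=6.0), p)
        for key in ("n_Na", "n_K", "n_Cl", "n_Hbound", "pH_lum"):
            assert d[key] == 0.0

    def test_potassium_has_no_pathway(self):
        d = step_derivatives(_state(U=-50.0, pH=6.0), TransporterParams())
        assert d["n_K"] == 0.0

    def test_initial_sodium_efflux_depolarizes_downward(self, wt_trajectory):
        # U starts lumen-positive (+70 mV) and collapses within the first
        # minute as TPC-mediated Na+ efflux removes charge
        assert wt_trajectory.U[0] == pytest.approx(70.0, abs=0.5)
        assert wt_trajectory.U[30] < 0.0


class TestSimulate:
    def test_all_transport_off_preserves_state(self):
        spec = make_scenario("WT", param_overrides=dict(
            g_TPC=0, g_ASOR=0, k_CLC=0, g_H=0, J_pump_max=0))
        tr = simulate(spec)
        assert np.allclose(tr.V, tr.V[0], rtol=1e-9)
        assert np.allclose(tr.pH, tr.pH[0], atol=1e-9)
        for sp in ("Na", "K", "Cl"):
            c = np.array([s.conc_mM(sp) for s in tr.states])
            assert np.allclose(c, c[0], rtol=1e-9)

    def test_wild_type_volume_never_increases(self, wt_trajectory):
        assert np.all(np.diff(wt_trajectory.V) <= 1e-20)

    def test_osmotic_constraint_everywhere(self, wt_trajectory):
        p = wt_trajectory.scenario.params
        for s in wt_trajectory.states[::60]:
            osm = (s.n_Na + s.n_K + s.n_Cl + s.n_X + s.n_A) / s.V
            assert abs(osm - p.Osm_ext) / p.Osm_ext < 1e-6

    def test_membrane_potential_matches_charge(self, wt_trajectory):
        # U must equal F * (net luminal charge) / (c_m * A) at all times
        p = wt_trajectory.scenario.params
        s0 = wt_trajectory.states[0]
        mol0 = s0.n_Na + s0.n_K + s0.n_Hbound - s0.n_Cl + s0.q_A
        q_off = p.c_m * s0.A_mem * (70.0 * 1e-3) / F
        for s in wt_trajectory.states[::120]:
            dq = (s.n_Na + s.n_K + s.n_Hbound - s.n_Cl + s.q_A) - mol0
            expected = 1e3 * F * (q_off + dq) / (p.c_m * s.A_mem)
            assert s.U == pytest.approx(expected, abs=0.05)

    def test_flux_bookkeeping_closes(self, wt_trajectory):
        tr = wt_trajectory
        n_na = np.array([s.n_Na for s in tr.states])
        integral = np.concatenate(
            ([0.0], np.cumsum((tr.fluxes["J_TPC_Na"].to_numpy()[1:] +
                               tr.fluxes["J_TPC_Na"].to_numpy()[:-1]) / 2.0)))
        drift = n_na - (n_na[0] + integral)
        # trapezoid quadrature on the 1-s output grid limits the comparison
        # (the initial potential collapse is much faster than 1 s)
        assert np.max(np.abs(drift)) < 5e-3 * (n_na[0] - n_na[-1])

    def test_impermeant_amounts_constant(self, wt_trajectory):
        nx = np.array([s.n_X for s in wt_trajectory.states])
        na_imp = np.array([s.n_A for s in wt_trajectory.states])
        assert np.all(nx == nx[0])
        assert np.all(na_imp == na_imp[0])


class TestScenarioOrderings:
    """Qualitative predictions for the intervention presets at t = 10 min."""

    def test_knockout_is_more_acidic_and_shrinks_less(self, scenario_endpoints):
        assert scenario_endpoints["TMEM206_KO"][1] < scenario_endpoints["WT"][1]
        assert scenario_endpoints["TMEM206_KO"][0] > scenario_endpoints["WT"][0]

    def test_low_chloride_acidifies_wild_type(self, scenario_endpoints):
        assert scenario_endpoints["low_luminal_Cl"][1] < scenario_endpoints["WT"][1]

    def test_low_chloride_alkalinizes_knockout(self, scenario_endpoints):
        assert (scenario_endpoints["low_luminal_Cl_KO"][1]
                > scenario_endpoints["TMEM206_KO"][1])

    def test_bafilomycin_slows_wild_type_but_not_knockout(self, scenario_endpoints):
        e = scenario_endpoints
        wt_effect = e["bafilomycin"][0] - e["WT"][0]
        ko_effect = e["TMEM206_KO_baf"][0] - e["TMEM206_KO"][0]
        assert wt_effect > 0
        assert ko_effect < wt_effect

    def test_alkaline_shifted_mutant_resolves_faster(self, scenario_endpoints):
        assert scenario_endpoints["R87C"][0] < scenario_endpoints["WT"][0]

    def test_gating_removal_clamps_near_neutral(self, scenario_endpoints):
        assert scenario_endpoints["gating_removed"][1] > 6.5

    def test_clc_alone_still_shrinks_but_slower_than_wt(self, scenario_endpoints):
        v_clc = scenario_endpoints["CLC_only"][0]
        assert v_clc < 0.9
        assert v_clc > scenario_endpoints["WT"][0]

    def test_weak_base_clamps_ph(self, scenario_endpoints):
        assert scenario_endpoints["NH4Cl"][1] > 6.9


class TestCopyNumberScan:
    def test_zero_asor_factor_reproduces_knockout(self):
        table = scan_copy_number(make_scenario("WT"), "g_ASOR", [0.0])
        ko = simulate(make_scenario("TMEM206_KO"))
        assert table.V_fraction.iloc[0] == pytest.approx(
            ko.volume_fraction[-1], rel=1e-9)
        assert table.pH_end.iloc[0] == pytest.approx(ko.pH[-1], abs=1e-8)

    def test_asor_density_resilience(self, scenario_endpoints):
        v1 = scenario_endpoints["WT"][0]
        v10 = scenario_endpoints["WT_ASOR_x10"][0]
        assert abs(v10 - v1) / v1 < 0.10

    def test_volume_fraction_monotone_in_tpc(self):
        table = scan_copy_number(make_scenario("WT"), "g_TPC", [0.0, 0.5, 1.0, 2.0])
        assert np.all(np.diff(table.V_fraction.to_numpy()) <= 1e-9)

    def test_negative_factor_rejected(self):
        with pytest.raises(ValueError):
            scan_copy_number(make_scenario("WT"), "g_ASOR", [-1.0])


class TestDonnanOracle:
    def test_two_species_toy_reaches_closed_form_equilibrium(self):
        """Na/Cl conductances plus impermeant anion relax to the Donnan state
        computed by an independent root-finder."""
        params = TransporterParams(g_TPC=5.0, g_ASOR=5.0, k_CLC=0.0, g_H=0.0,
                                   J_pump_max=0.0, gating_removed=True)
        spec = ScenarioSpec(
            name="donnan_toy", params=params,
            initial_luminal={"Na": 150.0, "K": 0.0, "Cl": 120.0, "pH": 7.2},
            impermeant=[(30.0, -1)], U0=10.0, duration=20000.0)
        tr = simulate(spec, output_dt=100.0)
        end = tr.states[-1]

        # oracle: U such that Nernst-equilibrated Na/Cl satisfy both the
        # electroneutrality (with the impermeant anion) and osmotic closures
        rt = R * params.T / F * 1e3  # mV
        V0 = 4.0 / 3.0 * math.pi * 1e-18 * 1e3
        mol = V0 * 1e-3
        n_imp = 30.0 * mol
        n_x = (320.0 - 300.0) * mol

        A0 = 4.0 * math.pi * 1e-12
        q_off = params.c_m * A0 * (10.0 * 1e-3) / F

        def _area(v):
            return 4.0 * math.pi * (3.0 * v * 1e-3 / (4.0 * math.pi)) ** (2.0 / 3.0)

        def _volume(U, na, cl):
            # charge closure incl. the (tiny) capacitor charge; fixed point
            v = n_imp / ((na - cl) * 1e-3)
            for _ in range(5):
                dq = params.c_m * _area(v) * (U * 1e-3) / F - q_off
                v = (n_imp + dq) / ((na - cl) * 1e-3)
            return v

        def osmotic_residual(U):
            na = params.Na_c * math.exp(-U / rt)
            cl = params.Cl_c * math.exp(U / rt)
            v = _volume(U, na, cl)
            return (na + cl) * 1e-3 * v + n_x + n_imp - 0.320 * v

        # below about -13 mV the equilibrated lumen holds more Na+ than Cl-,
        # which the impermeant anion requires; bracket inside that branch
        u_eq = brentq(osmotic_residual, -150.0, -14.0, xtol=1e-12)
        na_eq = params.Na_c * math.exp(-u_eq / rt)
        cl_eq = params.Cl_c * math.exp(u_eq / rt)
        v_eq = _volume(u_eq, na_eq, cl_eq)

        assert end.conc_mM("Na") == pytest.approx(na_eq, rel=1e-6)
        assert end.conc_mM("Cl") == pytest.approx(cl_eq, rel=1e-6)
        assert end.V == pytest.approx(v_eq, rel=1e-6)


class TestValidation:
    def test_non_neutral_initial_lumen_rejected(self):
        spec = make_scenario("WT")
        spec.initial_luminal = {"Na": 150.0, "K": 5.0, "Cl": 300.0, "pH": 7.2}
        with pytest.raises(ValueError, match="electroneutral"):
            simulate(spec)

    def test_hyperosmotic_initial_lumen_rejected(self):
        spec = make_scenario("WT")
        spec.initial_luminal = {"Na": 300.0, "K": 5.0, "Cl": 309.0, "pH": 7.2}
        with pytest.raises(ValueError, match="osmolarity"):
            simulate(spec)

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError, match="unknown scenario"):
            make_scenario("nonsense")
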