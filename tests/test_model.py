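"""Serial-resistor model: steady state, transient, fitting, p_c."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

import nanoheat as nh
from nanoheat.synthetic import LatticeThermalSpec, simulate_lattice


@pytest.fixture()
def fig_stack():
    """Steady-state parameter pair fitted to the MD profile."""
    return nh.InterfaceStack(G_C=12.60, kappa_L=0.12, delta=4.0, t_W=1.0)


class TestSteadyState:
    def test_zero_power_is_isothermal(self, fig_stack):
        prof, summary = nh.steady_state_profile(fig_stack, 0.0)
        np.testing.assert_allclose(prof.temperature, 300.0)
        assert summary["T_G"] == summary["T_W"] == 300.0

    def test_printed_parameter_algebra(self, fig_stack):
        prof, s = nh.steady_state_profile(fig_stack, 1.0)
        assert s["T_G"] - s["T_W"] == pytest.approx(79.37, abs=0.01)
        assert s["T_W"] - 300.0 == pytest.approx(33.33, abs=0.01)
        assert s["T_G"] == pytest.approx(412.70, abs=0.01)

    def test_halving_kappa_doubles_lipid_drop_only(self, fig_stack):
        soft = nh.InterfaceStack(G_C=12.60, kappa_L=0.06, delta=4.0, t_W=1.0)
        _, s0 = nh.steady_state_profile(fig_stack, 1.0)
        _, s1 = nh.steady_state_profile(soft, 1.0)
        assert s1["T_W"] - 300 == pytest.approx(2 * (s0["T_W"] - 300), rel=1e-12)
        assert s1["T_G"] - s1["T_W"] == pytest.approx(s0["T_G"] - s0["T_W"], rel=1e-12)

    def test_flux_continuity_interface_equals_lipid(self, fig_stack):
        p = 3.7
        _, s = nh.steady_state_profile(fig_stack, p)
        q_iface = fig_stack.G_C * 1e6 * (s["T_G"] - s["T_W"])
        q_lipid = fig_stack.kappa_L * (s["T_W"] - 300.0) / (fig_stack.delta * 1e-9)
        assert q_iface == pytest.approx(q_lipid, rel=1e-12)
        assert q_iface == pytest.approx(p * 1e9, rel=1e-12)

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(p=st.floats(min_value=0.01, max_value=50.0),
           scale=st.floats(min_value=0.1, max_value=10.0))
    def test_superposition_linearity_in_power(self, p, scale):
        stack = nh.InterfaceStack(G_C=10.0, kappa_L=0.12, delta=4.0, t_W=1.0)
        _, s1 = nh.steady_state_profile(stack, p)
        _, s2 = nh.steady_state_profile(stack, scale * p)
        assert s2["T_G"] - 300 == pytest.approx(scale * (s1["T_G"] - 300), rel=1e-9)


class TestTransient:
    def test_initial_condition_is_water_plateau(self, paper_sheet, fig_stack):
        s = nh.transient_graphene_temperature(paper_sheet, fig_stack, 5.0,
                                              [0.0, 1.0, 2.0])
        assert s.temperature[0] == pytest.approx(fig_stack.water_temperature(5.0))

    def test_plateau_rise_is_p_over_G(self, paper_sheet):
        stack = nh.InterfaceStack(G_C=10.16, kappa_L=0.12, delta=4.0, t_W=1.0)
        s = nh.transient_graphene_temperature(
            paper_sheet, stack, 16.25, [1e6], T_W=300.0)
        assert s.temperature[0] - 300.0 == pytest.approx(1599.4, abs=0.1)

    def test_matches_numerical_ode_integration(self, paper_sheet):
        """Closed form vs an independent ODE solve of the same balance."""
        stack = nh.InterfaceStack(G_C=10.16, kappa_L=0.12, delta=4.0, t_W=1.0)
        p, T_W = 16.25, 300.0
        times = np.linspace(0.0, 400.0, 81)
        closed = nh.transient_graphene_temperature(paper_sheet, stack, p, times,
                                                   T_W=T_W)
        c_area = paper_sheet.heat_capacity_per_area  # J/m^2/K

        def rhs(t_ps, T):
            return (p * 1e9 - stack.G_C * 1e6 * (T - T_W)) / c_area * 1e-12

        sol = solve_ivp(rhs, (0.0, 400.0), [T_W], t_eval=times,
                        rtol=1e-10, atol=1e-8)
        np.testing.assert_allclose(closed.temperature, sol.y[0], rtol=1e-6)

    def test_energy_balance_residual(self, paper_sheet):
        stack = nh.InterfaceStack(G_C=10.16, kappa_L=0.12, delta=4.0, t_W=1.0)
        times = np.linspace(0.0, 500.0, 2001)
        s = nh.transient_graphene_temperature(paper_sheet, stack, 16.25, times,
                                              T_W=300.0)
        c_area = paper_sheet.heat_capacity_per_area
        dTdt = np.gradient(s.temperature, times * 1e-12)
        resid = c_area * dTdt - (16.25e9 - stack.G_C * 1e6 * (s.temperature - 300.0))
        # central differences limit the check, not the solution itself
        assert np.max(np.abs(resid[1:-1])) / 16.25e9 < 1e-4

    def test_steady_limit_matches_steady_profile(self, paper_sheet, fig_stack):
        p = 2.5
        s = nh.transient_graphene_temperature(paper_sheet, fig_stack, p, [1e7])
        _, summary = nh.steady_state_profile(fig_stack, p)
        assert s.temperature[0] == pytest.approx(summary["T_G"], rel=1e-9)


class TestTransientFit:
    def test_noiseless_roundtrip_recovers_G_C(self, paper_sheet):
        stack = nh.InterfaceStack(G_C=10.16, kappa_L=0.12, delta=4.0, t_W=1.0)
        times = np.arange(0.0, 401.0, 1.0)
        series = nh.transient_graphene_temperature(paper_sheet, stack, 16.25,
                                                   times, T_W=300.0)
        res = nh.TransientHeatingModel(series, paper_sheet, 16.25).fit()
        assert res.G_C == pytest.approx(10.16, rel=1e-3)
        assert res.identifiable
        assert "G_C" in res.summary()

    def test_early_time_only_flagged_unidentifiable(self, paper_sheet):
        stack = nh.InterfaceStack(G_C=10.16, kappa_L=0.12, delta=4.0, t_W=1.0)
        times = np.arange(0.0, 5.0, 0.5)  # t << tau ~ 159 ps
        series = nh.transient_graphene_temperature(paper_sheet, stack, 16.25,
                                                   times, T_W=300.0)
        with pytest.warns(UserWarning, match="plateau"):
            res = nh.fit_transient(series, paper_sheet, 16.25)
        assert not res.identifiable

    def test_lattice_heating_in_lumped_limit(self, paper_sheet):
        """The fitted per-area conductance matches the lattice's sheet-water
        junction conductance divided by the mapped area."""
        area = 100.0  # nm^2
        sheet = nh.GrapheneSheet(A=area)
        c_sheet = sheet.heat_capacity  # J/K
        g_iface = 10e6 * area * 1e-18  # 10 MW/m^2/K through the junction
        spec = LatticeThermalSpec(
            layer_sites=(1, 1, 1),
            site_heat_capacity=(c_sheet, 1e-20, 1e-20),
            link_conductance=(1e-7,) * 3,
            interface_conductance=(g_iface, 1e-7),
            sink_coupling=1e-7,
            heating_power=2e-9,
            dt=0.02,
            n_steps=30_000,
            area=area,
        )
        run = simulate_lattice(spec, "heating", record_stride=20)
        series = run.layer_series("sheet")
        res = nh.fit_transient(series, sheet, 2e-9 / (area * 1e-18) / 1e9)
        assert res.G_C == pytest.approx(spec.interface_conductance_per_area(0),
                                        rel=0.05)


class TestSteadyFit:
    def test_noiseless_roundtrip(self, fig_stack):
        prof, _ = nh.steady_state_profile(fig_stack, 1.0, bin_width=0.1)
        res = nh.SteadyProfileModel(prof, 1.0, z_s=fig_stack.z_s,
                                    delta=fig_stack.delta).fit()
        assert res.G_C == pytest.approx(12.60, rel=1e-3)
        assert res.kappa_L == pytest.approx(0.12, rel=1e-3)
        assert res.identifiable

    def test_noisy_profile_within_5pct(self, fig_stack):
        prof, _ = nh.steady_state_profile(fig_stack, 1.0, bin_width=0.1)
        rng = np.random.default_rng(3)
        assert len(prof.z_bins) >= 50
        noisy = nh.TemperatureProfile(
            z_bins=prof.z_bins,
            temperature=prof.temperature + rng.normal(0, 2.0, len(prof.z_bins)),
        )
        res = nh.fit_steady_parameters(noisy, 1.0, z_s=fig_stack.z_s,
                                       delta=fig_stack.delta)
        assert res.G_C == pytest.approx(12.60, rel=0.05)
        assert res.kappa_L == pytest.approx(0.12, rel=0.05)

    def test_zero_interface_drop_flagged_infinite(self, fig_stack):
        prof, s = nh.steady_state_profile(fig_stack, 1.0)
        flat = prof.temperature.copy()
        flat[prof.z_bins < 0] = s["T_W"]  # erase the interfacial step
        with pytest.warns(UserWarning, match="unidentifiable"):
            res = nh.fit_steady_parameters(
                nh.TemperatureProfile(prof.z_bins, flat), 1.0,
                z_s=fig_stack.z_s, delta=fig_stack.delta)
        assert np.isinf(res.G_C)
        assert not res.identifiable

    def test_degenerate_gradient_free_profile_errors(self, fig_stack):
        prof, _ = nh.steady_state_profile(fig_stack, 1.0)
        flat = nh.TemperatureProfile(prof.z_bins,
                                     np.full_like(prof.temperature, 300.0))
        with pytest.raises(ValueError, match="degenerate"):
            nh.fit_steady_parameters(flat, 1.0, z_s=fig_stack.z_s,
                                     delta=fig_stack.delta)


class TestCriticalPowerPrediction:
    def test_surface_formula(self, fig_stack):
        pc = nh.predict_critical_power(fig_stack, 20.0, "lipid_surface")
        assert pc == pytest.approx(0.6, rel=1e-12)

    def test_average_doubles_surface(self, fig_stack):
        assert nh.predict_critical_power(fig_stack, 20.0, "lipid_average") == (
            pytest.approx(2 * nh.predict_critical_power(fig_stack, 20.0), rel=1e-12))

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(dtc=st.floats(min_value=1.0, max_value=100.0))
    def test_linear_in_threshold(self, dtc):
        stack = nh.InterfaceStack(G_C=12.60, kappa_L=0.12, delta=4.0, t_W=1.0)
        one = nh.predict_critical_power(stack, dtc)
        two = nh.predict_critical_power(stack, 2 * dtc)
        assert two == pytest.approx(2 * one, rel=1e-12)

    def test_flux_partition_reconciling_observed_pc(self, fig_stack):
        """eta that maps the serial model onto an observed p_c of 7.5 GW/m^2
        at a 20 K threshold; reported as a fitted partition."""
        eta = nh.fit_flux_partition(fig_stack, 20.0, 7.5)
        assert eta == pytest.approx(0.08, rel=1e-9)
        tuned = nh.InterfaceStack(G_C=12.60, kappa_L=0.12, delta=4.0,
                                  t_W=1.0, eta=eta)
        assert nh.predict_critical_power(tuned, 20.0) == pytest.approx(7.5, rel=1e-9)
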