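"""Slab temperatures, relaxation-time fits, Kapitza conductance, p_c."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import nanoheat as nh
from nanoheat.synthetic import maxwell_boltzmann_velocities


def _thermal_traj(temps_by_slab, n_per_slab=400, bw=0.2, seed=0):
    """Pseudo-particles placed per slab with MB velocities at given temps."""
    zs, temps = [], []
    for i, T in enumerate(temps_by_slab):
        zs.append(np.full(n_per_slab, (i + 0.5) * bw))
        temps.append(T)
    z = np.concatenate(zs)
    n = len(z)
    rng = np.random.default_rng(seed)
    pos = np.column_stack([rng.random(n) * 5, rng.random(n) * 5, z])[None]
    masses = np.full(n, 18.01528)
    vel = np.empty((1, n, 3))
    for i, T in enumerate(temps):
        sl = slice(i * n_per_slab, (i + 1) * n_per_slab)
        vel[0, sl] = maxwell_boltzmann_velocities(masses[sl], T, seed=seed + i)
    return nh.Trajectory(positions=pos, velocities=vel, masses=masses,
                         species=np.full(n, "W"), box=np.array([5, 5, 10.0]),
                         times=np.array([0.0]))


class TestSlabTemperature:
    def test_maxwell_boltzmann_slabs_read_300K(self):
        traj = _thermal_traj([300.0] * 5, n_per_slab=2000, seed=4)
        prof = nh.slab_temperature_profile(traj, bin_width=0.2)
        occ = np.isfinite(prof.temperature)
        # sampling error ~ T * sqrt(2/(3N))
        assert np.all(np.abs(prof.temperature[occ] - 300.0) < 300 * 4 * np.sqrt(2 / (3 * 2000)))

    def test_velocity_scaling_doubles_temperature_exactly(self):
        traj = _thermal_traj([250.0, 350.0], seed=1)
        hot = nh.Trajectory(positions=traj.positions,
                            velocities=traj.velocities * np.sqrt(2),
                            masses=traj.masses, species=traj.species,
                            box=traj.box, times=traj.times)
        p0 = nh.slab_temperature_profile(traj, bin_width=0.2)
        p1 = nh.slab_temperature_profile(hot, bin_width=0.2)
        occ = np.isfinite(p0.temperature)
        np.testing.assert_allclose(p1.temperature[occ], 2 * p0.temperature[occ],
                                   rtol=1e-12)

    def test_steady_resistor_profile_recovered_from_pseudo_particles(self):
        """Particles thermalized to the model's piecewise steady profile read
        back the interface drop and lipid gradient within 2%."""
        stack = nh.InterfaceStack(G_C=12.60, kappa_L=0.12, delta=4.0, t_W=1.0)
        model_profile, summary = nh.steady_state_profile(stack, 1.0, bin_width=0.4)
        temps = summary["T_G"], summary["T_W"], *np.linspace(
            summary["T_W"], 300.0, 6)[1:-1]
        traj = _thermal_traj(list(temps), n_per_slab=20_000, bw=0.4, seed=8)
        prof = nh.slab_temperature_profile(traj, bin_width=0.4)
        occ = np.isfinite(prof.temperature)
        measured = prof.temperature[occ]
        assert measured[0] == pytest.approx(summary["T_G"], rel=0.02)
        assert measured[1] == pytest.approx(summary["T_W"], rel=0.02)
        assert np.all(np.diff(measured[1:]) < 0)  # lipid gradient

    def test_empty_slab_is_nan_not_zero(self):
        traj = _thermal_traj([300.0], n_per_slab=50)
        # widen the binning range past the occupied region
        traj.positions[0, 0, 2] = 2.05
        prof = nh.slab_temperature_profile(traj, bin_width=0.2)
        assert np.isnan(prof.temperature).any()
        assert not np.any(prof.temperature == 0.0)

    def test_missing_velocities_rejected(self):
        traj = nh.Trajectory(positions=np.zeros((1, 2, 3)) + 0.5,
                             masses=[18, 18], species=["W", "W"],
                             box=[5, 5, 5], times=[0.0])
        with pytest.raises(ValueError, match="velocities"):
            nh.slab_temperature_profile(traj)


class TestRelaxation:
    def test_constant_series_rejected(self):
        s = nh.TemperatureSeries(np.arange(100.0), np.full(100, 300.0))
        with pytest.raises(ValueError):
            nh.relaxation_time(s, 300.0)

    def test_paper_constant_tau_recovered_to_0p1pct(self, paper_sheet):
        # tau = rho_g c_g d / G_C with G_C = 10.16 MW/m^2/K
        tau = paper_sheet.heat_capacity_per_area / 10.16e6 / 1e-12  # ps
        t = np.arange(0.0, 1000.0, 1.0)
        s = nh.TemperatureSeries(t, 300.0 + 200.0 * np.exp(-t / tau))
        fit = nh.relaxation_time(s, 300.0)
        assert fit.tau == pytest.approx(tau, rel=1e-3)
        assert tau == pytest.approx(159.17, abs=0.01)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(tau=st.floats(min_value=10.0, max_value=1e4),
           dT0=st.floats(min_value=5.0, max_value=500.0))
    def test_exponential_roundtrip_identity(self, tau, dT0):
        t = np.linspace(0.0, 5 * tau, 400)
        s = nh.TemperatureSeries(t, 300.0 + dT0 * np.exp(-t / tau))
        fit = nh.relaxation_time(s, 300.0)
        assert fit.tau == pytest.approx(tau, rel=1e-6)


class TestKapitza:
    def test_areal_heat_capacity_value(self, paper_sheet):
        assert paper_sheet.heat_capacity_per_area == pytest.approx(1.617e-3, rel=1e-3)

    def test_tau_159ps_gives_10p16(self, paper_sheet):
        assert nh.kapitza_conductance(paper_sheet, 159.17) == pytest.approx(10.16, rel=1e-3)

    def test_vanishes_for_long_tau(self, paper_sheet):
        assert nh.kapitza_conductance(paper_sheet, 1e12) < 1e-8

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(area=st.floats(min_value=1.0, max_value=1e4))
    def test_independent_of_area(self, area):
        a = nh.GrapheneSheet(A=area)
        b = nh.GrapheneSheet(A=27.55)
        assert nh.kapitza_conductance(a, 100.0) == pytest.approx(
            nh.kapitza_conductance(b, 100.0), rel=1e-12)


class TestCriticalPower:
    def test_piecewise_linear_crossing_is_exact(self):
        p = np.linspace(0, 16, 33)
        dT = np.maximum(0.0, 4.0 * (p - 2.5))
        pc = nh.critical_power(nh.DeltaTCurve(p, dT), 20.0)
        assert pc == pytest.approx(7.5, rel=1e-12)

    def test_flat_curve_below_threshold_errors_with_max(self):
        curve = nh.DeltaTCurve(np.linspace(0, 10, 11), np.full(11, 5.0))
        with pytest.raises(ValueError, match="max dT = 5"):
            nh.critical_power(curve, 20.0)

    def test_noisy_replicates_within_10pct(self):
        rng = np.random.default_rng(17)
        p = np.linspace(0, 16, 17)
        truth = np.maximum(0.0, 4.0 * (p - 2.5))
        pcs = []
        for _ in range(5):
            noisy = truth + rng.normal(0, 1.0, len(p))
            noisy[0] = max(noisy[0], 0.0)
            pcs.append(nh.critical_power(
                nh.DeltaTCurve(p, noisy), 20.0))
        assert np.mean(pcs) == pytest.approx(7.5, rel=0.10)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(a=st.floats(min_value=0.5, max_value=20.0))
    def test_monotone_nonincreasing_in_slope(self, a):
        p = np.linspace(0, 100, 2001)
        pc_a = nh.critical_power(nh.DeltaTCurve(p, a * p), 20.0)
        pc_2a = nh.critical_power(nh.DeltaTCurve(p, 2 * a * p), 20.0)
        assert pc_2a <= pc_a + 1e-9
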