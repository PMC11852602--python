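"""BMU kinetics: stimulus, activation sigmoid, specific surface, history
windows, porosity rates, electrical modulation, and the day-stepping loop."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from osteostim import (
    BMUClassParams, BMUHistoryBuffer, ConstantStimulus, MaterialMapping,
    RemodelingEngine, RemodelingParams, StimulationProtocol,
    build_material_field, daily_stimulus, disuse_activation_frequency,
    equilibrium_stimulus, es_modulated_activation, filling_rate,
    generate_block_fixture, porosity_rate, resorption_rate, specific_surface,
    synthetic_hu_field, CLASS_CORTICAL, CLASS_CANCELLOUS,
)

P = RemodelingParams()


def brute_force_counts(history, cp: BMUClassParams):
    """Independent oracle: windowed sums over an explicit history list."""
    h = np.asarray(history, dtype=float)
    n_r = np.sum(h[len(h) - cp.t_r:])
    lo = len(h) - cp.history_length
    n_f = np.sum(h[lo:lo + cp.t_f])
    return n_r, n_f


class TestStimulus:
    def test_single_case_identity(self):
        assert daily_stimulus(np.array([[2.0]]), np.array([1]), 4.0) == pytest.approx(2.0)

    def test_cycle_weighted_power_mean(self):
        vm = np.ones((3, 5))
        phi = daily_stimulus(vm, np.array([6000, 2000, 2000]), 4.0)
        assert np.allclose(phi, 10.0, rtol=1e-12)

    def test_zero_stress_zero_stimulus(self):
        assert np.all(daily_stimulus(np.zeros((3, 4)), np.array([6000, 2000, 2000]), 4.0) == 0)

    def test_equilibrium_from_single_loaded_case(self):
        vm = np.array([[2.0], [0.0], [0.0]])
        phi0 = equilibrium_stimulus(vm, np.array([6000, 2000, 2000]), 4.0)
        assert phi0[0] == pytest.approx(2.0 * 6000 ** 0.25, rel=1e-6)
        assert phi0[0] == pytest.approx(17.607, rel=1e-3)

    def test_floor_applies(self):
        phi0 = equilibrium_stimulus(np.zeros((3, 2)), np.array([1, 1, 1]), 4.0,
                                    floor=1e-6)
        assert np.all(phi0 == 1e-6)


class TestActivationSigmoid:
    def test_equilibrium_value(self):
        fa = disuse_activation_frequency(1.0, 1.0, 0.5, 0.1, 0.1)
        assert fa == pytest.approx(0.1 / (1 + np.e ** 5), rel=1e-12)

    def test_full_disuse_value(self):
        fa = disuse_activation_frequency(0.0, 1.0, 0.5, 0.1, 0.1)
        assert fa == pytest.approx(0.1 / (1 + np.e ** -5), rel=1e-12)

    def test_saturation_limits(self):
        assert disuse_activation_frequency(1e9, 1.0, 0.5, 0.1, 0.1) == 0.0
        assert disuse_activation_frequency(0.0, 1e-12, 0.5, 0.1, 0.1) <= 0.1

    @given(st.floats(0.0, 10.0), st.floats(0.0, 10.0))
    @settings(deadline=None, max_examples=50)
    def test_strictly_decreasing_in_stimulus(self, a, b):
        lo, hi = sorted((a, b))
        fa_lo = disuse_activation_frequency(lo, 1.0, 0.5, 0.1, 0.1)
        fa_hi = disuse_activation_frequency(hi, 1.0, 0.5, 0.1, 0.1)
        assert fa_hi <= fa_lo
        assert 0.0 <= fa_hi <= 0.1


class TestSurfaceAndRates:
    @pytest.mark.parametrize("p,expected", [(0.0, 0.0), (0.5, 3.9125)])
    def test_specific_surface_values(self, p, expected):
        assert specific_surface(p) == pytest.approx(expected, abs=1e-12)

    def test_specific_surface_vanishes_at_full_porosity(self):
        assert specific_surface(1.0) == pytest.approx(0.0, abs=1e-12)

    def test_specific_surface_nonnegative_on_unit_interval(self):
        p = np.linspace(0.0, 1.0, 1001)
        assert np.all(specific_surface(p) >= -1e-12)

    def test_out_of_range_porosity_rejected(self):
        with pytest.raises(Exception):
            specific_surface(np.array([1.2]))

    def test_bmu_geometry_rates(self):
        q_can = resorption_rate(CLASS_CANCELLOUS, P)
        q_cor = resorption_rate(CLASS_CORTICAL, P)
        assert q_can == pytest.approx(np.pi * 0.05 * 0.65 * 0.01 / 4, rel=1e-12)
        assert q_cor == pytest.approx(np.pi * 0.2 ** 2 * 0.01 / 4, rel=1e-12)
        assert resorption_rate(CLASS_CORTICAL, RemodelingParams(v=0.0)) == 0.0

    def test_filling_rate_balances_equilibrium(self):
        q_r = resorption_rate(CLASS_CORTICAL, P)
        q_f = filling_rate(q_r, 24, 64)
        assert q_f == pytest.approx(q_r * 24 / 64, rel=1e-12)
        assert filling_rate(q_r, 10, 10) == q_r
        c = 0.0123
        assert porosity_rate(c * 24, c * 64, q_r, q_f) == pytest.approx(0.0, abs=1e-18)

    def test_resorption_only_is_positive(self):
        assert porosity_rate(1.0, 0.0, 1e-4, 1e-4) > 0


class TestHistoryBuffer:
    @pytest.mark.parametrize("cp", [BMUClassParams(24, 8, 64),
                                    BMUClassParams(60, 57, 197)])
    def test_constant_history(self, cp):
        buf = BMUHistoryBuffer(3, cp, prefill=0.01)
        n_r, n_f = buf.counts()
        assert np.allclose(n_r, 0.01 * cp.t_r, rtol=1e-12)
        assert np.allclose(n_f, 0.01 * cp.t_f, rtol=1e-12)

    def test_zero_history(self):
        buf = BMUHistoryBuffer(2, BMUClassParams(24, 8, 64), prefill=0.0)
        n_r, n_f = buf.counts()
        assert np.all(n_r == 0) and np.all(n_f == 0)

    @pytest.mark.parametrize("cp", [BMUClassParams(24, 8, 64),
                                    BMUClassParams(60, 57, 197)])
    def test_matches_brute_force_exactly(self, cp, rng):
        """Ring-buffer windowed sums equal an explicit-list oracle bit for bit
        through hundreds of appends."""
        n_el = 50
        buf = BMUHistoryBuffer(n_el, cp, prefill=0.0)
        history = [np.zeros(n_el)] * cp.history_length
        for day in range(400):
            vals = rng.uniform(0, 0.2, n_el)
            buf.append(vals)
            history.append(vals)
            n_r, n_f = buf.counts()
            stacked = np.stack(history[-cp.history_length:])
            # (element, day) layout so the summation order matches exactly
            win_r = np.ascontiguousarray(stacked[cp.history_length - cp.t_r:].T)
            win_f = np.ascontiguousarray(stacked[:cp.t_f].T)
            assert np.array_equal(n_r, win_r.sum(axis=1))
            assert np.array_equal(n_f, win_f.sum(axis=1))

    def test_impulse_reaches_filling_after_exact_delay(self):
        """A unit impulse enters N_R immediately and first appears in N_F
        exactly T_R + T_I days later."""
        cp = BMUClassParams(24, 8, 64)
        buf = BMUHistoryBuffer(1, cp, prefill=0.0)
        buf.append(np.array([1.0]))
        seen_in_f = []
        assert buf.counts()[0][0] == 1.0
        for day in range(2, cp.history_length + 2):
            buf.append(np.array([0.0]))
            if buf.counts()[1][0] > 0:
                seen_in_f.append(day)
        assert seen_in_f[0] == 1 + cp.t_r + cp.t_i
        assert seen_in_f[-1] == cp.t_r + cp.t_i + cp.t_f


class TestESModulation:
    def test_zero_amplitude_is_identity(self):
        fa = np.array([0.05, 0.01])
        proto = StimulationProtocol(amplitude=0.0, start_day=1, duration_days=10)
        assert np.array_equal(
            es_modulated_activation(fa, np.ones(2), 0.0, 5, proto), fa)

    def test_zero_potential_is_identity(self):
        fa = np.array([0.05])
        proto = StimulationProtocol(amplitude=0.7, start_day=1, duration_days=10)
        assert np.array_equal(
            es_modulated_activation(fa, np.zeros(1), 0.7, 5, proto), fa)

    def test_peak_suppression(self):
        fa = np.array([9.9331e-2])
        proto = StimulationProtocol(amplitude=0.7, start_day=1, duration_days=10)
        out = es_modulated_activation(fa, np.ones(1), 0.7, 3, proto)
        assert out[0] == pytest.approx(2.9799e-2, rel=1e-4)

    def test_inactive_outside_window(self):
        fa = np.array([0.05])
        proto = StimulationProtocol(amplitude=0.7, start_day=101, duration_days=50)
        assert es_modulated_activation(fa, np.ones(1), 0.7, 100, proto)[0] == 0.05
        assert es_modulated_activation(fa, np.ones(1), 0.7, 151, proto)[0] == 0.05


def _block_engine(n=(4, 4, 4), phi_over_phi0=1.0, protocol=None, phi_hat=None,
                  params=None):
    """Small mixed-class engine on a block mesh with a fixed stimulus field."""
    mesh = generate_block_fixture(*n, (20.0, 20.0, 20.0))
    hu = synthetic_hu_field(mesh, 1700.0, 900.0, 50.0, shell_thickness_mm=3.0)
    mats = build_material_field(mesh, hu, MaterialMapping())
    phi0 = np.full(mesh.n_elements, 10.0)
    stim = ConstantStimulus(phi0 * phi_over_phi0)
    engine = RemodelingEngine(mesh, mats, params or RemodelingParams(),
                              phi0, stim, phi_hat=phi_hat, protocol=protocol)
    return engine


class TestEngine:
    def test_zero_day_run_returns_initial_state(self):
        engine = _block_engine()
        rho_before = engine.materials.density.copy()
        traj = engine.run(total_days=0)
        assert np.array_equal(traj.final_density, rho_before)
        assert len(traj.table) == 0

    def test_homeostasis_short(self):
        """At Phi = Phi0 with no stimulation the equilibrium pre-fill makes
        the porosity rate vanish: densities hold to machine precision."""
        engine = _block_engine(phi_over_phi0=1.0)
        rho0 = engine.materials.density.copy()
        traj = engine.run(total_days=60)
        drift = np.nanmax(np.abs(traj.final_density - rho0))
        assert drift <= 1e-12

    def test_deterministic_repeat(self):
        t1 = _block_engine(phi_over_phi0=0.4).run(total_days=80)
        t2 = _block_engine(phi_over_phi0=0.4).run(total_days=80)
        assert np.array_equal(t1.final_density, t2.final_density)
        assert t1.table.equals(t2.table)

    def test_disuse_loses_density(self):
        engine = _block_engine(phi_over_phi0=0.2)
        rho0 = engine.materials.density.copy()
        traj = engine.run(total_days=120)
        bone = engine.materials.is_bone
        assert np.all(traj.final_density[bone] <= rho0[bone] + 1e-15)
        assert np.nanmean(traj.final_density[bone] - rho0[bone]) < -1e-4

    def test_total_disuse_cortical_early_rate(self):
        """Under Phi = 0 the early cortical loss rate approaches
        -rho0 * Q_R * N_R once the resorption window saturates but before
        the new activation reaches the filling window."""
        params = RemodelingParams()
        engine = _block_engine(phi_over_phi0=0.0, params=params)
        cp = params.cortical
        for _ in range(cp.t_r + cp.t_i):
            engine.step_day()
        idx = engine.class_idx[CLASS_CORTICAL]
        buf = engine.buffers[CLASS_CORTICAL]
        n_r, n_f = buf.counts()
        q_r, q_f = engine.rates_qrqf[CLASS_CORTICAL]
        rate = engine._last_dpdt[idx]
        assert np.allclose(rate, q_r * n_r, rtol=0.02)

    def test_porosity_stays_in_clamp_bounds(self):
        engine = _block_engine(phi_over_phi0=0.0)
        traj = engine.run(total_days=400)
        bone = engine.materials.is_bone
        assert np.all(engine.materials.porosity[bone] <= 0.99)
        assert np.all(engine.materials.porosity[bone] >= 0.01)
        assert np.all(traj.final_density[bone] >= 0.018 - 1e-12)

    def test_monotone_dose_response_fixed_stimulus(self):
        """With a fixed stimulus field, stronger stimulation amplitude never
        yields lower final density, element by element."""
        finals = []
        for amp in (0.0, 0.3, 0.5, 0.7):
            proto = StimulationProtocol(amplitude=amp, start_day=31,
                                        duration_days=60)
            engine = _block_engine(phi_over_phi0=0.3, protocol=proto,
                                   phi_hat=None)
            engine.phi_hat = np.linspace(0, 1, engine.mesh.n_elements)
            finals.append(engine.run(total_days=120).final_density)
        bone = ~np.isnan(finals[0])
        for lo, hi in zip(finals, finals[1:]):
            assert np.all(hi[bone] >= lo[bone] - 1e-12)

    def test_stimulation_flips_rate_sign_transiently(self):
        """Suppressing activation cuts resorption within T_R days while
        filling still reflects the pre-stimulation past: the cortical density
        rate (resorption/reversal lag of 32 days) turns positive during a
        long stimulation window."""
        proto = StimulationProtocol(amplitude=0.7, start_day=61, duration_days=100)
        engine = _block_engine(phi_over_phi0=0.2, protocol=proto)
        engine.phi_hat = np.ones(engine.mesh.n_elements)
        traj = engine.run(total_days=160)
        rate = traj.table.density_rate_cortical.to_numpy()
        assert rate[59] < 0          # disuse loss before stimulation
        assert rate[60] > rate[59]   # immediate upward jump at onset
        assert rate[99:160].max() > 0   # density increasing late in window
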