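"""Integration, event handling and observables tests."""

import numpy as np
import pytest

from microshift import (
    FeedingPhase,
    FeedingSchedule,
    PulseEvent,
    ReactorState,
    Scenario,
    StrainParameters,
    max_specific_growth_rate,
    observables,
    rhs,
    simulate,
)
from microshift.feeding import feed_rate
from microshift.simulate import Trajectory

from .conftest import W3110_KW, batch_scenario


def rk4_batch(scenario, t_end, dt=1e-3):
    """Fixed-step classical Runge-Kutta oracle for a no-feed scenario."""
    y = np.array(scenario.initial_state.to_array())

    def f(t, y):
        deriv, _ = rhs(t, ReactorState.from_array(np.maximum(y, 0.0)),
                       scenario.params, 0.0, 0.0, scenario.t_lag)
        return np.array(deriv)

    t = scenario.t0
    n = int(round((t_end - scenario.t0) / dt))
    for _ in range(n):
        k1 = f(t, y)
        k2 = f(t + dt / 2, y + dt / 2 * k1)
        k3 = f(t + dt / 2, y + dt / 2 * k2)
        k4 = f(t + dt, y + dt * k3)
        y = y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        t += dt
    return y


class TestBasicIntegration:
    def test_zero_cell_scenario_is_constant(self, w3110_params):
        sc = batch_scenario(w3110_params, G0=5.0, C_M0=0.0, P0=0.0)
        traj = simulate(sc)
        assert np.allclose(traj.column("G"), 5.0)
        for f in ("P", "A", "C_M", "R", "I", "D"):
            assert np.allclose(traj.column(f), 0.0)

    def test_stocks_remain_nonnegative(self, w3110_trajectory):
        assert traj_min(w3110_trajectory) >= 0.0

    def test_adaptive_solution_matches_fixed_step_oracle(self, w3110_params):
        """5 h batch window: stiff adaptive vs classical RK4 at dt = 1e-3 h."""
        sc = batch_scenario(w3110_params, t_end=5.0)
        traj = simulate(sc, output_grid_step=0.05)
        y_oracle = rk4_batch(sc, 5.0)
        y_solver = traj.states[-1]
        scale = np.maximum(np.abs(y_oracle[:8]), 1e-6)
        rel = np.abs(y_solver - y_oracle[:8]) / scale
        assert rel.max() < 1e-3

    def test_halving_tolerances_stable(self, w3110_params):
        sc = batch_scenario(w3110_params, t_end=5.0)
        b1 = final_biomass(simulate(sc, rtol=1e-6, atol=1e-9))
        b2 = final_biomass(simulate(sc, rtol=5e-7, atol=5e-10))
        assert abs(b1 - b2) / b1 < 1e-4

    def test_grid_refinement_consistency(self, w3110_params):
        sc = batch_scenario(w3110_params, t_end=5.0)
        coarse = simulate(sc, output_grid_step=0.1)
        fine = simulate(sc, output_grid_step=0.01)
        shared = np.intersect1d(np.round(coarse.times, 9), np.round(fine.times, 9))
        ic = np.searchsorted(np.round(coarse.times, 9), shared)
        jf = np.searchsorted(np.round(fine.times, 9), shared)
        mass_c = coarse.states[ic, :4].sum(axis=1)
        mass_f = fine.states[jf, :4].sum(axis=1)
        assert np.max(np.abs(mass_c - mass_f) / np.maximum(mass_f, 1e-9)) < 1e-4


class TestSegmentation:
    def test_artificial_phase_split_is_invisible(self, w3110_params):
        """A batch run split into two batch phases integrates identically."""
        one = batch_scenario(w3110_params, t_end=5.0)
        split = Scenario(
            initial_state=one.initial_state,
            schedule=FeedingSchedule(
                phases=(FeedingPhase("batch", 0.0), FeedingPhase("batch", 2.5)),
                V0=1.0, t_end=5.0,
            ),
            params=w3110_params,
        )
        a = simulate(one).states[-1]
        b = simulate(split).states[-1]
        assert np.allclose(a, b, rtol=1e-5, atol=1e-9)

    def test_pulse_event_applied_exactly(self, w3110_params):
        sc = batch_scenario(w3110_params, G0=1.0, C_M0=0.0, P0=0.0, t_end=4.0)
        pulsed = Scenario(
            initial_state=sc.initial_state,
            schedule=FeedingSchedule(
                phases=(FeedingPhase("batch", 0.0),), V0=1.0, t_end=4.0,
                pulses=(PulseEvent(2.0, 2.0),),
            ),
            params=w3110_params,
        )
        traj = simulate(pulsed)
        # no cells: G is piecewise constant with a 2 g jump at t = 2
        assert np.allclose(traj.column("G")[traj.times < 2.0], 1.0)
        assert np.allclose(traj.column("G")[traj.times >= 2.0], 3.0)

    def test_lag_holds_glucose_until_t_lag(self, w3110_params):
        sc = batch_scenario(w3110_params, t_end=5.0, t_lag=2.0)
        traj = simulate(sc)
        g = traj.column("G")
        assert np.allclose(g[traj.times <= 2.0], 5.0, rtol=1e-9)
        assert g[-1] < 5.0


class TestGlucoseLedger:
    def test_batch_conservation(self, w3110_params):
        sc = batch_scenario(w3110_params, t_end=5.0)
        traj = simulate(sc)
        g0, g_end = traj.column("G")[0], traj.column("G")[-1]
        assert g0 - g_end == pytest.approx(traj.cumulative_uptake[-1], rel=1e-6)

    def test_fed_batch_conservation(self, w3110_preset):
        traj = simulate(w3110_preset.scenario)
        sched = w3110_preset.scenario.schedule
        stops = [p.t_start for p in sched.phases[1:]] + [sched.t_end]
        fed = sum(
            ph.fed_volume(ph.t_start, stop) * ph.c_F
            for ph, stop in zip(sched.phases, stops)
        )
        fed += sum(p.glucose_mass for p in sched.pulses)
        supplied = traj.column("G")[0] + fed
        residual = traj.column("G")[-1] + traj.cumulative_uptake[-1]
        assert residual == pytest.approx(supplied, rel=1e-6)


class TestDeathSwitch:
    @pytest.fixture(scope="class")
    def lethal_run(self):
        # a low death threshold makes [P] cross tau during batch growth
        params = StrainParameters(**dict(W3110_KW, tau=0.1))
        sc = batch_scenario(params, t_end=10.0)
        return simulate(sc)

    def test_death_flux_active_iff_threshold_exceeded(self, lethal_run):
        pconc = np.array([d.Pconc for d in lethal_run.derived])
        death = np.array([r.death_cm for r in lethal_run.rates])
        cm = lethal_run.column("C_M")
        tau, delta = 0.1, 0.1
        on = pconc > tau
        assert np.all(death[~on] == 0.0)
        assert np.allclose(death[on], delta * cm[on], rtol=1e-9)

    def test_dead_mass_grows_only_while_switch_on(self, lethal_run):
        d = lethal_run.column("D")
        assert d[-1] > 0.0
        dd = np.diff(d)
        assert dd.min() > -1e-12  # D never decreases

    def test_inhibitor_stock_nondecreasing(self, w3110_trajectory):
        di = np.diff(w3110_trajectory.column("I"))
        assert di.min() > -1e-12


class TestObservables:
    def test_pure_exponential_growth_rate_recovered(self, w3110_batch):
        times = np.arange(0.0, 10.0001, 0.05)
        states = np.zeros((times.size, 8))
        states[:, 3] = 0.2 * np.exp(0.3 * times)  # C_M only
        states[:, 7] = 1.0
        traj = Trajectory(times=times, states=states,
                          cumulative_uptake=np.zeros_like(times),
                          scenario=w3110_batch)
        assert max_specific_growth_rate(traj, (1.0, 9.0)) == pytest.approx(0.3, rel=1e-6)

    def test_stationary_segment_rate_zero(self, w3110_batch):
        times = np.arange(0.0, 5.0001, 0.05)
        states = np.zeros((times.size, 8))
        states[:, 3] = 1.0
        states[:, 7] = 1.0
        traj = Trajectory(times=times, states=states,
                          cumulative_uptake=np.zeros_like(times),
                          scenario=w3110_batch)
        assert max_specific_growth_rate(traj, (0.0, 5.0)) == pytest.approx(0.0, abs=1e-12)

    def test_empty_window_rejected(self, w3110_trajectory):
        with pytest.raises(ValueError):
            max_specific_growth_rate(w3110_trajectory, (5.0, 5.0))

    def test_concentrations_finite_and_nonnegative(self, w3110_trajectory):
        obs = observables(w3110_trajectory)
        for arr in (obs.biomass_conc, obs.glucose_conc, obs.acetate_conc):
            assert np.all(np.isfinite(arr))
            assert arr.min() >= 0.0

    def test_dead_cells_excluded_from_biomass_by_default(self, w3110_batch):
        times = np.array([0.0, 1.0])
        states = np.zeros((2, 8))
        states[:, 3] = 1.0   # C_M
        states[:, 6] = 9.0   # D
        states[:, 7] = 1.0
        traj = Trajectory(times=times, states=states,
                          cumulative_uptake=np.zeros(2), scenario=w3110_batch)
        assert observables(traj).biomass_conc == pytest.approx([1.0, 1.0])

    def test_concentrations_use_time_matched_volume(self, w3110_preset):
        traj = simulate(w3110_preset.scenario)
        obs = observables(traj)
        v = traj.column("V")
        assert np.allclose(obs.glucose_conc, traj.column("G") / v)
        assert v[-1] > v[0]  # feeding added volume


class TestMonodLimit:
    def test_batch_growth_monotone_without_feedbacks(self):
        """With feedbacks off, batch biomass rises monotonically to G exhaustion."""
        params = StrainParameters(
            **dict(W3110_KW, sigma_A=1e-12, sigma_I=1e-12, P_max=1e6)
        )
        traj = simulate(batch_scenario(params, t_end=10.0))
        mass = traj.column("P") + traj.column("C_M") + traj.column("R")
        g = traj.column("G")
        growing = g > 1e-3
        dmass = np.diff(mass[growing])
        assert dmass.min() > -1e-9


def traj_min(traj) -> float:
    return float(traj.states.min())


def final_biomass(traj) -> float:
    return float(traj.states[-1, 1] + traj.states[-1, 3] + traj.states[-1, 4])
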