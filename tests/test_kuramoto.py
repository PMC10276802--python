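"""Kuramoto core: critical coupling, order parameter, logistic schedule,
integration invariants."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from kurasync import (
    CouplingSchedule,
    OscillatorEnsemble,
    SimulationConfig,
    classify_locked_drifting,
    coupling_crossing_time,
    critical_coupling,
    logistic_closed_form,
    order_parameter,
    simulate,
)

from conftest import PAPER_A, PAPER_C, PAPER_K0


class TestCriticalCoupling:
    def test_published_fourteen_oscillator_value(self, table1_ensemble):
        res = critical_coupling(table1_ensemble)
        assert res.K_c == pytest.approx(69.02359, rel=1e-3)

    def test_two_oscillators_reduce_to_frequency_gap(self):
        res = critical_coupling(OscillatorEnsemble([0.0, 1.0]))
        assert res.gamma == pytest.approx(np.pi / 2)
        assert res.K_c == pytest.approx(1.0)

    def test_identical_frequencies_need_no_coupling(self):
        assert critical_coupling(OscillatorEnsemble([2.0, 2.0, 2.0])).K_c == 0.0

    def test_scales_linearly_with_frequencies(self, table1_ensemble):
        w = table1_ensemble.natural_frequencies
        for lam in (0.5, 2.0, 2 * np.pi):
            assert critical_coupling(OscillatorEnsemble(lam * w)).K_c == pytest.approx(
                lam * critical_coupling(table1_ensemble).K_c, rel=1e-14
            )

    def test_single_oscillator_rejected(self):
        with pytest.raises(ValueError, match="N >= 2"):
            critical_coupling(OscillatorEnsemble([1.0]))

    def test_nonfinite_frequency_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            OscillatorEnsemble([0.0, np.inf])


class TestOrderParameter:
    def test_identical_phases_fully_coherent(self):
        r, psi = order_parameter(np.full(5, 1.3))
        assert r == pytest.approx(1.0)
        assert psi == pytest.approx(1.3)

    def test_antipodal_pair_incoherent(self):
        r, psi = order_parameter(np.array([0.0, np.pi]))
        assert r == pytest.approx(0.0, abs=1e-12)
        assert psi == 0.0  # degenerate convention

    def test_quarter_turn_pair(self):
        r, psi = order_parameter(np.array([0.0, np.pi / 2]))
        assert r == pytest.approx(np.sqrt(2) / 2)
        assert psi == pytest.approx(np.pi / 4)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            order_parameter(np.array([]))

    def test_bounded_for_random_phase_sets(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            r, _ = order_parameter(rng.uniform(-np.pi, np.pi, rng.integers(1, 40)))
            assert 0.0 <= r <= 1.0


class TestLogisticSchedule:
    def test_fixed_point_at_carrying_capacity(self):
        sched = CouplingSchedule.logistic(a=0.1, C=75.0, K0=75.0)
        t = np.linspace(0, 1000, 11)
        assert logistic_closed_form(sched, t) == pytest.approx(75.0)

    def test_starts_at_initial_value(self):
        sched = CouplingSchedule.logistic(a=PAPER_A, C=PAPER_C, K0=1.0)
        assert logistic_closed_form(sched, 0.0) == pytest.approx(1.0)

    def test_strictly_increasing_below_capacity(self):
        sched = CouplingSchedule.logistic(a=PAPER_A, C=PAPER_C, K0=PAPER_K0)
        K = logistic_closed_form(sched, np.linspace(0, 5000, 2001))
        assert np.all(np.diff(K) > 0)
        assert K[-1] < PAPER_C

    def test_unit_initial_coupling_crosses_critical_value_near_1038(self):
        sched = CouplingSchedule.logistic(a=PAPER_A, C=PAPER_C, K0=1.0)
        t = coupling_crossing_time(sched, 69.02359)
        assert t == pytest.approx(1038.5, abs=0.5)

    def test_calibrated_initial_coupling_crosses_near_1800(self):
        sched = CouplingSchedule.logistic(a=PAPER_A, C=PAPER_C, K0=PAPER_K0)
        t = coupling_crossing_time(sched, 69.02359)
        assert t == pytest.approx(1800.0, abs=5.0)

    def test_crossing_time_vanishes_near_initial_value(self):
        sched = CouplingSchedule.logistic(a=PAPER_A, C=PAPER_C, K0=1.0)
        assert 0 < coupling_crossing_time(sched, 1.0 + 1e-9) < 1e-3

    @pytest.mark.parametrize("level", [10.0, 40.0, 74.9])
    def test_crossing_time_round_trip(self, level):
        sched = CouplingSchedule.logistic(a=PAPER_A, C=PAPER_C, K0=PAPER_K0)
        t = coupling_crossing_time(sched, level)
        assert logistic_closed_form(sched, t) == pytest.approx(level, abs=1e-9)

    @pytest.mark.parametrize("level", [0.001, 75.0, 100.0])
    def test_crossing_level_outside_range_rejected(self, level):
        sched = CouplingSchedule.logistic(a=PAPER_A, C=PAPER_C, K0=PAPER_K0)
        with pytest.raises(ValueError, match="level"):
            coupling_crossing_time(sched, level)

    def test_nonpositive_initial_coupling_rejected(self):
        with pytest.raises(ValueError, match="K0"):
            CouplingSchedule.logistic(a=PAPER_A, C=PAPER_C, K0=0.0)

    def test_closed_form_matches_co_integrated_ode(self):
        # independent route: integrate dK/dt = a*K*(1 - K/C) directly
        sched = CouplingSchedule.logistic(a=PAPER_A, C=PAPER_C, K0=PAPER_K0)
        t_eval = np.linspace(0.0, 2580.0, 259)
        sol = solve_ivp(
            lambda t, K: PAPER_A * K * (1.0 - K / PAPER_C),
            (0.0, 2580.0),
            [PAPER_K0],
            t_eval=t_eval,
            rtol=1e-12,
            atol=1e-14,
            method="DOP853",
        )
        assert sol.success
        closed = logistic_closed_form(sched, t_eval)
        assert np.max(np.abs(sol.y[0] - closed)) < 1e-8


class TestSimulate:
    def test_uncoupled_phases_advance_linearly(self):
        omega = np.array([0.3, 1.0, 2.5])
        result = simulate(
            OscillatorEnsemble(omega),
            CouplingSchedule.constant(0.0),
            SimulationConfig(t_end=10.0, output_rate=10.0),
        )
        assert result.phases[-1] == pytest.approx(10.0 * omega, abs=1e-6)

    def test_two_oscillator_steady_state_matches_closed_form(self):
        # dphi/dt = dw - K sin(phi) locks at phi* = arcsin(dw/K) = pi/6;
        # r = cos(phi*/2)
        result = simulate(
            OscillatorEnsemble([0.0, 1.0]),
            CouplingSchedule.constant(2.0),
            SimulationConfig(t_end=60.0, output_rate=10.0),
        )
        phi = result.phases[-1, 1] - result.phases[-1, 0]
        assert phi == pytest.approx(np.pi / 6, abs=1e-6)
        late_r = result.r[result.t > 40.0]
        assert late_r == pytest.approx(np.cos(np.pi / 12), abs=1e-3)

    def test_phase_sum_conserved(self):
        # pairwise sine antisymmetry: sum(theta_i(t)) = sum(theta_i(0)) + t*sum(omega)
        rng = np.random.default_rng(5)
        omega = rng.uniform(0.0, 3.0, 8)
        result = simulate(
            OscillatorEnsemble(omega),
            CouplingSchedule.constant(4.0),
            SimulationConfig(t_end=50.0, output_rate=2.0),
        )
        expected = result.t * omega.sum()
        actual = result.phases.sum(axis=1)
        scale = max(1.0, np.max(np.abs(expected)))
        assert np.max(np.abs(actual - expected)) / scale < 1e-5

    def test_order_parameter_bounded_along_trajectory(self, paper_run):
        assert np.all(paper_run.r >= 0.0)
        assert np.all(paper_run.r <= 1.0)
        assert np.all(np.diff(paper_run.t) > 0)
        assert np.all(paper_run.coupling > 0)
        assert np.all(paper_run.coupling <= PAPER_C)

    def test_rotating_frame_equivariance(self):
        rng = np.random.default_rng(11)
        omega = rng.uniform(0.0, 2.0, 6)
        config = SimulationConfig(t_end=30.0, output_rate=5.0, rtol=1e-11, atol=1e-11)
        sched = CouplingSchedule.constant(3.0)
        base = simulate(OscillatorEnsemble(omega), sched, config)
        c = 0.8
        shifted = simulate(OscillatorEnsemble(omega + c), sched, config)
        assert shifted.phases == pytest.approx(
            base.phases + c * base.t[:, None], abs=1e-6
        )
        assert shifted.r == pytest.approx(base.r, abs=1e-7)

    def test_time_frequency_scale_equivariance(self):
        rng = np.random.default_rng(13)
        omega = rng.uniform(0.5, 2.0, 5)
        lam = 3.0
        base = simulate(
            OscillatorEnsemble(omega),
            CouplingSchedule.constant(2.0),
            SimulationConfig(t_end=30.0, output_rate=4.0, rtol=1e-11, atol=1e-11),
        )
        scaled = simulate(
            OscillatorEnsemble(lam * omega),
            CouplingSchedule.constant(lam * 2.0),
            SimulationConfig(t_end=30.0 / lam, output_rate=4.0 * lam, rtol=1e-11, atol=1e-11),
        )
        assert scaled.phases == pytest.approx(base.phases, abs=1e-6)
        assert scaled.r == pytest.approx(base.r, abs=1e-7)

    def test_two_oscillator_locking_threshold_matches_formula(self):
        # simulate() locks iff K >= K_c: bracket the threshold within 1%
        ensemble = OscillatorEnsemble([0.0, 1.0])
        K_c = critical_coupling(ensemble).K_c

        def drifts(K):
            result = simulate(
                ensemble,
                CouplingSchedule.constant(K),
                SimulationConfig(t_end=400.0, output_rate=1.0),
            )
            phi = result.phases[:, 1] - result.phases[:, 0]
            # drifting: phase difference keeps growing through the second half
            return phi[-1] - phi[len(phi) // 2] > np.pi

        assert drifts(0.99 * K_c)
        assert not drifts(1.01 * K_c)

    def test_random_initial_phases_reproducible_and_in_range(self):
        config = SimulationConfig(t_end=1.0, initial_phases="random", seed=42)
        th1 = config.theta0(1000)
        th2 = config.theta0(1000)
        assert np.array_equal(th1, th2)
        assert np.all(th1 > -np.pi) and np.all(th1 <= np.pi)

    def test_refinement_stability_of_reference_run(
        self, table1_ensemble, paper_schedule, paper_run
    ):
        # halving tolerances must not move the final-window mean r
        tighter = simulate(
            table1_ensemble,
            paper_schedule,
            SimulationConfig(t_end=2580.0, output_rate=1.0, rtol=5e-9, atol=5e-9),
        )
        window = paper_run.t >= 2280.0
        assert np.mean(tighter.r[window]) == pytest.approx(
            np.mean(paper_run.r[window]), abs=1e-3
        )

    def test_nonpositive_horizon_rejected(self):
        with pytest.raises(ValueError, match="t_end"):
            SimulationConfig(t_end=0.0)


class TestClassifyLockedDrifting:
    def test_identical_frequencies_all_locked(self):
        labels = classify_locked_drifting(
            OscillatorEnsemble([2.0, 2.0, 2.0]), K=1.0, r=0.5
        )
        assert labels == ["locked"] * 3

    def test_pair_outside_entrainment_radius_drifts(self):
        labels = classify_locked_drifting(
            OscillatorEnsemble([0.0, 1.0]), K=0.8, r=0.5, Omega=0.5
        )
        assert labels == ["drifting", "drifting"]

    def test_reference_ensemble_has_one_drifting_gamma_oscillator(self, table1):
        # K*r = 60 around the mean frequency ~13.79: only the 119.93 Hz
        # gamma component falls outside, verified by direct enumeration
        w = table1.frequencies_hz
        Omega = w.mean()
        outside = np.abs(w - Omega) > 75.0 * 0.8
        assert outside.sum() == 1 and outside[-1]
        labels = classify_locked_drifting(
            OscillatorEnsemble(w), K=75.0, r=0.8, Omega=Omega
        )
        assert labels.count("drifting") == 1
        assert labels[-1] == "drifting"

    def test_invalid_coherence_rejected(self):
        with pytest.raises(ValueError, match="r must"):
            classify_locked_drifting(OscillatorEnsemble([0.0, 1.0]), K=1.0, r=0.0)
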