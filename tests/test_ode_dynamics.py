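"""Deterministic propagation, transient metrics and amplitude sweeps."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.linalg import expm

from phenomem import (
    CompartmentState,
    InvalidParameterError,
    ModelParams,
    Trajectory,
    amplitude_sweep,
    build_rate_matrix,
    calibrate_epsilon,
    equilibrium_on_fraction,
    integrate,
    integrate_schedule,
    spectral_summary,
    transient_metrics,
)
from phenomem.environments import (
    Season,
    EnvironmentSchedule,
    default_permissive_params,
    default_treatment_params,
    make_treatment_schedule,
)


class TestIntegrate:
    def test_matches_matrix_exponential_reference(self, symmetric_params,
                                                  all_off_start):
        traj = integrate(symmetric_params, all_off_start, t_end=7.3, dt_out=0.25)
        A = build_rate_matrix(symmetric_params)
        ref = expm(A * 7.3) @ all_off_start.abundances
        assert np.allclose(traj.states[-1], ref, rtol=1e-6)
        assert traj.times[-1] == pytest.approx(7.3)
        assert traj.times[0] == 0.0

    def test_without_switching_nothing_happens(self):
        p = ModelParams(n_on=1, mu=0.0, epsilon=0.7, birth=1.0, death=1.0)
        traj = integrate(p, CompartmentState.all_off(1, 100.0), t_end=5.0,
                         dt_out=0.5)
        assert np.allclose(traj.states[:, 0], 100.0)
        assert np.allclose(traj.fraction_on, 0.0)

    @pytest.mark.parametrize("n_on", [1, 4, 9])
    def test_long_run_growth_rate_is_b_minus_d(self, n_on):
        p = ModelParams(n_on=n_on, mu=0.2, epsilon=0.5, birth=1.0, death=0.98)
        traj = integrate(p, CompartmentState.all_off(n_on, 1000.0),
                         t_end=400.0, dt_out=1.0)
        N = traj.total_population
        g = np.log(N[-1] / N[0]) / 400.0
        assert g == pytest.approx(0.02, abs=1e-4)

    def test_fraction_converges_to_dominant_eigenvector(self, symmetric_params,
                                                        all_off_start):
        s = spectral_summary(symmetric_params)
        t_end = 50.0 / s.spectral_gap
        traj = integrate(symmetric_params, all_off_start, t_end=t_end, dt_out=0.5)
        assert traj.fraction_on[-1] == pytest.approx(
            s.equilibrium_on_fraction, abs=1e-4)

    @settings(deadline=None, max_examples=15, derandomize=True)
    @given(st.floats(0.1, 50.0))
    def test_linearity_in_initial_condition(self, c):
        p = ModelParams(n_on=3, mu=0.3, epsilon=0.4, birth=1.0, death=0.9)
        x0 = CompartmentState(time=0.0, abundances=[5.0, 1.0, 0.0, 2.0])
        xc = CompartmentState(time=0.0, abundances=c * x0.abundances)
        t1 = integrate(p, x0, t_end=4.0, dt_out=0.5)
        t2 = integrate(p, xc, t_end=4.0, dt_out=0.5)
        assert np.allclose(t2.states, c * t1.states, rtol=1e-10, atol=1e-12)

    def test_growth_identity_along_trajectory(self, symmetric_params,
                                              all_off_start):
        # d/dt log N = sum_i (b_i - d_i) x_i / N; symmetric => exactly b - d
        traj = integrate(symmetric_params, all_off_start, t_end=10.0, dt_out=0.01)
        logN = np.log(traj.total_population)
        dlogN = np.gradient(logN, traj.times)
        assert np.allclose(dlogN[2:-2], 0.02, atol=1e-4)

    def test_empty_initial_state_rejected(self, symmetric_params):
        with pytest.raises(InvalidParameterError):
            integrate(symmetric_params,
                      CompartmentState(time=0.0, abundances=np.zeros(5)),
                      t_end=1.0)

    def test_dimension_mismatch_rejected(self, symmetric_params):
        with pytest.raises(InvalidParameterError):
            integrate(symmetric_params, CompartmentState.all_off(2, 10.0),
                      t_end=1.0)

    def test_tsv_round_trip(self, tmp_path, symmetric_params, all_off_start):
        traj = integrate(symmetric_params, all_off_start, t_end=2.0, dt_out=0.5)
        path = tmp_path / "traj.tsv"
        traj.to_tsv(path)
        header = path.read_text().splitlines()[0]
        assert header == "time\tx_0\tx_1\tx_2\tx_3\tx_4\tN\tfraction_on"
        back = Trajectory.from_tsv(path)
        assert np.allclose(back.times, traj.times)
        assert np.allclose(back.states, traj.states)


class TestIntegrateSchedule:
    def test_single_permissive_season_is_pure_growth(self):
        sched = make_treatment_schedule(
            0.0, 0.0, 10.0, default_permissive_params(1),
            default_treatment_params(1))
        traj = integrate_schedule(sched, CompartmentState.all_off(1, 1000.0),
                                  dt_out=0.5)
        assert traj.total_population[-1] == pytest.approx(1000.0 * np.e**0.2,
                                                          rel=1e-9)

    def test_zero_length_treatment_matches_permissive_only(self):
        pp, tp = default_permissive_params(3), default_treatment_params(3)
        with_t = make_treatment_schedule(0.0, 4.0, 20.0, pp, tp)
        plain = EnvironmentSchedule((Season(20.0, "permissive", pp),))
        init = CompartmentState.all_off(3, 500.0)
        t1 = integrate_schedule(with_t, init, dt_out=0.5)
        t2 = integrate_schedule(plain, init, dt_out=0.5)
        assert np.allclose(t1.states, t2.states, rtol=1e-12)

    def test_state_continuous_at_boundaries(self):
        sched = make_treatment_schedule(5.0, 5.0, 20.0,
                                        default_permissive_params(2),
                                        default_treatment_params(2))
        traj = integrate_schedule(sched, CompartmentState.all_off(2, 1000.0),
                                  dt_out=0.25)
        # strictly increasing grid covering the full horizon, no jumps
        assert traj.times[0] == 0.0 and traj.times[-1] == pytest.approx(20.0)
        jumps = np.abs(np.diff(traj.total_population))
        assert jumps.max() < 50  # no teleports at season boundaries

    def test_mismatched_n_on_rejected(self):
        s1 = Season(5.0, "permissive", default_permissive_params(2))
        s2 = Season(5.0, "treatment", default_treatment_params(3))
        with pytest.raises(InvalidParameterError):
            integrate_schedule(EnvironmentSchedule((s1, s2)),
                               CompartmentState.all_off(2, 10.0))


class TestTransientMetrics:
    def test_single_compartment_is_monotone(self):
        p = ModelParams(n_on=1, mu=0.2, epsilon=0.5, birth=1.0, death=0.98)
        traj = integrate(p, CompartmentState.all_off(1, 1000.0), t_end=100.0,
                         dt_out=0.01)
        m = transient_metrics(traj, p)
        assert m.peak_to_peak == 0.0

    def test_overshoot_above_equilibrium_for_moderate_memory(self):
        p = ModelParams(n_on=4, mu=0.2, epsilon=0.5, birth=1.0, death=0.98)
        traj = integrate(p, CompartmentState.all_off(4, 1000.0), t_end=300.0,
                         dt_out=0.01)
        m = transient_metrics(traj, p)
        assert m.equilibrium_fraction == pytest.approx(0.8 / 1.3, abs=1e-12)
        assert m.overshoot_value > m.equilibrium_fraction
        assert m.peak_to_peak > 0
        assert not m.not_converged

    def test_start_at_equilibrium_is_flat(self, symmetric_params):
        eq = spectral_summary(symmetric_params).equilibrium_distribution
        init = CompartmentState(time=0.0, abundances=1000.0 * eq)
        traj = integrate(symmetric_params, init, t_end=50.0, dt_out=0.05)
        m = transient_metrics(traj, symmetric_params)
        assert m.peak_to_peak == 0.0

    def test_deep_memory_oscillates_at_least_once(self):
        # interior extremum appears by n_on = 10 at mu=0.2, eps=0.5
        p = ModelParams(n_on=10, mu=0.2, epsilon=0.5, birth=1.0, death=0.98)
        traj = integrate(p, CompartmentState.all_off(10, 1000.0), t_end=800.0,
                         dt_out=0.02)
        m = transient_metrics(traj, p)
        assert m.overshoot_value > 0 and not np.isnan(m.undershoot_value)
        assert m.peak_to_peak > 0

    def test_unconverged_trajectory_is_flagged(self, symmetric_params,
                                               all_off_start):
        short = integrate(symmetric_params, all_off_start, t_end=1.0, dt_out=0.01)
        assert transient_metrics(short, symmetric_params).not_converged


class TestAmplitudeSweep:
    def test_amplitude_increases_with_memory_at_fixed_equilibrium(self):
        tab = amplitude_sweep(0.2, 1.0, 0.98, n_grid=[5, 15, 25, 35],
                              target_equilibrium=0.8)
        assert np.allclose(tab["equilibrium_fraction"], 0.8, atol=1e-9)
        amps = tab["peak_to_peak"].to_numpy()
        assert np.all(np.diff(amps) > 0)

    def test_amplitude_compressed_near_full_on_equilibrium(self):
        # boundary effect: fraction_on cannot exceed 1
        lo = amplitude_sweep(0.2, 1.0, 1.0, n_grid=[12],
                             target_equilibrium=0.60)
        hi = amplitude_sweep(0.2, 1.0, 1.0, n_grid=[12],
                             target_equilibrium=0.97)
        assert hi["peak_to_peak"].iloc[0] < lo["peak_to_peak"].iloc[0]

    def test_single_point_sweep_matches_direct_metrics(self):
        p = ModelParams(n_on=8, mu=0.2, epsilon=0.5, birth=1.0, death=0.98)
        tab = amplitude_sweep(0.2, 1.0, 0.98, n_grid=[8], epsilon_fixed=0.5)
        from phenomem.ode_dynamics import _sweep_horizon

        traj = integrate(p, CompartmentState.all_off(8, 1000.0),
                         t_end=_sweep_horizon(p), dt_out=0.02)
        m = transient_metrics(traj, p)
        assert tab["peak_to_peak"].iloc[0] == pytest.approx(m.peak_to_peak,
                                                            rel=1e-9)

    def test_empty_sweep_rejected(self):
        with pytest.raises(InvalidParameterError):
            amplitude_sweep(0.2, 1.0, 1.0)
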