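"""Integration with extinction pruning, attractor extrema, Lyapunov
machinery (checked on closed-form systems) and dynamics classification."""

import numpy as np
import pytest

from mestweb.dynamics import (IntegrationOptions, TimeSeries,
                              attractor_extrema, classify_dynamics,
                              default_initial_state, distinct_extrema,
                              integrate, lyapunov_from_field, scan_options)
from mestweb.model import CommunityState, four_species_params


@pytest.fixture
def p():
    return four_species_params()


def make_series(times, values, params, var="F1"):
    """Wrap a scalar signal into a TimeSeries on the chosen variable."""
    states = np.zeros((times.size, params.dim))
    idx = params.variable_names().index(var)
    states[:, idx] = values
    return TimeSeries(times=times, states=states, params=params)


class TestIntegrate:
    def test_mutualist_relaxes_to_logistic_equilibrium(self, p):
        """With C, P and the exploiter absent, F0 follows the logistic
        closed form to (r0-d0)/alpha0."""
        s0 = CommunityState(F0=0.1, F=[0.0], C=0.0, P=0.0, theta=[0.5, 0.5])
        series = integrate(p, s0, 500.0, IntegrationOptions())
        assert series.final_state.F0 == pytest.approx(0.45 / 0.13, abs=1e-6)

    def test_extinction_face_is_absorbing(self, p):
        s0 = CommunityState(F0=1.0, F=[0.0], C=0.5, P=0.5, theta=[0.5, 0.2])
        series = integrate(p, s0, 300.0, IntegrationOptions())
        assert np.all(series.variable("F1") == 0.0)

    def test_nonnegativity_and_simplex_along_trajectory(self, p):
        s0 = default_initial_state(p)
        series = integrate(p, s0, 2000.0, scan_options())
        assert series.states.min() >= 0.0
        theta_sum = series.states[:, 4:].sum(axis=1)
        assert np.all(theta_sum <= 1.0 + 1e-8)

    def test_simplex_conserved_without_pruning(self, p):
        """Total foraging effort is a conserved quantity of the replicator
        flow: integrating the *extended* system with thetaC as an explicit
        replicator coordinate keeps theta0+theta1+thetaC = 1 to 1e-8, and
        matches the reduced (thetaC-derived) representation."""
        from scipy.integrate import solve_ivp
        from mestweb.model import rhs_vector

        def extended_rhs(t, y):
            x, thC = y[:-1], y[-1]
            dx = rhs_vector(x, p)
            w = np.array([p.u0 * x[0], p.ui[0] * x[1], p.uC * x[2]]) * p.eP
            wbar = x[4] * w[0] + x[5] * w[1] + thC * w[2]
            return np.concatenate([dx, [p.g * thC * (w[2] - wbar)]])

        s0 = CommunityState(F0=1.2, F=[0.7], C=0.8, P=0.84,
                            theta=[0.15, 0.32])
        y0 = np.concatenate([s0.to_vector(), [s0.thetaC]])
        sol = solve_ivp(extended_rhs, (0, 5000), y0, method="DOP853",
                        rtol=1e-10, atol=1e-13,
                        t_eval=np.arange(0, 5000, 5.0))
        total = sol.y[4] + sol.y[5] + sol.y[6]
        assert np.abs(total - 1.0).max() < 1e-8
        # short-horizon endpoint agreement between the two representations
        # (long horizons diverge through sensitive dependence)
        reduced = integrate(p, s0, 500.0, scan_options(sample_dt=5.0))
        i500 = int(np.argmin(np.abs(sol.t - 500.0)))
        np.testing.assert_allclose(reduced.states[-1][:6], sol.y[:6, i500],
                                   atol=1e-5)

    def test_pruning_records_extinction_events(self, p):
        # high mutualist abundance makes the exploiter's competition load
        # exceed its growth, so F1 declines through the threshold
        s0 = CommunityState(F0=3.2, F=[1e-4], C=0.0, P=0.0,
                            theta=[0.4, 0.3])
        series = integrate(p, s0, 500.0,
                           IntegrationOptions(extinction_threshold=1e-6))
        names = [n for n, _ in series.extinction_events]
        assert "F1" in names
        assert series.final_state.F[0] == 0.0

    def test_self_convergence_under_tighter_tolerances(self, p):
        """Halving the tolerances does not move the solution: F1 at
        t=1000 changes by < 1e-4 for the reference parameter set."""
        s0 = CommunityState(F0=1.2, F=[0.7], C=0.8, P=0.84,
                            theta=[0.15, 0.32])
        a = integrate(p, s0, 1000.0, scan_options(record=False))
        b = integrate(p, s0, 1000.0,
                      scan_options(rtol=1e-12, atol=1e-15, record=False))
        assert abs(a.states[-1][1] - b.states[-1][1]) < 1e-4

    def test_time_reversal_recovers_initial_state(self, p):
        """Short-horizon back-integration returns to the start before any
        pruning event (a consistency check of the integrator setup)."""
        from scipy.integrate import solve_ivp
        from mestweb.model import rhs_vector
        x0 = default_initial_state(p).to_vector()
        fwd = solve_ivp(lambda t, y: rhs_vector(y, p), (0, 50), x0,
                        method="DOP853", rtol=1e-11, atol=1e-13)
        back = solve_ivp(lambda t, y: -rhs_vector(y, p), (0, 50),
                         fwd.y[:, -1], method="DOP853", rtol=1e-11,
                         atol=1e-13)
        np.testing.assert_allclose(back.y[:, -1], x0, atol=1e-6)


class TestAttractorExtrema:
    def test_constant_series_is_fixed_point(self, p):
        t = np.linspace(0, 100, 500)
        ext = attractor_extrema(make_series(t, np.full_like(t, 0.7), p), "F1")
        assert ext["maxima"].size == 1
        assert ext["maxima"][0] == pytest.approx(0.7)

    def test_sinusoid_has_one_branch_each(self, p):
        t = np.linspace(0, 100, 5000)
        y = 1.0 + 0.3 * np.sin(t)
        ext = attractor_extrema(make_series(t, y, p), "F1")
        assert distinct_extrema(ext["maxima"]).size == 1
        assert distinct_extrema(ext["minima"]).size == 1
        assert ext["maxima"].max() == pytest.approx(1.3, abs=1e-3)

    def test_window_too_short_raises(self, p):
        t = np.linspace(0, 2, 20)
        y = np.sin(0.1 * t)
        with pytest.raises(ValueError):
            attractor_extrema(make_series(t, y, p), "F1", min_cycles=5)

    def test_distinct_extrema_clustering(self):
        vals = np.array([1.0, 1.0002, 1.5, 1.5003, 2.0])
        assert distinct_extrema(vals, tol=1e-3).size == 3


class TestLyapunovOnClosedForms:
    def test_pure_decay_has_exponent_minus_one(self):
        """dx/dt = -x: the only exponent is exactly -1."""
        f = lambda t, x: -x
        jac = lambda t, x: np.array([[-1.0]])
        spec = lyapunov_from_field(f, jac, np.array([1.0]), t_transient=5,
                                   t_total=200, renorm_dt=1.0)
        assert spec.leading == pytest.approx(-1.0, abs=0.01)

    def test_harmonic_oscillator_has_zero_leading_exponent(self):
        A = np.array([[0.0, 1.0], [-1.0, 0.0]])
        f = lambda t, x: A @ x
        jac = lambda t, x: A
        spec = lyapunov_from_field(f, jac, np.array([1.0, 0.0]),
                                   t_transient=0, t_total=500, renorm_dt=1.0)
        assert abs(spec.leading) < 0.01
        # rotation is volume preserving: the two exponents cancel
        assert abs(spec.exponents.sum()) < 0.01

    def test_saddle_spectrum(self):
        """Diagonal linear system: exponents are the diagonal rates,
        sorted descending."""
        A = np.diag([0.3, -0.7])
        f = lambda t, x: A @ x
        jac = lambda t, x: A
        # start on the stable manifold so the base orbit stays bounded;
        # the tangent flow still explores both eigendirections
        spec = lyapunov_from_field(f, jac, np.array([0.0, 1.0]),
                                   t_transient=0, t_total=500,
                                   renorm_dt=0.5, bound=1e12)
        np.testing.assert_allclose(spec.exponents, [0.3, -0.7], atol=0.01)

    def test_unbounded_trajectory_raises(self):
        f = lambda t, x: x
        jac = lambda t, x: np.array([[1.0]])
        with pytest.raises(RuntimeError, match="unbounded"):
            lyapunov_from_field(f, jac, np.array([1.0]), t_transient=0,
                                t_total=100, renorm_dt=1.0, bound=1e3)


class TestClassification:
    def _spec(self, le):
        from mestweb.dynamics import LyapunovSpectrum
        return LyapunovSpectrum(exponents=np.array([le]),
                                trace=np.zeros((1, 1)),
                                leading_ci=(le - 1e-4, le + 1e-4), dim_used=1)

    def test_fixed_point(self):
        ext = {"maxima": np.array([1.0]), "minima": np.array([1.0])}
        assert classify_dynamics(ext, self._spec(-0.1)) == "fixed_point"

    def test_single_branch_is_periodic(self):
        ext = {"maxima": np.array([1.3, 1.3001]),
               "minima": np.array([0.7, 0.7001])}
        assert classify_dynamics(ext, self._spec(-0.01)) == "periodic"

    def test_two_branches_is_period_doubled(self):
        ext = {"maxima": np.array([1.3, 1.1, 1.3, 1.1]),
               "minima": np.array([0.7, 0.6])}
        assert classify_dynamics(ext, self._spec(0.0)) == "period_doubled"

    def test_positive_exponent_is_chaotic(self):
        ext = {"maxima": np.linspace(1.0, 1.4, 17),
               "minima": np.linspace(0.4, 0.7, 17)}
        assert classify_dynamics(ext, self._spec(0.02)) == "chaotic"

    def test_contradictory_inputs_flagged(self):
        ext = {"maxima": np.array([1.0]), "minima": np.array([1.0])}
        assert classify_dynamics(ext, self._spec(0.02)) == "unresolved"
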