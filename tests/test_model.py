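"""Vector-field contracts: term-by-term oracle, replicator identities,
invariant faces and the analytic Jacobian."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mestweb.model import (CommunityState, ModelParams, four_species_params,
                           fitness_gradients, predator_fitness, rhs,
                           rhs_jacobian, rhs_vector)
from conftest import random_state


def oracle_rhs(state: CommunityState, p: ModelParams) -> np.ndarray:
    """Independent term-by-term evaluation of the model equations,
    written scalar-by-scalar from the labelled interaction terms
    (growth, competition, predation, mortality, replicator)."""
    n = p.n
    F0, F, C, P = state.F0, state.F, state.C, state.P
    th = state.theta
    thC = 1.0 - th.sum()

    growth0 = p.r0
    dd0 = p.alpha0 * F0
    comp0 = sum(p.beta[i + 1, 0] * F[i] for i in range(n))
    byC = p.aC * C
    byP0 = th[0] * p.u0 * P
    dF0 = F0 * (growth0 - dd0 - comp0 - byC - byP0 - p.d0)

    dF = np.zeros(n)
    for i in range(n):
        cap = max(F0, 1e-12) / p.q
        mut_growth = p.ri[i] * F[i] * (1.0 - F[i] / cap)
        comp = 0.0
        for j in range(n + 1):
            if j == i + 1:
                continue
            Fj = F0 if j == 0 else F[j - 1]
            comp += p.beta[j, i + 1] * Fj * F[i]
        byP = th[i + 1] * p.ui[i] * F[i] * P
        dF[i] = mut_growth - comp - byP - p.di[i] * F[i]

    dC = C * (p.eC * p.aC * F0 - thC * p.uC * P - p.dC - p.alphaC * C)

    WP = (p.eP * sum(th[k] * ([p.u0] + list(p.ui))[k] * ([F0] + list(F))[k]
                     for k in range(n + 1))
          + p.eP * thC * p.uC * C - p.dP - p.alphaP * P)
    dP = P * WP

    w = [p.eP * p.u0 * F0] + [p.eP * p.ui[i] * F[i] for i in range(n)]
    wC = p.eP * p.uC * C
    wbar = sum(th[k] * w[k] for k in range(n + 1)) + thC * wC
    dth = np.array([p.g * th[j] * (w[j] - wbar) for j in range(n + 1)])

    return np.concatenate([[dF0], dF, [dC, dP], dth])


class TestRhs:
    def test_mutualist_alone_is_logistic(self, fig2_params):
        s = CommunityState(F0=2.0, F=[0.0], C=0.0, P=0.0, theta=[0.5, 0.3])
        d = rhs(s, fig2_params)
        p = fig2_params
        assert d.F0 == pytest.approx(2.0 * (p.r0 - p.alpha0 * 2.0 - p.d0))
        assert np.all(d.F == 0) and d.C == 0 and d.P == 0

    def test_total_extinction_is_a_fixed_point(self, fig2_params):
        s = CommunityState(F0=0.0, F=[0.0], C=0.0, P=0.0, theta=[0.5, 0.5])
        d = rhs(s, fig2_params).to_vector()
        assert np.all(d[:4] == 0)

    @pytest.mark.parametrize("n", [1, 3, 7])
    def test_matches_term_by_term_oracle(self, rng, n):
        p = ModelParams(n=n, ri=rng.uniform(0.3, 0.4, n), beta=0.12, g=0.3)
        for _ in range(350):
            s = random_state(rng, n)
            got = rhs_vector(s.to_vector(), p)
            want = oracle_rhs(s, p)
            np.testing.assert_allclose(got, want, atol=1e-12)

    def test_dimension_mismatch_raises(self, fig2_params):
        s = CommunityState(F0=1.0, F=[1.0, 1.0], C=1.0, P=1.0,
                           theta=[0.2, 0.2, 0.2])
        with pytest.raises(ValueError, match="exploiters"):
            rhs(s, fig2_params)

    def test_negative_biomass_rejected(self, fig2_params):
        s = CommunityState(F0=-0.1, F=[1.0], C=1.0, P=1.0, theta=[0.2, 0.2])
        with pytest.raises(ValueError, match="nonnegative"):
            rhs(s, fig2_params)


class TestPredatorFitness:
    def test_starvation_value(self, fig2_params):
        s = CommunityState(F0=0, F=[0.0], C=0, P=0, theta=[0.3, 0.3])
        assert predator_fitness(s, fig2_params) == pytest.approx(-0.05)

    def test_hand_value_on_mutualist_diet(self, fig2_params):
        # theta = (1, 0), F0 = 1: W_P = eP*u0*1 - dP = 0.11 - 0.05
        s = CommunityState(F0=1.0, F=[0.0], C=0.0, P=0.0, theta=[1.0, 0.0])
        assert predator_fitness(s, fig2_params) == pytest.approx(0.06)

    def test_dP_identity(self, fig2_params, rng):
        for _ in range(100):
            s = random_state(rng)
            d = rhs(s, fig2_params)
            assert d.P == pytest.approx(s.P * predator_fitness(s, fig2_params),
                                        abs=1e-12)


class TestReplicator:
    def test_gradients_vanish_at_extinction(self, fig2_params):
        s = CommunityState(F0=0, F=[0.0], C=0, P=1.0, theta=[0.3, 0.3])
        assert np.all(fitness_gradients(s, fig2_params) == 0)

    def test_equal_gradients_freeze_efforts(self):
        # engineer w0 = w1 = wC: u0*F0 = u1*F1 = uC*C
        p = four_species_params(u1=0.15)
        F0, F1 = 1.5, 0.11 * 1.5 / 0.15
        C = 0.11 * 1.5 / 0.2
        s = CommunityState(F0=F0, F=[F1], C=C, P=0.7, theta=[0.25, 0.45])
        d = rhs(s, p)
        np.testing.assert_allclose(d.theta, 0.0, atol=1e-14)

    def test_hand_replicator_arithmetic(self):
        # w = (1, 0, 0) across (F0, F1, C); theta=(0.5, 0.5), g=1
        # dtheta0 = 1*0.5*(1 - 0.5) = 0.25, dtheta1 = -0.25
        p = four_species_params(u1=0.3, g=1.0).replace(u0=1.0, uC=0.2)
        s = CommunityState(F0=1.0, F=[0.0], C=0.0, P=0.0, theta=[0.5, 0.5])
        d = rhs(s, p)
        assert d.theta[0] == pytest.approx(0.25)
        assert d.theta[1] == pytest.approx(-0.25)

    def test_simplex_derivative_sums_to_zero_with_C(self, fig2_params, rng):
        """The full-simplex replicator conserves total effort: the implied
        d(thetaC)/dt = g*thetaC*(wC - wbar) is minus the sum of the
        stored effort derivatives."""
        p = fig2_params
        for _ in range(50):
            s = random_state(rng)
            d = rhs(s, p)
            w = fitness_gradients(s, p)
            thC = s.thetaC
            wbar = s.theta @ w[:-1] + thC * w[-1]
            dthC = p.g * thC * (w[-1] - wbar)
            assert d.theta.sum() + dthC == pytest.approx(0.0, abs=1e-12)


class TestReductions:
    def test_g_zero_freezes_preferences(self, rng):
        p = four_species_params(g=0.0)
        for _ in range(20):
            s = random_state(rng)
            assert np.all(rhs(s, p).theta == 0)

    def test_q_zero_decouples_exploiters_from_mutualist(self, rng):
        """q -> 0 removes the mutualistic dependence: the exploiter growth
        term becomes ri*Fi regardless of F0."""
        p = four_species_params(q=0.0, beta=0.0)
        s1 = CommunityState(F0=0.5, F=[0.8], C=0.0, P=0.0, theta=[0.5, 0.0])
        s2 = CommunityState(F0=2.5, F=[0.8], C=0.0, P=0.0, theta=[0.5, 0.0])
        d1, d2 = rhs(s1, p), rhs(s2, p)
        assert d1.F[0] == pytest.approx(d2.F[0])
        assert d1.F[0] == pytest.approx(0.8 * (p.ri[0] - p.di[0]))

    def test_invariant_faces(self, fig2_params, rng):
        """Derivatives vanish on every extinction face {x_i = 0}."""
        p = fig2_params
        for idx in range(6):
            s = random_state(rng)
            x = s.to_vector()
            x[idx] = 0.0
            assert rhs_vector(x, p)[idx] == 0.0


class TestJacobian:
    @pytest.mark.parametrize("n", [1, 4])
    def test_matches_central_differences(self, rng, n):
        p = ModelParams(n=n, ri=rng.uniform(0.3, 0.4, n), beta=0.15, g=0.28)
        h = 1e-6
        for _ in range(30):
            x = random_state(rng, n).to_vector()
            J = rhs_jacobian(x, p)
            Jfd = np.zeros_like(J)
            for k in range(x.size):
                e = np.zeros(x.size)
                e[k] = h
                Jfd[:, k] = (rhs_vector(x + e, p) - rhs_vector(x - e, p)) / (2 * h)
            np.testing.assert_allclose(J, Jfd, atol=5e-7)

    def test_exploiter_exchange_symmetry(self, rng):
        """With two identical exploiters, swapping them permutes the
        Jacobian spectrum (it is invariant as a set)."""
        p = ModelParams(n=2, ri=[0.35, 0.35], beta=0.1, g=0.28)
        b = rng.uniform(0.2, 2.0, 2)
        x = np.array([1.0, b[0], b[1], 0.7, 0.5, 0.2, 0.15, 0.15])
        xs = np.array([1.0, b[1], b[0], 0.7, 0.5, 0.2, 0.15, 0.15])
        lam = np.sort_complex(np.linalg.eigvals(rhs_jacobian(x, p)))
        lam_s = np.sort_complex(np.linalg.eigvals(rhs_jacobian(xs, p)))
        np.testing.assert_allclose(lam, lam_s, atol=1e-10)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.floats(0.01, 3.0), st.floats(0.01, 3.0), st.floats(0.01, 3.0),
       st.floats(0.01, 3.0), st.floats(0.01, 0.98))
def test_field_is_finite_on_valid_states(F0, F1, C, P, t0):
    """Any state satisfying the invariants yields finite derivatives."""
    p = four_species_params()
    t1 = (1.0 - t0) * 0.5
    s = CommunityState(F0=F0, F=[F1], C=C, P=P, theta=[t0, t1])
    assert np.all(np.isfinite(rhs(s, p).to_vector()))
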