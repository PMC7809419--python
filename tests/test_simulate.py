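"""Three-timescale integration, QSS reduction and equilibrium-input
solving, checked against closed forms and independent solvers."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.optimize import lsq_linear

from triscale.kinetics import CompiledNetwork, StateVectors
from triscale.network import build_toy_network
from triscale.simulate import (
    CustomSystem,
    IntegrationError,
    QSSInfeasibleError,
    TimescaleConfig,
    Trajectory,
    integrate,
    qss_fast,
    qss_ultrafast,
    reduced_slow_derivative,
    solve_equilibrium_input,
    write_trajectory_csv,
)

W = 1.0 / 60.0


def _linear_cascade():
    """x frozen; y relaxes to x; z relaxes to y."""
    return CustomSystem(
        p=1, s=1, m=1, c=1,
        f=lambda x, y, z, u: np.array([0.0]),
        g=lambda x, y, z, u: x - y,
        h=lambda x, y, z, u: y - z,
    )


class TestIntegrate:
    def test_cascade_reaches_fixed_point(self):
        sysm = _linear_cascade()
        cfg = TimescaleConfig(t_grid=np.linspace(0, 2, 21))
        traj = integrate(sysm, StateVectors([0.3], [0.9], [0.1], [0.0]),
                         np.array([0.0]), cfg)
        assert traj.Y[-1] == pytest.approx([0.3], abs=1e-6)
        assert traj.Z[-1] == pytest.approx([0.3], abs=1e-6)

    def test_unit_ratios_match_reference_adaptive_solver(self, toy_spec):
        """At w1 = w2 = 1 the model is an ordinary ODE; our integrator must
        agree with an independent high-order solve to 1e-8."""
        comp = CompiledNetwork(toy_spec)
        rng = np.random.default_rng(0)
        init = StateVectors(rng.uniform(0.3, 0.7, toy_spec.p),
                            rng.uniform(0.3, 0.7, toy_spec.s),
                            rng.uniform(0.3, 0.7, toy_spec.m),
                            rng.uniform(0.3, 0.7, toy_spec.c))
        t_grid = np.linspace(0, 1.0, 5)
        cfg = TimescaleConfig(w1=1.0, w2=1.0, t_grid=t_grid,
                              rel_tol=1e-11, abs_tol=1e-12, clamp=False)
        traj = integrate(comp, init, init.u, cfg)
        rhs = comp.rhs(1.0, 1.0, lambda t: init.u, clip=False)
        ref = solve_ivp(rhs, (0, 1.0), np.concatenate([init.x, init.y, init.z]),
                        method="DOP853", rtol=1e-12, atol=1e-13, t_eval=t_grid)
        np.testing.assert_allclose(
            np.hstack([traj.X, traj.Y, traj.Z]), ref.y.T, atol=1e-8)

    def test_modes_agree_on_toy_fixture(self):
        sysm = _linear_cascade()
        init = StateVectors([0.3], [0.5], [0.2], [0.0])
        t_grid = np.linspace(0, 1, 6)
        kw = dict(w1=0.25, w2=0.25, t_grid=t_grid, rel_tol=1e-8, abs_tol=1e-10)
        direct = integrate(sysm, init, np.array([0.0]),
                           TimescaleConfig(integration_mode="direct_stiff", **kw))
        nested = integrate(sysm, init, np.array([0.0]),
                           TimescaleConfig(integration_mode="nested_multirate", **kw))
        diff = np.max(np.abs(direct.species_matrix() - nested.species_matrix()))
        assert diff <= 10 * 1e-4  # nested RK4 cascade at dt*w1*w2 resolution

    def test_seed_free_determinism(self, toy_spec):
        comp = CompiledNetwork(toy_spec)
        init = StateVectors(np.full(toy_spec.p, 0.5), np.full(toy_spec.s, 0.5),
                            np.full(toy_spec.m, 0.5), np.full(toy_spec.c, 0.5))
        cfg = TimescaleConfig(t_grid=np.linspace(0, 2, 11))
        a = integrate(comp, init, init.u, cfg)
        b = integrate(comp, init, init.u, cfg)
        np.testing.assert_array_equal(a.species_matrix(), b.species_matrix())

    def test_invalid_grid_rejected(self):
        with pytest.raises(ValueError, match="t_grid"):
            TimescaleConfig(t_grid=np.array([0.0]))
        with pytest.raises(ValueError, match="ratios"):
            TimescaleConfig(w1=0.0)


class TestQSS:
    def test_fast_closed_form_identity(self):
        sysm = CustomSystem(1, 1, 1, 1,
                            f=lambda x, y, z, u: np.array([0.0]),
                            g=lambda x, y, z, u: x - y,
                            h=lambda x, y, z, u: y - z)
        y = qss_fast(sysm, np.array([0.25]), np.array([0.0]))
        assert y == pytest.approx([0.25], abs=1e-9)

    def test_fast_root_matches_bisection_oracle(self):
        """g^ = x*u - y^2 with x=0.25, u=1: root y* = 0.5 (bisection)."""
        sysm = CustomSystem(1, 1, 1, 1,
                            f=lambda x, y, z, u: np.array([0.0]),
                            g=lambda x, y, z, u: x * u - y ** 2,
                            h=lambda x, y, z, u: u - z)

        def g_scalar(yv):
            return 0.25 * 1.0 - yv ** 2

        lo, hi = 0.0, 1.0
        for _ in range(60):
            mid = (lo + hi) / 2
            if g_scalar(lo) * g_scalar(mid) <= 0:
                hi = mid
            else:
                lo = mid
        oracle = (lo + hi) / 2
        y = qss_fast(sysm, np.array([0.25]), np.array([1.0]))
        assert y == pytest.approx([oracle], abs=1e-8)

    def test_ultrafast_michaelis_balance(self):
        """Saturating consumption z/(1+z) balancing constant inflow 0.2:
        z* = 0.25."""
        sysm = CustomSystem(1, 1, 1, 1,
                            f=lambda x, y, z, u: np.array([0.0]),
                            g=lambda x, y, z, u: -y,
                            h=lambda x, y, z, u: 0.2 - z / (1.0 + z))
        z = qss_ultrafast(sysm, np.array([1.0]), np.array([0.0]), np.array([0.0]))
        assert z == pytest.approx([0.25], abs=1e-8)

    def test_ultrafast_linear_identity(self):
        sysm = CustomSystem(1, 1, 1, 1,
                            f=lambda x, y, z, u: np.array([0.0]),
                            g=lambda x, y, z, u: -y,
                            h=lambda x, y, z, u: u - z)
        z = qss_ultrafast(sysm, np.array([0.0]), np.array([0.0]), np.array([0.7]))
        assert z == pytest.approx([0.7], abs=1e-9)

    def test_residuals_below_tolerance_on_random_instances(self):
        """Returned QSS roots satisfy their defining residuals to 1e-8 on
        100 random toy systems with known interior equilibria."""
        rng = np.random.default_rng(10)
        for _ in range(100):
            a, b = rng.uniform(0.2, 0.9, 2)
            sysm = CustomSystem(
                1, 1, 1, 1,
                f=lambda x, y, z, u: np.array([0.0]),
                g=lambda x, y, z, u, a=a: a * x * u - y,
                h=lambda x, y, z, u, b=b: b * y - z,
            )
            x = rng.uniform(0.1, 0.9, 1)
            u = rng.uniform(0.1, 0.9, 1)
            y = qss_fast(sysm, x, u)
            z = qss_ultrafast(sysm, x, y, u)
            assert np.max(np.abs(sysm.g(x, y, z, u))) <= 1e-8
            assert np.max(np.abs(sysm.h(x, y, z, u))) <= 1e-8

    def test_infeasible_root_raises(self):
        sysm = CustomSystem(1, 1, 1, 1,
                            f=lambda x, y, z, u: np.array([0.0]),
                            g=lambda x, y, z, u: np.array([1.0]),  # no root
                            h=lambda x, y, z, u: -z)
        with pytest.raises(QSSInfeasibleError):
            qss_fast(sysm, np.array([0.5]), np.array([0.5]))

    def test_full_trajectory_tracks_ultrafast_qss(self):
        """After burn-in |z(t) - H'(x, y, u)| <= 5*w2 on the linear toy."""
        sysm = _linear_cascade()
        cfg = TimescaleConfig(t_grid=np.linspace(0, 2, 21))
        traj = integrate(sysm, StateVectors([0.3], [0.9], [0.1], [0.0]),
                         np.array([0.0]), cfg)
        for i in range(10, len(traj)):
            zstar = qss_ultrafast(sysm, traj.X[i], traj.Y[i], traj.U[i])
            assert np.max(np.abs(traj.Z[i] - zstar)) <= 5 * cfg.w2


class TestReducedModel:
    @staticmethod
    def _nonlinear_system(a=0.6, b=0.8):
        # closed forms: G(x, u) = a*x*u, H(x, u) = b*G
        return CustomSystem(
            1, 1, 1, 1,
            f=lambda x, y, z, u: 0.3 * y + 0.2 * z - 0.4 * x,
            g=lambda x, y, z, u: a * x * u - y,
            h=lambda x, y, z, u: b * y - z,
        )

    def test_reduced_derivative_matches_hand_substitution(self):
        sysm = self._nonlinear_system()
        x, u = np.array([0.5]), np.array([0.8])
        G = 0.6 * x * u
        H = 0.8 * G
        expected = 0.3 * G + 0.2 * H - 0.4 * x
        got = reduced_slow_derivative(sysm, x, u)
        assert got == pytest.approx(expected, abs=1e-7)

    def test_reduction_error_shrinks_with_timescale_ratio(self):
        """|x_full - x_reduced| at the horizon decreases over
        w in {1/4, 1/16, 1/60}."""
        sysm = self._nonlinear_system()
        x0, u = np.array([0.5]), np.array([0.8])
        horizon = 2.0

        # reference: reduced slow model integrated accurately
        def reduced_rhs(t, x):
            return reduced_slow_derivative(sysm, x, u)

        ref = solve_ivp(reduced_rhs, (0, horizon), x0, rtol=1e-10, atol=1e-12)
        x_red = ref.y[:, -1]

        errors = []
        for w in (1 / 4, 1 / 16, 1 / 60):
            cfg = TimescaleConfig(w1=w, w2=w, t_grid=np.linspace(0, horizon, 11),
                                  rel_tol=1e-9, abs_tol=1e-11)
            traj = integrate(sysm, StateVectors(x0, [0.2], [0.9], u), u, cfg)
            errors.append(abs(traj.X[-1, 0] - x_red[0]))
        assert errors[0] > errors[1] > errors[2]
        assert errors[2] <= 0.05


class TestEquilibriumInput:
    def test_scalar_linear_root(self):
        sysm = CustomSystem(1, 1, 1, 1,
                            f=lambda x, y, z, u: np.array([0.0]),
                            g=lambda x, y, z, u: np.array([0.0]),
                            h=lambda x, y, z, u: u - z)
        st = StateVectors([0.5], [0.5], [0.3], [0.9])
        u, exact = solve_equilibrium_input(sysm, st)
        assert exact
        assert u == pytest.approx([0.3], abs=1e-6)

    def test_two_input_linear_matches_least_squares_oracle(self):
        A = np.array([[0.7, 0.2], [0.1, 0.5], [0.3, 0.3]])
        b = np.array([0.30, 0.25, 0.20])
        sysm = CustomSystem(1, 1, 3, 2,
                            f=lambda x, y, z, u: np.array([0.0]),
                            g=lambda x, y, z, u: np.array([0.0]),
                            h=lambda x, y, z, u: A @ u - b)
        st = StateVectors([0.5], [0.5], [0.2, 0.2, 0.2], [0.5, 0.5])
        u, _ = solve_equilibrium_input(sysm, st, max_nfev=200)
        oracle = lsq_linear(A, b, bounds=(0, 1)).x
        assert u == pytest.approx(oracle, abs=1e-5)

    def test_beats_random_restarts(self, toy_spec):
        comp = CompiledNetwork(toy_spec)
        rng = np.random.default_rng(2)
        st = StateVectors(rng.uniform(0.2, 0.8, toy_spec.p),
                          rng.uniform(0.2, 0.8, toy_spec.s),
                          rng.uniform(0.2, 0.8, toy_spec.m),
                          rng.uniform(0.2, 0.8, toy_spec.c))

        def resid_norm(u):
            d = comp.derivative(st.x, st.y, st.z, u, 1.0, 1.0)
            return np.linalg.norm(np.concatenate(d))

        u, _ = solve_equilibrium_input(comp, st, max_nfev=200)
        best = resid_norm(u)
        for _ in range(100):
            assert best <= resid_norm(rng.uniform(0, 1, toy_spec.c)) + 1e-12


def test_trajectory_csv_has_canonical_header(tmp_path, toy_spec):
    comp = CompiledNetwork(toy_spec)
    init = StateVectors(np.full(toy_spec.p, 0.5), np.full(toy_spec.s, 0.5),
                        np.full(toy_spec.m, 0.5), np.full(toy_spec.c, 0.5))
    traj = integrate(comp, init, init.u, TimescaleConfig(t_grid=np.linspace(0, 1, 3)))
    path = write_trajectory_csv(traj, toy_spec, tmp_path / "traj.csv")
    header = path.read_text().splitlines()[0].split(",")
    assert header[0] == "time"
    assert header[1:1 + toy_spec.p + toy_spec.s + toy_spec.m] == toy_spec.species_names()
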