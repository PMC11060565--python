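"""Physics oracles for the 1D finite-difference solver.

The checks compare the scheme against independent references: the analytic
small-amplitude wave speed, Richardson refinement for the convergence order,
and a generic multivariate root-finder for the bifurcation closure.
"""

import math

import numpy as np
import pytest
from scipy.optimize import root

import pulsevol as pv
from pulsevol import _kernel as K
from pulsevol.arterial_tree import VesselSegment
from pulsevol.pulse_wave_solver import SolverConfig, make_grid


def uniform_segment(L=40.0, r=0.4):
    return VesselSegment(id=1, name="straight", L=L, r_in=r, r_out=r)


def right_moving_bump(grid, wall, eps=0.002, x0=10.0, width=2.0):
    """Small-amplitude simple wave: W- uniform, so the bump moves only +x."""
    A0, c0 = grid.A0n, grid.wave_speeds()
    A = A0 * (1.0 + eps * np.exp(-((grid.x - x0) / width) ** 2))
    c = np.sqrt(0.5 * grid.fn / wall.rho * np.sqrt(A0 / A))
    u = 4.0 * (c0 - c)
    grid.A = A
    grid.Q = A * u
    return grid


class TestRestState:
    def test_uniform_rest_is_machine_fixed_point(self, wall):
        grid = make_grid(uniform_segment(), wall, SolverConfig(dx_target=0.5))
        cfg = SolverConfig(dx_target=0.5, dt=2e-4)
        g = grid
        for _ in range(50):
            g = pv.lax_wendroff_step(g, cfg, wall)
        assert np.array_equal(g.A, grid.A0n)
        assert np.array_equal(g.Q, np.zeros(g.n))

    def test_tapered_rest_stays_at_equilibrium(self, wall):
        # the geometric source balances the flux gradient: residual motion
        # after many steps stays at discretization (not O(1)) level
        seg = VesselSegment(id=1, name="taper", L=20.0, r_in=0.5, r_out=0.3)
        grid = make_grid(seg, wall, SolverConfig(dx_target=0.25))
        cfg = SolverConfig(dx_target=0.25, dt=5e-5)
        g = grid
        for _ in range(200):
            g = pv.lax_wendroff_step(g, cfg, wall)
        u = np.abs(g.Q / g.A)
        assert np.max(u) < 0.05  # cm/s; physiological flows are O(10-100)

    def test_flux_and_source_rest_equilibrium(self, wall):
        seg = uniform_segment()
        (_, Fq_a), (Sa, Sq) = pv.flux_and_source(0.3, 0.0, seg, 5.0, wall)
        (_, Fq_b), _ = pv.flux_and_source(0.3, 0.0, seg, 15.0, wall)
        assert Sa == 0.0
        assert Sq == pytest.approx(0.0, abs=1e-12)
        assert Fq_a == pytest.approx(Fq_b)  # no flux gradient at rest

    def test_friction_is_linear_in_flow(self, wall):
        seg = uniform_segment()
        A = float(np.pi * 0.4**2)
        (_, _), (_, s1) = pv.flux_and_source(A, 10.0, seg, 5.0, wall)
        (_, _), (_, s2) = pv.flux_and_source(A, 20.0, seg, 5.0, wall)
        assert s2 == pytest.approx(2.0 * s1)
        assert s1 == pytest.approx(-8.0 * np.pi * wall.nu * 10.0 / A)


class TestPulsePropagation:
    def test_small_pulse_speed_matches_analytic(self, wall):
        seg = uniform_segment(L=40.0, r=0.4)
        cfg = SolverConfig(dx_target=0.05)
        grid = right_moving_bump(make_grid(seg, wall, cfg), wall)
        c0 = float(grid.wave_speeds()[0])
        dt = 0.4 * grid.dx / c0
        step_cfg = SolverConfig(dx_target=0.05, dt=dt)

        def peak_x(g):
            i = int(np.argmax(g.A))
            y0, y1, y2 = g.A[i - 1], g.A[i], g.A[i + 1]
            return g.x[i] + 0.5 * g.dx * (y0 - y2) / (y0 - 2 * y1 + y2)

        n_steps = 400
        x_start = peak_x(grid)
        g = grid
        for _ in range(n_steps):
            g = pv.lax_wendroff_step(g, step_cfg, wall)
        speed = (peak_x(g) - x_start) / (n_steps * dt)
        assert speed == pytest.approx(c0, rel=0.05)

    def test_observed_convergence_order_is_two(self, wall):
        seg = uniform_segment(L=40.0, r=0.4)
        t_end = 8.0e-3
        sols = {}
        for k, dx in enumerate([0.2, 0.1, 0.05]):
            cfg = SolverConfig(dx_target=dx)
            g = right_moving_bump(make_grid(seg, wall, cfg), wall,
                                  eps=0.004, x0=15.0, width=3.0)
            c0 = float(g.wave_speeds()[0])
            n = 80 * 2**k
            step = SolverConfig(dx_target=dx, dt=t_end / n)
            assert step.dt < 0.5 * dx / c0
            for _ in range(n):
                g = pv.lax_wendroff_step(g, step, wall)
            sols[dx] = g
        # restrict to common nodes (every 2nd/4th point)
        a_c = sols[0.2].A
        a_m = sols[0.1].A[::2]
        a_f = sols[0.05].A[::4]
        e_cm = np.linalg.norm(a_c - a_m)
        e_mf = np.linalg.norm(a_m - a_f)
        order = math.log2(e_cm / e_mf)
        assert 1.7 < order < 2.4


class TestJunction:
    def _setup(self, wall):
        cfg = SolverConfig(dx_target=0.25)
        parent = make_grid(VesselSegment(id=1, name="p", L=10, r_in=0.45,
                                         r_out=0.42), wall, cfg)
        d1 = make_grid(VesselSegment(id=2, name="d1", L=10, r_in=0.33,
                                     r_out=0.30), wall, cfg)
        d2 = make_grid(VesselSegment(id=3, name="d2", L=10, r_in=0.28,
                                     r_out=0.25), wall, cfg)
        # perturbed, flowing state
        for g, amp, q in ((parent, 1.03, 40.0), (d1, 1.01, 25.0), (d2, 1.005, 15.0)):
            g.A = g.A0n * (amp + 0.01 * np.sin(g.x / g.seg.L * np.pi))
            g.Q = np.full(g.n, q) + 2.0 * np.cos(g.x / g.seg.L * np.pi)
        return parent, d1, d2, cfg

    def test_symmetric_daughters_split_evenly(self, wall):
        cfg = SolverConfig(dx_target=0.25, dt=1e-4)
        parent = make_grid(uniform_segment(L=10, r=0.4), wall, cfg)
        mk = lambda i: make_grid(VesselSegment(id=i, name="d", L=10, r_in=0.3,
                                               r_out=0.3), wall, cfg)
        d1, d2 = mk(2), mk(3)
        parent.A *= 1.02
        parent.Q += 30.0
        (Ap, Qp), (A1, Q1), (A2, Q2) = pv.junction_solve(parent, (d1, d2),
                                                         cfg, wall)
        assert Q1 == pytest.approx(Q2, rel=1e-12)
        assert A1 == pytest.approx(A2, rel=1e-12)
        # mass conservation to the solver's scaled tolerance (1e-12 of the
        # characteristic flow scale A*c, ~1e-11 relative to Q here)
        assert Qp == pytest.approx(Q1 + Q2, rel=1e-9)

    def test_interface_relations_hold_to_tolerance(self, wall):
        parent, d1, d2, cfg = self._setup(wall)
        dt = 1e-4
        (Ap, Qp), (A1, Q1), (A2, Q2) = pv.junction_solve(parent, (d1, d2),
                                                         cfg, wall, dt=dt)
        Pp = K.press(Ap, parent.A0n[-1], parent.fn[-1], wall.P0)
        P1 = K.press(A1, d1.A0n[0], d1.fn[0], wall.P0)
        P2 = K.press(A2, d2.A0n[0], d2.fn[0], wall.P0)
        assert abs(Qp - Q1 - Q2) / abs(Qp) < 1e-10
        assert abs(Pp - P1) / Pp < 1e-10
        assert abs(Pp - P2) / Pp < 1e-10

    def test_agrees_with_generic_root_finder(self, wall):
        """Independent oracle: scipy.optimize.root on the six-unknown system."""
        parent, d1, d2, cfg = self._setup(wall)
        dt = 1e-4
        rho, nu = wall.rho, wall.nu
        wp = K.foot_w_plus(parent.A, parent.Q, parent.n - 1, parent.A0n,
                           parent.fn, rho, nu, parent.dx, dt)
        w1 = K.foot_w_minus(d1.A, d1.Q, 0, d1.A0n, d1.fn, rho, nu, d1.dx, dt)
        w2 = K.foot_w_minus(d2.A, d2.Q, 0, d2.A0n, d2.fn, rho, nu, d2.dx, dt)
        geo = [(parent.A0n[-1], parent.fn[-1]), (d1.A0n[0], d1.fn[0]),
               (d2.A0n[0], d2.fn[0])]

        def c_of(A, g):
            return math.sqrt(0.5 * g[1] / rho * math.sqrt(g[0] / A))

        def equations(y):
            Ap, Qp, A1, Q1, A2, Q2 = y
            Pp = K.press(Ap, *geo[0], wall.P0)
            P1 = K.press(A1, *geo[1], wall.P0)
            P2 = K.press(A2, *geo[2], wall.P0)
            return [Qp - Q1 - Q2,
                    (Pp - P1) / wall.P0,
                    (Pp - P2) / wall.P0,
                    Qp / Ap - 4 * c_of(Ap, geo[0]) - wp,
                    Q1 / A1 + 4 * c_of(A1, geo[1]) - w1,
                    Q2 / A2 + 4 * c_of(A2, geo[2]) - w2]

        y0 = [parent.A[-1], parent.Q[-1], d1.A[0], d1.Q[0], d2.A[0], d2.Q[0]]
        oracle = root(equations, y0, tol=1e-13)
        assert oracle.success
        (Ap, Qp), (A1, Q1), (A2, Q2) = pv.junction_solve(parent, (d1, d2),
                                                         cfg, wall, dt=dt)
        got = np.array([Ap, Qp, A1, Q1, A2, Q2])
        assert np.allclose(got, oracle.x, rtol=1e-7)


class TestNoReflection:
    def test_admittance_matched_junction_reflects_little(self, wall):
        """A pulse crossing into two daughters whose combined characteristic
        admittance matches the parent's leaves only a small reflected wave."""
        from scipy.optimize import brentq

        def admittance(r):
            A0 = math.pi * r * r
            f = (4.0 / 3.0) * (wall.k1 * math.exp(wall.k2 * r) + wall.k3)
            return A0 / (wall.rho * math.sqrt(0.5 * f / wall.rho))

        r_p = 0.4
        r_d = brentq(lambda r: 2 * admittance(r) - admittance(r_p), 0.1, 0.4)
        cfg = SolverConfig(dx_target=0.1)
        parent = make_grid(uniform_segment(L=30.0, r=r_p), wall, cfg)
        d1 = make_grid(VesselSegment(id=2, name="d1", L=30.0, r_in=r_d,
                                     r_out=r_d), wall, cfg)
        d2 = make_grid(VesselSegment(id=3, name="d2", L=30.0, r_in=r_d,
                                     r_out=r_d), wall, cfg)
        eps = 0.003
        parent = right_moving_bump(parent, wall, eps=eps, x0=18.0, width=2.5)
        c0 = float(parent.wave_speeds()[0])
        dt = 0.4 * parent.dx / c0
        step = SolverConfig(dx_target=0.1, dt=dt)
        n_steps = int(round(18.0 / c0 / dt))  # pulse crosses and moves on
        for _ in range(n_steps):
            pn = pv.lax_wendroff_step(parent, step, wall)
            g1 = pv.lax_wendroff_step(d1, step, wall)
            g2 = pv.lax_wendroff_step(d2, step, wall)
            (Ap, Qp), (A1, Q1), (A2, Q2) = pv.junction_solve(
                parent, (d1, d2), step, wall, dt=dt)
            pn.A[-1], pn.Q[-1] = Ap, Qp
            g1.A[0], g1.Q[0] = A1, Q1
            g2.A[0], g2.Q[0] = A2, Q2
            parent, d1, d2 = pn, g1, g2
        # transmitted pulse is in the daughters; what remains in the parent
        # (away from the interface node) is the reflection
        refl = np.max(np.abs(parent.A[:-2] / parent.A0n[:-2] - 1.0))
        trans = np.max(np.abs(d1.A / d1.A0n - 1.0))
        assert trans > 0.3 * eps          # the pulse did cross
        assert refl < 0.2 * eps           # and little of it came back


class TestStableTimestep:
    def test_rest_value_and_scalings(self, wall):
        cfg = SolverConfig(dx_target=0.5)
        g = make_grid(uniform_segment(L=20, r=0.4), wall, cfg)
        c0 = float(g.wave_speeds()[0])
        dt = pv.stable_timestep([g], cfg)
        assert dt == pytest.approx(cfg.cfl * g.dx / c0)
        # adding flow shrinks the step
        g.Q += 50.0
        assert pv.stable_timestep([g], cfg) < dt
        # halving dx halves dt
        g2 = make_grid(uniform_segment(L=20, r=0.4), wall,
                       SolverConfig(dx_target=0.25))
        assert pv.stable_timestep([g2], cfg) == pytest.approx(dt / 2, rel=0.05)
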