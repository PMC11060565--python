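"""Per-vessel finite-difference machinery: grids, Lax-Wendroff steps, junctions.

This module exposes the building blocks of the 1D solver on a single-segment
level (useful for testing and experimentation); `pulsevol.simulation` wires
them into the full coupled model.  All quantities are CGS.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from . import _kernel as K
from .arterial_tree import VesselSegment, WallModel


@dataclass(frozen=True)
class SolverConfig:
    """Discretization parameters.

    ``dx_target`` is an upper bound on the node spacing; every segment keeps
    at least ``n_min`` nodes (>= 5 interior).  ``dt`` is derived from the CFL
    condition at setup; it may be pinned explicitly for single-step use.
    """

    dx_target: float = 0.2
    cfl: float = 0.5
    dt: float | None = None
    max_newton_iter: int = 40
    newton_tol: float = 1e-12
    n_min: int = 7

    def __post_init__(self) -> None:
        if not 0 < self.cfl <= 1:
            raise ValueError("CFL number must be in (0, 1]")
        if self.dx_target <= 0:
            raise ValueError("dx_target must be positive")
        if self.n_min < 7:
            raise ValueError("need >= 7 nodes (5 interior) per segment")


#: coarse profile for tests and calibration inner loops
FAST = SolverConfig(dx_target=1.0)
#: coarsest profile for cohort-scale studies on the reduced tree
COARSE = SolverConfig(dx_target=2.0)
#: production profile
PRODUCTION = SolverConfig(dx_target=0.2)


def segment_geometry(seg: VesselSegment, wall: WallModel, x: np.ndarray):
    """Nominal geometry along a segment: (A0, f, dA0/dx, df/dx) at positions x.

    The taper ``r0(x) = r_in (r_out/r_in)^(x/L)`` gives analytic derivatives
    ``r0' = kappa r0`` with ``kappa = ln(r_out/r_in)/L``.
    """
    kappa = math.log(seg.r_out / seg.r_in) / seg.L
    r0 = seg.r_in * np.exp(kappa * x)
    dr0 = kappa * r0
    f = (4.0 / 3.0) * (wall.k1 * np.exp(wall.k2 * r0) + wall.k3)
    df = (4.0 / 3.0) * wall.k1 * wall.k2 * np.exp(wall.k2 * r0) * dr0
    A0 = np.pi * r0**2
    dA0 = 2.0 * np.pi * r0 * dr0
    return A0, f, dA0, df


@dataclass
class VesselGrid:
    """Uniform grid on one vessel with state (A, Q) and precomputed geometry."""

    seg: VesselSegment
    x: np.ndarray
    A: np.ndarray
    Q: np.ndarray
    A0n: np.ndarray
    fn: np.ndarray
    A0h: np.ndarray
    fh: np.ndarray
    dA0h: np.ndarray
    dfh: np.ndarray
    rho: float = 1.06
    P0: float = 97.0 * 1333.22

    def __post_init__(self) -> None:
        if self.x.size < 3:
            raise ValueError("grid needs at least 3 nodes")
        if np.any(self.A <= 0):
            raise ValueError("all areas must be positive")

    @property
    def n(self) -> int:
        return self.x.size

    @property
    def dx(self) -> float:
        return float(self.x[1] - self.x[0])

    def pressure(self) -> np.ndarray:
        return self.P0 + self.fn * (1.0 - np.sqrt(self.A0n / self.A))

    def wave_speeds(self) -> np.ndarray:
        return np.sqrt(0.5 * self.fn / self.rho * np.sqrt(self.A0n / self.A))


def make_grid(seg: VesselSegment, wall: WallModel,
              config: SolverConfig = PRODUCTION) -> VesselGrid:
    """Build a rest-state grid (A = A0, Q = 0) for one segment."""
    n = max(config.n_min, int(math.ceil(seg.L / config.dx_target)) + 1)
    x = np.linspace(0.0, seg.L, n)
    xh = 0.5 * (x[:-1] + x[1:])
    A0n, fn, _, _ = segment_geometry(seg, wall, x)
    A0h, fh, dA0h, dfh = segment_geometry(seg, wall, xh)
    return VesselGrid(seg, x, A0n.copy(), np.zeros(n), A0n, fn,
                      A0h, fh, dA0h, dfh, rho=wall.rho, P0=wall.P0)


def stable_timestep(grids, config: SolverConfig) -> float:
    """CFL-limited time step: ``dt = CFL * min dx / (|u| + c)`` over all nodes."""
    if isinstance(grids, VesselGrid):
        grids = [grids]
    dt = math.inf
    for g in grids:
        c = g.wave_speeds()
        u = np.abs(g.Q / g.A)
        dt = min(dt, g.dx / float(np.max(u + c)))
    return config.cfl * dt


def flux_and_source(A: float, Q: float, seg: VesselSegment, x: float,
                    wall: WallModel):
    """Conservation-form flux F(U) and source S(U) at a point, U = (A, Q).

    ``F = (Q, Q^2/A + f sqrt(A0 A)/rho)``; the momentum source combines
    parabolic-profile friction ``-8 pi nu Q/A`` with the geometric terms from
    the taper (df/dx, dA0/dx) that make the rest state an equilibrium.
    """
    if A <= 0:
        raise ValueError("area must be positive")
    xa = np.asarray([float(x)])
    A0, f, dA0, df = (float(v[0]) for v in segment_geometry(seg, wall, xa))
    F = (Q, K.flux_q(A, Q, A0, f, wall.rho))
    S = (0.0, K.source_q(A, Q, A0, f, dA0, df, wall.rho, wall.nu))
    return F, S


def lax_wendroff_step(grid: VesselGrid, config: SolverConfig,
                      wall: WallModel) -> VesselGrid:
    """Advance the interior nodes one step of the two-step Richtmyer scheme.

    Boundary nodes are copied unchanged (they belong to the ghost-point /
    characteristic closures).  Raises on CFL violation or if any updated area
    is non-positive.
    """
    dt = config.dt if config.dt is not None else stable_timestep(grid, config)
    c = grid.wave_speeds()
    u = np.abs(grid.Q / grid.A)
    if dt > grid.dx / float(np.max(u + c)) + 1e-15:
        raise ValueError("CFL condition violated for this dt")
    An = grid.A.copy()
    Qn = grid.Q.copy()
    K.lw_interior(grid.A, grid.Q, An, Qn, 0, grid.n, 0, grid.dx, dt,
                  grid.A0n, grid.fn, grid.A0h, grid.fh, grid.dA0h, grid.dfh,
                  wall.rho, wall.nu)
    if np.any(An <= 0):
        raise FloatingPointError("negative area after Lax-Wendroff step")
    return replace(grid, A=An, Q=Qn)


def dump_grids_csv(grids, path) -> None:
    """Write per-node solver state (segment, x, A, Q, P) to CSV for debugging."""
    import pandas as pd
    if isinstance(grids, VesselGrid):
        grids = [grids]
    rows = []
    for g in grids:
        P = g.pressure()
        for i in range(g.n):
            rows.append((g.seg.id, g.seg.name, g.x[i], g.A[i], g.Q[i], P[i]))
    pd.DataFrame(rows, columns=["segment_id", "segment", "x_cm", "A_cm2",
                                "Q_ml_s", "P_dyn_cm2"]).to_csv(path, index=False)


def junction_solve(parent: VesselGrid, daughters, config: SolverConfig,
                   wall: WallModel, dt: float | None = None):
    """Solve the bifurcation interface at t+dt.

    Returns ``((A_p, Q_p), (A_1, Q_1), (A_2, Q_2))`` satisfying mass
    conservation, pressure continuity and the three outgoing characteristic
    compatibility relations to the configured Newton tolerance.
    """
    d1, d2 = daughters
    if dt is None:
        dt = config.dt if config.dt is not None else stable_timestep(
            [parent, d1, d2], config)
    rho = wall.rho
    ip = parent.n - 1
    wp = K.foot_w_plus(parent.A, parent.Q, ip, parent.A0n, parent.fn,
                       rho, wall.nu, parent.dx, dt)
    w1 = K.foot_w_minus(d1.A, d1.Q, 0, d1.A0n, d1.fn, rho, wall.nu, d1.dx, dt)
    w2 = K.foot_w_minus(d2.A, d2.Q, 0, d2.A0n, d2.fn, rho, wall.nu, d2.dx, dt)
    Ap, Qp, A1, Q1, A2, Q2, ok = K.junction_newton(
        parent.A[ip], d1.A[0], d2.A[0], wp, w1, w2,
        parent.A0n[ip], parent.fn[ip], d1.A0n[0], d1.fn[0], d2.A0n[0], d2.fn[0],
        wall.P0, rho, config.newton_tol, config.max_newton_iter)
    if not ok:
        raise RuntimeError("junction Newton iteration did not converge")
    return (Ap, Qp), (A1, Q1), (A2, Q2)
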