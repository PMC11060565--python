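"""Coupled 0-1D simulation: assemble tree + boundaries, run cardiac cycles.

`CoupledModel` bundles a (height-scaled) arterial tree, its wall law, the
elastance ventricle and the discretization profile.  `run_to_periodic`
advances whole cardiac cycles until the pressure waveform at the measurement
site repeats to within a tolerance, then records one full cycle of the
solution; `sample_waveform` and `stroke_volume` extract the quantities used
downstream (the radial pressure waveform and the net aortic-root flow
integral).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernel as K
from .arterial_tree import MMHG, ArterialTree, WallModel
from .elastance_heart import HeartParams, HeartState
from .pulse_wave_solver import PRODUCTION, SolverConfig, segment_geometry
from .terminal_windkessel import split_resistances


class SimulationError(RuntimeError):
    """Raised when the forward model becomes unstable or non-physical."""


@dataclass(frozen=True)
class PressureWaveform:
    """One cardiac period of pressure samples.

    ``t`` (s) is strictly increasing, starts at 0 and stays below the period
    ``T``; ``p`` is in mmHg.  ``sbp``/``dbp`` carry optional cuff-calibration
    metadata.
    """

    t: np.ndarray
    p: np.ndarray
    T: float
    sbp: float | None = None
    dbp: float | None = None

    def __post_init__(self) -> None:
        t, p = np.asarray(self.t, float), np.asarray(self.p, float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "p", p)
        if t.ndim != 1 or t.shape != p.shape or t.size < 4:
            raise ValueError("waveform needs matching 1-D t/p with >= 4 samples")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time samples must be strictly increasing")
        if t[0] < 0 or t[-1] >= self.T * (1 + 1e-9):
            raise ValueError("time samples must lie in [0, T)")
        if not (np.all(np.isfinite(p)) and np.isfinite(self.T) and self.T > 0):
            raise ValueError("non-finite waveform")

    @property
    def n(self) -> int:
        return self.t.size

    def is_uniform(self, rtol: float = 1e-8) -> bool:
        d = np.diff(self.t)
        return bool(np.all(np.abs(d - d[0]) <= rtol * d[0]))


def foot_align(w: PressureWaveform) -> PressureWaveform:
    """Cyclically shift a uniformly sampled beat so its minimum (foot) is at t=0."""
    if not w.is_uniform():
        raise ValueError("foot alignment requires uniform sampling")
    i = int(np.argmin(w.p))
    return replace(w, p=np.roll(w.p, -i))


@dataclass(frozen=True)
class CoupledModel:
    """A fully specified forward model (already height-scaled)."""

    tree: ArterialTree
    heart: HeartParams
    wall: WallModel = field(default_factory=WallModel)
    solver: SolverConfig = PRODUCTION
    init_pressure_mmHg: float = 80.0

    def __post_init__(self) -> None:
        n_term = len(self.tree.terminal_ids)
        if n_term == 0:
            raise ValueError("tree has no terminal segments")


class _FlatModel:
    """Flattened kernel-ready arrays for one CoupledModel (CGS units)."""

    def __init__(self, model: CoupledModel):
        tree, wall, cfg = model.tree, model.wall, model.solver
        self.model = model
        order = tree.topological_order()
        self.seg_ids = [s.id for s in order]
        idx = {sid: i for i, sid in enumerate(self.seg_ids)}
        nseg = len(order)
        nn = np.empty(nseg, np.int64)
        dxs = np.empty(nseg)
        for i, s in enumerate(order):
            n = max(cfg.n_min, int(math.ceil(s.L / cfg.dx_target)) + 1)
            nn[i] = n
            dxs[i] = s.L / (n - 1)
        off = np.zeros(nseg + 1, np.int64)
        off[1:] = np.cumsum(nn)
        hoff = np.zeros(nseg + 1, np.int64)
        hoff[1:] = np.cumsum(nn - 1)
        NN, NH = int(off[-1]), int(hoff[-1])
        A0n = np.empty(NN); fn = np.empty(NN)
        A0h = np.empty(NH); fh = np.empty(NH)
        dA0h = np.empty(NH); dfh = np.empty(NH)
        for i, s in enumerate(order):
            x = np.linspace(0.0, s.L, nn[i])
            xh = 0.5 * (x[:-1] + x[1:])
            a0, f, _, _ = segment_geometry(s, wall, x)
            A0n[off[i]:off[i + 1]] = a0
            fn[off[i]:off[i + 1]] = f
            a0h, fhh, da0, df = segment_geometry(s, wall, xh)
            A0h[hoff[i]:hoff[i + 1]] = a0h
            fh[hoff[i]:hoff[i + 1]] = fhh
            dA0h[hoff[i]:hoff[i + 1]] = da0
            dfh[hoff[i]:hoff[i + 1]] = df
        jp, j1, j2 = [], [], []
        for i, s in enumerate(order):
            if not s.is_terminal:
                d1, d2 = s.daughters
                jp.append(i); j1.append(idx[d1]); j2.append(idx[d2])
        terms = [i for i, s in enumerate(order) if s.is_terminal]
        R1 = np.empty(len(terms)); R2 = np.empty(len(terms))
        CT = np.empty(len(terms)); PT = np.zeros(len(terms))
        for m, i in enumerate(terms):
            r1, r2 = split_resistances(order[i].terminal_R)
            R1[m], R2[m], CT[m] = r1, r2, order[i].terminal_C
        self.off, self.nn, self.hoff, self.dxs = off, nn, hoff, dxs
        self.A0n, self.fn = A0n, fn
        self.A0h, self.fh, self.dA0h, self.dfh = A0h, fh, dA0h, dfh
        self.jparent = np.asarray(jp, np.int64)
        self.jd1 = np.asarray(j1, np.int64)
        self.jd2 = np.asarray(j2, np.int64)
        self.tseg = np.asarray(terms, np.int64)
        self.wR1, self.wR2, self.wCT, self.wPT = R1, R2, CT, PT
        site_seg, rel = tree.measurement_site
        si = idx[site_seg]
        self.site_node = int(off[si] + round(rel * (nn[si] - 1)))
        # CFL time step at rest, rounded so an integer number of steps per beat
        c0 = np.sqrt(0.5 * fn / wall.rho)
        dt = math.inf
        for i in range(nseg):
            cmax = float(np.max(c0[off[i]:off[i + 1]]))
            dt = min(dt, dxs[i] / cmax)
        dt *= cfg.cfl
        T = model.heart.T
        self.nsteps = int(math.ceil(T / dt))
        self.dt = T / self.nsteps
        for m in range(len(terms)):
            if self.dt >= R2[m] * CT[m]:  # explicit Euler margin (bound is 2 R2 CT)
                raise ValueError(
                    f"dt={self.dt:.3e}s violates Windkessel stability for terminal "
                    f"{order[terms[m]].name!r} (R2*CT={R2[m]*CT[m]:.3e}s)")

    def initial_state(self):
        """Quiescent initialization at a uniform (diastolic) pressure.

        Areas are set from the tube law at the initial pressure, Q = 0,
        Windkessels at the same pressure, ventricle full and in filling
        phase: no startup discontinuity anywhere in the domain.
        """
        p0 = self.model.init_pressure_mmHg * MMHG
        wall = self.model.wall
        A = self.A0n / (1.0 - (p0 - wall.P0) / self.fn) ** 2
        Q = np.zeros_like(A)
        wPend = np.full(self.tseg.size, p0)
        wQend = np.zeros(self.tseg.size)
        heart = self.model.heart
        hstate = HeartState(phase="filling", V_lv=heart.V_max)
        hs, phase = hstate.to_kernel()
        return A, Q, wPend, wQend, hs, phase


@dataclass
class PeriodicSolution:
    """Final-cycle fields of a (near-)periodic simulation.

    Pressures in mmHg, flows in ml/s, volumes in ml.  ``A_rec``/``Q_rec``
    hold stride-sampled per-node state (CGS) over the final cycle for
    arbitrary-site sampling; full-resolution traces are kept at the
    measurement site and the aortic root.
    """

    t: np.ndarray
    dt: float
    T: float
    site_p: np.ndarray
    p_root: np.ndarray
    q_root: np.ndarray
    v_lv: np.ndarray
    rec_t: np.ndarray
    A_rec: np.ndarray
    Q_rec: np.ndarray
    conv_metric_mmHg: float
    converged: bool
    n_cycles: int
    v_in_ml: float
    v_out_ml: float
    tree_vol_start_ml: float
    tree_vol_end_ml: float
    vlv_cycle_start_ml: float
    vlv_cycle_end_ml: float
    heart_state: HeartState
    flat: _FlatModel


def run_to_periodic(model: CoupledModel, max_cycles: int = 15,
                    tol_mmHg: float = 0.5, min_cycles: int = 1) -> PeriodicSolution:
    """Run whole cardiac cycles until the site waveform repeats within tol.

    Convergence metric: max |P_site(cycle k) - P_site(cycle k-1)| over the
    beat.  Valve events shift by whole time steps between early cycles, which
    makes the metric decay non-monotonically, so the stopping rule demands
    two consecutive cycles within tolerance.  After it fires (or
    ``max_cycles`` is exhausted) one more cycle is run with full recording;
    the returned metric refers to that final cycle.  Setting
    ``min_cycles = max_cycles`` forces a fixed cycle count, which makes
    downstream objectives smooth in the model parameters.  Non-convergence is
    flagged on the result, not fatal; numerical blow-up raises
    :class:`SimulationError`.
    """
    flat = _FlatModel(model)
    A, Q, wPend, wQend, hs, phase = flat.initial_state()
    An, Qn = A.copy(), Q.copy()
    ns = flat.nsteps
    site_p = np.empty(ns); q_root = np.empty(ns)
    p_root = np.empty(ns); vlv = np.empty(ns)
    empty = np.empty((0, A.size))
    hp = model.heart.to_cgs()
    wall = model.wall
    prev = None
    metric = math.inf
    cycles = 0
    passes = 0
    for _ in range(max_cycles):
        phase, v_in, v_out, ok = K.run_one_cycle(
            A, Q, An, Qn, flat.off, flat.nn, flat.hoff, flat.dxs,
            flat.A0n, flat.fn, flat.A0h, flat.fh, flat.dA0h, flat.dfh,
            flat.jparent, flat.jd1, flat.jd2,
            flat.tseg, flat.wR1, flat.wR2, flat.wCT, flat.wPT, wPend, wQend,
            hs, phase, hp, wall.rho, wall.nu, wall.P0,
            flat.dt, ns, flat.site_node,
            site_p, q_root, p_root, vlv, 0, empty, empty)
        cycles += 1
        if not ok or not np.all(np.isfinite(site_p)):
            raise SimulationError(f"forward model unstable in cycle {cycles}")
        if prev is not None:
            metric = float(np.max(np.abs(site_p - prev))) / MMHG
        prev = site_p.copy()
        passes = passes + 1 if metric < tol_mmHg else 0
        if cycles >= min_cycles and passes >= 2:
            break
    # recording cycle (also the one all reported fields refer to)
    stride = max(1, ns // 512)
    nrec = (ns + stride - 1) // stride
    A_rec = np.empty((nrec, A.size)); Q_rec = np.empty((nrec, A.size))
    vol0 = float(K.tree_volume(A, flat.off, flat.nn, flat.dxs))
    vlv0 = float(hs[K.HS_VLV])
    phase, v_in, v_out, ok = K.run_one_cycle(
        A, Q, An, Qn, flat.off, flat.nn, flat.hoff, flat.dxs,
        flat.A0n, flat.fn, flat.A0h, flat.fh, flat.dA0h, flat.dfh,
        flat.jparent, flat.jd1, flat.jd2,
        flat.tseg, flat.wR1, flat.wR2, flat.wCT, flat.wPT, wPend, wQend,
        hs, phase, hp, wall.rho, wall.nu, wall.P0,
        flat.dt, ns, flat.site_node,
        site_p, q_root, p_root, vlv, stride, A_rec, Q_rec)
    cycles += 1
    if not ok or not np.all(np.isfinite(site_p)):
        raise SimulationError(f"forward model unstable in cycle {cycles}")
    metric = float(np.max(np.abs(site_p - prev))) / MMHG
    vol1 = float(K.tree_volume(A, flat.off, flat.nn, flat.dxs))
    t = np.arange(ns) * flat.dt
    return PeriodicSolution(
        t=t, dt=flat.dt, T=model.heart.T,
        site_p=site_p / MMHG, p_root=p_root / MMHG, q_root=q_root.copy(),
        v_lv=vlv.copy(), rec_t=t[::stride][:nrec], A_rec=A_rec, Q_rec=Q_rec,
        conv_metric_mmHg=metric, converged=bool(metric < tol_mmHg),
        n_cycles=cycles, v_in_ml=float(v_in), v_out_ml=float(v_out),
        tree_vol_start_ml=vol0, tree_vol_end_ml=vol1,
        vlv_cycle_start_ml=vlv0, vlv_cycle_end_ml=float(hs[K.HS_VLV]),
        heart_state=HeartState.from_kernel(hs, phase), flat=flat)


def sample_waveform(solution: PeriodicSolution,
                    site: tuple[int, float] | None = None) -> PressureWaveform:
    """Pressure waveform over the final cycle at a tree site, foot-aligned.

    ``site = (segment id, relative position in [0,1])``; None selects the
    model's measurement site (full time resolution).  The aortic root at
    relative position 0 also uses the full-resolution trace.
    """
    flat = solution.flat
    tree = flat.model.tree
    if site is None:
        site = tree.measurement_site
    sid, rel = site
    if sid not in tree.segments or not 0.0 <= rel <= 1.0:
        raise ValueError(f"invalid site {site}")
    i = flat.seg_ids.index(sid)
    node = int(flat.off[i] + round(rel * (flat.nn[i] - 1)))
    if node == flat.site_node:
        t, p = solution.t, solution.site_p
    elif sid == tree.root_id and node == flat.off[0]:
        t, p = solution.t, solution.p_root
    else:
        a = solution.A_rec[:, node]
        p = (flat.model.wall.P0 + flat.fn[node]
             * (1.0 - np.sqrt(flat.A0n[node] / a))) / MMHG
        t = solution.rec_t
    w = PressureWaveform(t=t.copy(), p=np.asarray(p, float).copy(), T=solution.T,
                         sbp=float(np.max(p)), dbp=float(np.min(p)))
    return foot_align(w)


def stroke_volume(solution: PeriodicSolution) -> float:
    """Net aortic-root inflow volume over one period (ml), trapezoid rule.

    Backflow during aortic valve closure enters with its (negative) sign.
    """
    q = np.append(solution.q_root, solution.q_root[0])
    return float(np.trapezoid(q, dx=solution.dt))
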