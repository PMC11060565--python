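"""Two-stage subject-specific parameter estimation against a radial waveform.

Four parameters are tuned per subject: the maximal ventricular elastance
``E_max``, the time to onset of constant elastance ``t_m``, and global
scalings of all terminal resistances (``S_R``) and compliances (``S_C``).
A particle-swarm search (15 particles, 10 iterations) explores the bounded
4-box; its best points seed a gradient-based refinement (trust-region
Gauss-Newton on the Fourier-coefficient residuals, finite-difference
Jacobians).  The objective is the squared distance between the 13-element
Fourier signatures of the simulated and measured radial beats.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize

from .arterial_tree import ArterialTree, BodyScaling, WallModel, default_tree, \
    scale_terminals, scale_tree
from .elastance_heart import HeartParams
from .objective import FourierSignature, align_smooth, fourier_signature, mape
from .pulse_wave_solver import PRODUCTION, SolverConfig
from .simulation import CoupledModel, PressureWaveform, SimulationError, \
    foot_align, run_to_periodic, sample_waveform, stroke_volume

#: objective value returned for unstable / non-physical forward runs
PENALTY = 1.0e9


@dataclass(frozen=True)
class ParameterVector:
    """The four subject-specific parameters."""

    E_max: float   # mmHg/ml
    t_m: float     # s
    S_R: float     # terminal-resistance scaling, dimensionless
    S_C: float     # terminal-compliance scaling, dimensionless

    def as_array(self) -> np.ndarray:
        return np.array([self.E_max, self.t_m, self.S_R, self.S_C])

    @classmethod
    def from_array(cls, x) -> "ParameterVector":
        return cls(*(float(v) for v in x))


@dataclass(frozen=True)
class ParameterBounds:
    """Box bounds for (E_max, t_m, S_R, S_C)."""

    lo: np.ndarray
    hi: np.ndarray

    def __post_init__(self) -> None:
        lo, hi = np.asarray(self.lo, float), np.asarray(self.hi, float)
        object.__setattr__(self, "lo", lo)
        object.__setattr__(self, "hi", hi)
        if lo.shape != (4,) or hi.shape != (4,) or np.any(lo >= hi):
            raise ValueError("bounds must be two length-4 vectors with lo < hi")

    def contains(self, p: ParameterVector) -> bool:
        x = p.as_array()
        return bool(np.all(x >= self.lo) and np.all(x <= self.hi))

    def clip(self, x: np.ndarray) -> np.ndarray:
        return np.clip(x, self.lo, self.hi)


def default_bounds(T: float) -> ParameterBounds:
    """Search box covering the population spread of the four parameters.

    ``t_m`` is capped at 0.95 T so a constant-elastance interval always
    exists within the beat.
    """
    return ParameterBounds(lo=np.array([0.5, 0.3, 0.3, 1.0]),
                           hi=np.array([8.0, 0.95 * T, 5.0, 30.0]))


def build_subject_model(tree: ArterialTree, meta, wall: WallModel | None = None,
                        solver: SolverConfig = PRODUCTION,
                        heart_base: HeartParams | None = None) -> CoupledModel:
    """Personalize the vascular and cardiac scaffolding to a subject.

    ``meta`` needs attributes height (cm), SBP, DBP (mmHg) and T (s).  The
    tree geometry scales by S = height/175 (terminals by S^-3 / S^3); the
    ventricular volumes V_max = 120 ml and V0 = 15 ml scale by S^3; the heart
    period is the subject's; Windkessels start at the diastolic pressure.
    """
    if not (meta.SBP > meta.DBP > 0):
        raise ValueError("need SBP > DBP > 0")
    if meta.T <= 0 or meta.height <= 0:
        raise ValueError("need positive height and heart period")
    scaling = BodyScaling(meta.height)
    S3 = scaling.S ** 3
    base = heart_base if heart_base is not None else HeartParams(
        T=meta.T, t_m=min(0.55, 0.68 * meta.T))
    heart = replace(base, T=meta.T, V_max=120.0 * S3, V0=15.0 * S3,
                    t_m=min(base.t_m, 0.9 * meta.T))
    return CoupledModel(tree=scale_tree(tree, scaling), heart=heart,
                        wall=wall if wall is not None else WallModel(),
                        solver=solver, init_pressure_mmHg=meta.DBP)


def apply_parameters(model: CoupledModel, p: ParameterVector,
                     bounds: ParameterBounds | None = None) -> CoupledModel:
    """Return the model with the four estimated parameters applied.

    ``S_R``/``S_C`` multiply every terminal R_T / C_T on top of body-size
    scaling; ``E_max``/``t_m`` replace the heart's values.
    """
    if bounds is not None and not bounds.contains(p):
        raise ValueError(f"parameters {p} outside bounds")
    if min(p.E_max, p.t_m, p.S_R, p.S_C) <= 0 or p.t_m >= model.heart.T:
        raise ValueError(f"non-physical parameters {p}")
    tree = scale_terminals(model.tree, p.S_R, p.S_C)
    heart = replace(model.heart, E_max=p.E_max, t_m=p.t_m)
    return replace(model, tree=tree, heart=heart)


def signature_residuals(model: CoupledModel, p: ParameterVector,
                        target: FourierSignature,
                        n_cycles: int = 9) -> np.ndarray:
    """Fourier-coefficient residual vector (simulated minus target).

    The forward model runs a fixed number of cycles (plus the recording
    cycle) so the residuals are smooth in ``p``; unstable or clearly
    non-periodic runs return a uniform large-residual vector whose squared
    norm is the ``PENALTY`` value.
    """
    n = target.c.size
    try:
        m = apply_parameters(model, p)
        sol = run_to_periodic(m, max_cycles=n_cycles, tol_mmHg=0.0,
                              min_cycles=n_cycles)
        if sol.conv_metric_mmHg > 5.0:
            return np.full(n, math.sqrt(PENALTY / n))
        w = align_smooth(sample_waveform(sol), target.n_harmonics)
        return fourier_signature(w, target.n_harmonics).c - target.c
    except (SimulationError, FloatingPointError, ValueError):
        return np.full(n, math.sqrt(PENALTY / n))


def evaluate_objective(model: CoupledModel, p: ParameterVector,
                       target: FourierSignature, n_cycles: int = 9) -> float:
    """Forward-simulate at ``p`` and score the radial-beat signature distance
    (sum of squared Fourier-coefficient differences)."""
    return float(np.sum(signature_residuals(model, p, target, n_cycles) ** 2))


def pso_search(objective, bounds: ParameterBounds, n_particles: int = 15,
               n_iterations: int = 10, seed: int | None = None,
               inertia: float = 0.7, c_cog: float = 1.5, c_soc: float = 1.5,
               return_swarm: bool = False):
    """Global-best particle swarm over the 4-box.

    Velocities are clamped to 20% of each bound range per step and particles
    reflect off the box faces.  Returns ``(best ParameterVector, trace)``
    where ``trace`` is the per-iteration global-best objective
    (non-increasing by construction); with ``return_swarm`` the personal-best
    positions and values are appended (used as extra refinement starts).
    Fully determined by ``seed``.
    """
    rng = np.random.default_rng(seed)
    lo, hi = bounds.lo, bounds.hi
    rng_span = hi - lo
    vmax = 0.2 * rng_span
    X = lo + rng.uniform(size=(n_particles, 4)) * rng_span
    V = rng.uniform(-1.0, 1.0, size=(n_particles, 4)) * vmax
    fX = np.array([objective(ParameterVector.from_array(x)) for x in X])
    pbest, fpbest = X.copy(), fX.copy()
    g = int(np.argmin(fX))
    gbest, fgbest = X[g].copy(), float(fX[g])
    trace = [fgbest]
    for _ in range(n_iterations):
        r1 = rng.uniform(size=(n_particles, 4))
        r2 = rng.uniform(size=(n_particles, 4))
        V = inertia * V + c_cog * r1 * (pbest - X) + c_soc * r2 * (gbest - X)
        V = np.clip(V, -vmax, vmax)
        X = X + V
        # reflect off box faces
        for k in range(2):
            low = X < lo
            X[low] = (2 * lo - X)[low]
            V[low] = -V[low]
            high = X > hi
            X[high] = (2 * hi - X)[high]
            V[high] = -V[high]
        X = bounds.clip(X)
        for i in range(n_particles):
            f = objective(ParameterVector.from_array(X[i]))
            if f < fpbest[i]:
                fpbest[i] = f
                pbest[i] = X[i].copy()
                if f < fgbest:
                    fgbest = float(f)
                    gbest = X[i].copy()
        trace.append(fgbest)
    if return_swarm:
        return ParameterVector.from_array(gbest), np.asarray(trace), pbest, fpbest
    return ParameterVector.from_array(gbest), np.asarray(trace)


def gradient_refine(objective, p0: ParameterVector, bounds: ParameterBounds,
                    rel_step: float = 1e-2, max_iter: int = 50,
                    max_evals: int = 450, ftol: float = 1e-10,
                    n_restarts: int = 3, residuals=None, extra_starts=None):
    """Gradient-based polish of the swarm's best point.

    The search runs in normalized box coordinates so the model Hessian is
    well conditioned despite the disparate parameter scales, with
    finite-difference steps of ``rel_step`` of the box span: valve events in
    the forward model shift in whole time-step quanta, giving the objective a
    fine staircase texture that smaller steps would sample instead of the
    underlying trend.

    When ``residuals(p) -> vector`` is supplied (the fitting objective is a
    sum of squared Fourier-coefficient differences) the descent is a
    trust-region Gauss-Newton iteration on that vector
    (:func:`scipy.optimize.least_squares`), which follows the narrow
    E_max/S_R valley far more efficiently than a generic quasi-Newton; it is
    restarted while it keeps improving.  Otherwise a bound-constrained
    quasi-Newton (L-BFGS-B) with central differences is used.  In both cases
    the best point ever evaluated is returned, so the result is never worse
    than ``p0``.
    """
    if residuals is not None:
        return _gauss_newton_refine(objective, residuals, p0, bounds,
                                    rel_step=rel_step, max_evals=max_evals,
                                    n_restarts=n_restarts,
                                    extra_starts=extra_starts)
    lo, hi = bounds.lo, bounds.hi
    span = hi - lo
    cache: dict[tuple, float] = {}
    best = {"x": p0.as_array().copy(), "f": math.inf}

    def fun(z):
        z = np.clip(z, 0.0, 1.0)
        key = tuple(np.round(z, 12))
        if key in cache:
            return cache[key]
        if len(cache) >= max_evals:
            return best["f"] + abs(best["f"]) + 1.0  # budget exhausted
        x = lo + z * span
        f = objective(ParameterVector.from_array(x))
        cache[key] = f
        if f < best["f"]:
            best["f"] = f
            best["x"] = x.copy()
        return f

    def grad(z):
        g = np.zeros(4)
        for i in range(4):
            zp, zm = z.copy(), z.copy()
            zp[i] = min(z[i] + rel_step, 1.0)
            zm[i] = max(z[i] - rel_step, 0.0)
            denom = zp[i] - zm[i]
            g[i] = (fun(zp) - fun(zm)) / denom if denom > 0 else 0.0
        return g

    total_iter = 0
    messages = []
    for _ in range(n_restarts):
        f_before = best["f"] if np.isfinite(best["f"]) else fun(
            (p0.as_array() - lo) / span)
        z_start = (best["x"] - lo) / span
        res = minimize(fun, z_start, jac=grad, method="L-BFGS-B",
                       bounds=[(0.0, 1.0)] * 4,
                       options={"maxiter": max_iter, "ftol": ftol,
                                "maxfun": max_evals})
        total_iter += int(res.nit)
        messages.append(str(res.message))
        if len(cache) >= max_evals:
            break
        if best["f"] >= f_before * (1.0 - 1e-3) and np.isfinite(f_before):
            break  # restart gained (almost) nothing
    info = {"n_evals": len(cache), "n_iter": total_iter, "message": messages}
    return ParameterVector.from_array(best["x"]), float(best["f"]), info


def _gauss_newton_refine(objective, residuals, p0: ParameterVector,
                         bounds: ParameterBounds, rel_step: float = 1e-2,
                         max_evals: int = 700, n_restarts: int = 3,
                         nfev_per_round: int = 40, extra_starts=None,
                         good_enough: float = 0.5):
    """Trust-region Gauss-Newton rounds on the residual vector.

    Runs restarted rounds from ``p0`` and optionally from additional swarm
    starts (distinct basins), keeping the best point overall.  Coordinates
    are mapped to the [1, 2] box so scipy's relative ``diff_step`` yields a
    uniform absolute finite-difference step of about ``rel_step`` for every
    parameter.
    """
    from scipy.optimize import least_squares

    lo, span = bounds.lo, bounds.hi - bounds.lo
    n_evals = [0]

    def resid_z(z):
        n_evals[0] += 1
        x = lo + (np.clip(z, 1.0, 2.0) - 1.0) * span
        return np.asarray(residuals(ParameterVector.from_array(x)), float)

    def rounds_from(z_start, f_start):
        z_loc, f_loc = z_start.copy(), f_start
        for _ in range(n_restarts):
            res = least_squares(
                resid_z, z_loc, bounds=(np.ones(4), np.full(4, 2.0)),
                diff_step=rel_step, xtol=1e-12, ftol=1e-12, gtol=1e-14,
                max_nfev=nfev_per_round)
            f = 2.0 * float(res.cost)
            improved = f < f_loc * (1.0 - 1e-3)
            if f < f_loc:
                f_loc, z_loc = f, res.x.copy()
            if not improved or n_evals[0] >= max_evals:
                break
        return z_loc, f_loc

    f_best = objective(p0)
    z_best, f_best = rounds_from(1.0 + (p0.as_array() - lo) / span, f_best)
    n_starts = 1
    for x0 in (extra_starts if extra_starts is not None else []):
        # further basins are only worth exploring while the best fit still
        # corresponds to a visible waveform discrepancy
        if n_evals[0] >= max_evals or f_best < good_enough:
            break
        z0 = 1.0 + (np.asarray(x0, float) - lo) / span
        z, f = rounds_from(z0, math.inf)
        n_starts += 1
        if f < f_best:
            z_best, f_best = z, f
    x_best = lo + (np.clip(z_best, 1.0, 2.0) - 1.0) * span
    info = {"n_evals": n_evals[0], "n_starts": n_starts,
            "message": ["gauss-newton multistart"]}
    return ParameterVector.from_array(x_best), float(f_best), info


@dataclass
class CalibrationResult:
    """Outcome of one subject calibration."""

    params: ParameterVector
    objective_value: float
    mape_pct: float
    sv_ml: float
    fitted_waveform: PressureWaveform
    diagnostics: dict = field(default_factory=dict)


def calibrate(waveform: PressureWaveform, meta, *,
              tree: ArterialTree | None = None,
              wall: WallModel | None = None,
              solver: SolverConfig = PRODUCTION,
              heart_base: HeartParams | None = None,
              bounds: ParameterBounds | None = None,
              seed: int | None = 0,
              n_particles: int = 15, n_iterations: int = 10,
              n_cycles_fit: int = 9) -> CalibrationResult:
    """Full pipeline: personalize, search, refine, report.

    ``waveform`` is one cuff-calibrated radial beat; ``meta`` carries height,
    SBP, DBP and heart period T.  Deterministic for a fixed ``seed``.
    """
    if tree is None:
        tree = default_tree()
    model = build_subject_model(tree, meta, wall=wall, solver=solver,
                                heart_base=heart_base)
    if bounds is None:
        bounds = default_bounds(meta.T)
    target = fourier_signature(align_smooth(waveform))
    n_evals = [0]

    def objective(p: ParameterVector) -> float:
        n_evals[0] += 1
        return evaluate_objective(model, p, target, n_cycles=n_cycles_fit)

    def residuals(p: ParameterVector) -> np.ndarray:
        n_evals[0] += 1
        return signature_residuals(model, p, target, n_cycles=n_cycles_fit)

    p_pso, trace, pbest, fpbest = pso_search(
        objective, bounds, n_particles=n_particles,
        n_iterations=n_iterations, seed=seed, return_swarm=True)
    # additional refinement starts: best personal-best positions that sit in
    # visibly different regions of the (normalized) box
    span = bounds.hi - bounds.lo
    chosen = [p_pso.as_array()]
    extra = []
    for i in np.argsort(fpbest):
        cand = pbest[i]
        if all(np.linalg.norm((cand - c) / span) > 0.08 for c in chosen):
            chosen.append(cand)
            extra.append(cand)
        if len(extra) == 4:
            break
    p_ref, f_ref, ginfo = gradient_refine(objective, p_pso, bounds,
                                          residuals=residuals,
                                          extra_starts=extra)
    # final forward run with the convergence stopping rule
    fitted = apply_parameters(model, p_ref)
    sol = run_to_periodic(fitted, max_cycles=20, tol_mmHg=0.1)
    w_fit = sample_waveform(sol)
    result = CalibrationResult(
        params=p_ref,
        objective_value=f_ref,
        mape_pct=mape(w_fit, foot_align(waveform)),
        sv_ml=stroke_volume(sol),
        fitted_waveform=w_fit,
        diagnostics={
            "n_evals": n_evals[0],
            "pso_trace": trace.tolist(),
            "pso_best": p_pso.as_array().tolist(),
            "refine": ginfo,
            "forward_converged": sol.converged,
            "forward_cycles": sol.n_cycles,
            "conv_metric_mmHg": sol.conv_metric_mmHg,
            "max_phi": fitted.heart.max_activation(),
            "seed": seed,
        })
    return result
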