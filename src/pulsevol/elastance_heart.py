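"""Time-varying-elastance left ventricle with a four-phase valve state machine.

The ventricle provides the inflow boundary condition of the arterial tree.
Its pressure is ``P_lv = E_lv(t) (V_lv - V0)`` with the periodic elastance

    E_lv(t) = E_min (1 - phi(t)) + E_max phi(t)
    phi(t)  = a sin(pi t/t_m) - b sin(2 pi t/t_m)   for 0 <= t < t_m
            = 0                                     for t_m <= t < T

The within-beat clock ``t`` resets every heart period ``T``; the valve phases
are driven by a separate state machine (mitral closure at maximal volume,
aortic opening when LV pressure exceeds root pressure, aortic closure after a
small allowed backflow volume).  Phase ODEs (filling inertance/resistance,
ejection inertance/resistance) are integrated with classical RK4.

Clinical units throughout this module: mmHg, ml, s.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import _kernel as K
from .arterial_tree import MMHG

PHASES = ("filling", "isovolumic_contraction", "ejection",
          "aortic_closing", "isovolumic_relaxation")


@dataclass(frozen=True)
class HeartParams:
    """Elastance-ventricle parameters (clinical units).

    ``E_max``/``t_m`` are the two heart parameters estimated per subject; the
    shape constants (a, b), diastolic elastance, valve resistances/inertances
    and the backflow allowance are fixed, literature-inherited defaults.
    ``V_max`` (mitral-closure volume) and ``V0`` scale with body size as S^3.
    """

    T: float = 0.8
    E_max: float = 2.6         # mmHg/ml
    E_min: float = 0.06        # mmHg/ml
    t_m: float = 0.55          # s
    a: float = 0.9
    b: float = 0.25
    V0: float = 15.0           # ml
    V_max: float = 120.0       # ml
    P_la: float = 8.0          # mmHg
    R_la: float = 0.01         # mmHg s/ml
    L_la: float = 5.0e-4       # mmHg s^2/ml
    R_lv: float = 0.006        # mmHg s/ml
    L_lv: float = 5.0e-4       # mmHg s^2/ml
    Vb_bar: float = 1.5        # ml

    def __post_init__(self) -> None:
        if not self.E_max > self.E_min > 0:
            raise ValueError("need E_max > E_min > 0")
        if not 0 < self.t_m < self.T:
            raise ValueError("need 0 < t_m < T")
        if not self.V_max > self.V0 >= 0:
            raise ValueError("need V_max > V0 >= 0")
        if self.Vb_bar < 0:
            raise ValueError("backflow allowance must be >= 0")

    def to_cgs(self) -> np.ndarray:
        """Pack into the kernel's CGS parameter vector."""
        hp = np.empty(14)
        hp[K.HP_EMAX] = self.E_max * MMHG
        hp[K.HP_EMIN] = self.E_min * MMHG
        hp[K.HP_TM] = self.t_m
        hp[K.HP_A] = self.a
        hp[K.HP_B] = self.b
        hp[K.HP_T] = self.T
        hp[K.HP_V0] = self.V0
        hp[K.HP_VMAX] = self.V_max
        hp[K.HP_PLA] = self.P_la * MMHG
        hp[K.HP_RLA] = self.R_la * MMHG
        hp[K.HP_LLA] = self.L_la * MMHG
        hp[K.HP_RLV] = self.R_lv * MMHG
        hp[K.HP_LLV] = self.L_lv * MMHG
        hp[K.HP_VBBAR] = self.Vb_bar
        return hp

    def max_activation(self) -> float:
        """Peak of phi(t) over the beat (diagnostic: effective peak elastance
        is E_min + (E_max - E_min) * max_activation)."""
        t = np.linspace(0.0, self.t_m, 2001)
        return float(np.max(self.a * np.sin(np.pi * t / self.t_m)
                            - self.b * np.sin(2 * np.pi * t / self.t_m)))


@dataclass
class HeartState:
    """Instantaneous ventricle state within a beat."""

    phase: str = "filling"
    V_lv: float = 120.0
    Q_la: float = 0.0
    Q_lv: float = 0.0
    V_b: float = 0.0
    t_star: float = float("nan")

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise ValueError(f"unknown phase {self.phase!r}")
        if self.V_lv <= 0:
            raise ValueError("ventricular volume must be positive")

    def to_kernel(self) -> tuple[np.ndarray, int]:
        hs = np.array([self.V_lv, self.Q_la, self.Q_lv, self.V_b, self.t_star])
        return hs, PHASES.index(self.phase)

    @classmethod
    def from_kernel(cls, hs: np.ndarray, phase: int) -> "HeartState":
        return cls(phase=PHASES[phase], V_lv=float(hs[K.HS_VLV]),
                   Q_la=float(hs[K.HS_QLA]), Q_lv=float(hs[K.HS_QLV]),
                   V_b=float(hs[K.HS_VB]), t_star=float(hs[K.HS_TSTAR]))


def load_config(path=None):
    """Load wall and heart constants from a YAML config.

    Returns ``(WallModel, HeartParams)``.  Omitted keys fall back to the
    shipped defaults (``data/default_config.yaml`` documents every constant).
    """
    import yaml

    from .arterial_tree import WallModel, _data_path

    base = yaml.safe_load(_data_path("default_config.yaml").read_text())
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        for section in ("wall", "heart"):
            base.setdefault(section, {}).update(user.get(section, {}))
    w = {k: float(v) for k, v in base["wall"].items()}
    w["P0"] = w.pop("P0_mmHg") * MMHG
    h = {k: float(v) for k, v in base["heart"].items()}
    return WallModel(**w), HeartParams(**h)


def activation_phi(t: float, t_m: float, a: float, b: float, T: float) -> float:
    """Dimensionless activation phi(t); zero on [t_m, T)."""
    if not 0 <= t < T:
        raise ValueError(f"t={t} outside [0, {T})")
    return float(K.activation(t, t_m, a, b))


def elastance(t: float, params: HeartParams) -> float:
    """Time-varying elastance E_lv(t) in mmHg/ml."""
    if not 0 <= t < params.T:
        raise ValueError(f"t={t} outside [0, {params.T})")
    phi = K.activation(t, params.t_m, params.a, params.b)
    return params.E_min * (1.0 - phi) + params.E_max * phi


def lv_pressure(V_lv: float, t: float, params: HeartParams) -> float:
    """Ventricular pressure E_lv(t) (V_lv - V0) in mmHg."""
    if V_lv <= 0:
        raise ValueError("ventricular volume must be positive")
    return elastance(t, params) * (V_lv - params.V0)


def advance_heart(state: HeartState, params: HeartParams, P_a: float,
                  t: float, dt: float) -> tuple[HeartState, float]:
    """One RK4 step + valve transition checks; returns (new state, Q_lv imposed).

    ``P_a`` is the aortic-root pressure (mmHg) from the current 1D solution,
    held fixed across the step.  The imposed root flow is Q_lv during
    ejection/closing and zero otherwise.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    hs, phase = state.to_kernel()
    phase = K.heart_step(phase, hs, params.to_cgs(), P_a * MMHG, t, dt)
    if not np.all(np.isfinite(hs[:4])):
        raise FloatingPointError("non-finite heart state")
    new = HeartState.from_kernel(hs, phase)
    q_imposed = new.Q_lv if new.phase in ("ejection", "aortic_closing") else 0.0
    return new, q_imposed


def backflow_volume(t: np.ndarray, Q_lv: np.ndarray, t_star: float,
                    t_end: float) -> float:
    """Retrograde volume |int of negative Q_lv| accumulated on [t_star, t_end].

    Trapezoid rule on the negative part of the flow history; this is the
    quantity compared against the closure allowance ``Vb_bar``.
    """
    if t_end < t_star:
        raise ValueError("t_end must be >= t_star")
    t = np.asarray(t, float)
    q = np.minimum(np.asarray(Q_lv, float), 0.0)
    m = (t >= t_star) & (t <= t_end)
    if m.sum() < 2:
        return 0.0
    return float(-np.trapezoid(q[m], t[m]))
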