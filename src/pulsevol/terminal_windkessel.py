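"""Three-element Windkessel outflow boundaries.

Each terminal vessel drains into a lumped representation of its downstream
bed: a proximal resistance ``R1`` in series with a parallel distal resistance
``R2`` / compliance ``CT`` pair referenced to the terminal pressure ``PT``.
The governing relation between end flow and end pressure is

    R1 R2 CT dQ/dt = R2 CT dP/dt + (P - PT) - (R1 + R2) Q

advanced by explicit Euler in lockstep with the 1D solver.  This module works
in clinical units (mmHg, ml); the solver kernel keeps its own CGS copy.
"""

from __future__ import annotations

from dataclasses import dataclass, replace


def split_resistances(RT: float) -> tuple[float, float]:
    """Split a total terminal resistance with the fixed ratio R1/RT = 0.2."""
    if RT <= 0:
        raise ValueError("total resistance must be positive")
    return 0.2 * RT, 0.8 * RT


@dataclass(frozen=True)
class WindkesselBC:
    """Lumped outflow boundary state.

    R1, R2 in mmHg s/ml; CT in ml/mmHg; pressures in mmHg; flows in ml/s.
    ``P_end``/``Q_end`` are the current boundary values at the attached 1D end.
    """

    R1: float
    R2: float
    CT: float
    PT: float = 0.0
    P_end: float = 0.0
    Q_end: float = 0.0

    def __post_init__(self) -> None:
        if min(self.R1, self.R2, self.CT) <= 0:
            raise ValueError("R1, R2, CT must be positive")

    @classmethod
    def from_total(cls, RT: float, CT: float, PT: float = 0.0,
                   P_init: float = 0.0) -> "WindkesselBC":
        R1, R2 = split_resistances(RT)
        return cls(R1=R1, R2=R2, CT=CT, PT=PT, P_end=P_init)

    @property
    def tau(self) -> float:
        """Diastolic decay time constant R2*CT (s)."""
        return self.R2 * self.CT

    def stability_bound(self) -> float:
        """Largest explicit-Euler-stable time step, 2*R2*CT."""
        return 2.0 * self.R2 * self.CT


def windkessel_advance(bc: WindkesselBC, Q_end_new: float, dt: float) -> WindkesselBC:
    """One explicit-Euler step given the new end flow.

    ``dQ/dt`` is finite-differenced from the stored and the new end flow; the
    pressure-relaxation and resistive terms are taken at the old time level:

        P_new = P + R1 (Q_new - Q) + dt/(R2 CT) [(R1+R2) Q - (P - PT)]

    Steady state recovers ``P = PT + (R1+R2) Q``; with zero inflow the
    pressure relaxes to ``PT`` with time constant ``R2 CT``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    P_new = bc.P_end + bc.R1 * (Q_end_new - bc.Q_end) \
        + dt / (bc.R2 * bc.CT) * ((bc.R1 + bc.R2) * bc.Q_end - (bc.P_end - bc.PT))
    return replace(bc, P_end=P_new, Q_end=Q_end_new)
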