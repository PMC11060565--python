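"""Arterial-tree data model: vessel network, constitutive wall law, body-size scaling.

The systemic arterial tree is represented as a binary bifurcating network of
tapered elastic vessels.  Each terminal vessel carries the nominal lumped
parameters (total resistance ``R_T`` and compliance ``C_T``) of its downstream
vascular bed, later turned into a three-element Windkessel boundary.

Units
-----
Internal computations use CGS throughout: cm, g, s, pressure in dyn/cm^2,
flow in cm^3/s (= ml/s).  File I/O and user-facing values use clinical units
(mmHg, ml); ``MMHG`` converts between the two (1 mmHg = 1333.22 dyn/cm^2).
Resistances are stored internally in dyn s/cm^5 and compliances in cm^5/dyn.
Radii in the tree file are defined at the nominal distending pressure ``P0``
(97 mmHg by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

#: dyn/cm^2 per mmHg
MMHG = 1333.22

#: reference body height (cm) for which the shipped tree geometry is defined
REFERENCE_HEIGHT_CM = 175.0


@dataclass(frozen=True)
class WallModel:
    """Arterial wall stiffness law and blood properties.

    The stiffness of a vessel of nominal radius ``r0`` is
    ``f(r0) = (4/3) * (k1 * exp(k2 * r0) + k3)`` (dyn/cm^2), an empirical
    law in which small vessels (muscular, distal) are stiffer than large
    elastic ones.  Defaults follow the classical parameterization used
    throughout the 1D pulse-wave literature.

    Parameters
    ----------
    k1, k3 : float
        Stiffness constants, dyn/cm^2 (before the 4/3 factor).
    k2 : float
        Radius decay rate, 1/cm (negative: stiffness falls with radius).
    P0 : float
        Nominal distending pressure at which tree radii are defined, dyn/cm^2.
    rho : float
        Blood density, g/cm^3.
    mu : float
        Blood dynamic viscosity, g/(cm s).
    """

    k1: float = 2.0e7
    k2: float = -22.53
    k3: float = 8.65e5
    P0: float = 97.0 * MMHG
    rho: float = 1.06
    mu: float = 0.049

    def __post_init__(self) -> None:
        if self.P0 <= 0 or self.rho <= 0 or self.mu <= 0:
            raise ValueError("P0, rho and mu must all be positive")

    @property
    def nu(self) -> float:
        """Kinematic viscosity, cm^2/s."""
        return self.mu / self.rho


@dataclass(frozen=True)
class BodyScaling:
    """Dimensionless body-size scaling relative to the 175 cm reference subject."""

    height_cm: float

    def __post_init__(self) -> None:
        if not self.height_cm > 0:
            raise ValueError(f"height must be positive, got {self.height_cm}")

    @property
    def S(self) -> float:
        return self.height_cm / REFERENCE_HEIGHT_CM


@dataclass(frozen=True)
class VesselSegment:
    """One tapered elastic vessel.

    ``terminal_R`` (dyn s/cm^5) and ``terminal_C`` (cm^5/dyn) are present iff
    the segment is terminal (no daughters); they are the *nominal* total
    resistance and compliance of the downstream bed.
    """

    id: int
    name: str
    L: float
    r_in: float
    r_out: float
    daughters: tuple[int, ...] = ()
    terminal_R: float | None = None
    terminal_C: float | None = None

    def __post_init__(self) -> None:
        if self.L <= 0 or self.r_in <= 0 or self.r_out <= 0:
            raise ValueError(f"segment {self.id}: L, r_in, r_out must be positive")
        if len(self.daughters) not in (0, 2):
            raise ValueError(f"segment {self.id}: must have exactly 0 or 2 daughters")
        has_r = self.terminal_R is not None
        has_c = self.terminal_C is not None
        if has_r != has_c:
            raise ValueError(
                f"segment {self.id}: terminal_R and terminal_C go together")
        if has_r and not self.is_terminal:
            raise ValueError(
                f"segment {self.id}: only terminal segments carry R_T/C_T")
        if has_r and (self.terminal_R <= 0 or self.terminal_C <= 0):
            raise ValueError(f"segment {self.id}: terminal R/C must be positive")

    @property
    def is_terminal(self) -> bool:
        return len(self.daughters) == 0


@dataclass(frozen=True)
class ArterialTree:
    """Connected, acyclic, single-rooted binary tree of :class:`VesselSegment`.

    ``measurement_site`` is ``(segment id, relative position in [0, 1])``: the
    location at which the simulated pressure waveform is compared with the
    measured (radial-artery) one.
    """

    segments: dict[int, VesselSegment]
    root_id: int
    measurement_site: tuple[int, float]

    def __post_init__(self) -> None:
        segs = self.segments
        if self.root_id not in segs:
            raise ValueError("root_id not among segments")
        parent: dict[int, int] = {}
        for s in segs.values():
            for d in s.daughters:
                if d not in segs:
                    raise ValueError(f"segment {s.id} refers to unknown daughter {d}")
                if d in parent:
                    raise ValueError(f"segment {d} has more than one parent")
                parent[d] = s.id
        if self.root_id in parent:
            raise ValueError("root segment must not have a parent")
        for sid in segs:
            if sid != self.root_id and sid not in parent:
                raise ValueError(f"segment {sid} is disconnected from the root")
        # reachability from root (acyclicity follows from unique parents + count)
        seen: set[int] = set()
        stack = [self.root_id]
        while stack:
            sid = stack.pop()
            if sid in seen:
                raise ValueError("cycle detected in tree")
            seen.add(sid)
            stack.extend(segs[sid].daughters)
        if seen != set(segs):
            raise ValueError("tree is not connected")
        for s in segs.values():
            if s.is_terminal and s.terminal_R is None:
                raise ValueError(
                    f"terminal segment {s.id} lacks its Windkessel R_T/C_T")
        site_id, site_x = self.measurement_site
        if site_id not in segs or not 0.0 <= site_x <= 1.0:
            raise ValueError(f"invalid measurement site {self.measurement_site}")

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    @property
    def terminal_ids(self) -> list[int]:
        return [s.id for s in self.topological_order() if s.is_terminal]

    def topological_order(self) -> list[VesselSegment]:
        """Segments in root-first (parent before daughters) order."""
        out: list[VesselSegment] = []
        stack = [self.root_id]
        while stack:
            s = self.segments[stack.pop()]
            out.append(s)
            stack.extend(reversed(s.daughters))
        return out


# ---------------------------------------------------------------------------
# Constitutive relations (tube law)
# ---------------------------------------------------------------------------

def radius_at(seg: VesselSegment, x: float) -> float:
    """Nominal radius at position ``x`` (cm) along an exponentially tapered vessel.

    ``r0(x) = r_in * (r_out / r_in)**(x / L)`` so that the taper interpolates
    geometrically between the proximal and distal radii.
    """
    if not 0.0 <= x <= seg.L:
        raise ValueError(f"x={x} outside [0, {seg.L}]")
    return seg.r_in * (seg.r_out / seg.r_in) ** (x / seg.L)


def wall_stiffness(r0: float, wall: WallModel) -> float:
    """Elastic stiffness ``f = (4/3)(k1 exp(k2 r0) + k3)`` (dyn/cm^2) at radius r0."""
    if r0 <= 0:
        raise ValueError("radius must be positive")
    return (4.0 / 3.0) * (wall.k1 * math.exp(wall.k2 * r0) + wall.k3)


def tube_law_pressure(A, A0, f, P0):
    """Transmural pressure from area: ``P = P0 + f (1 - sqrt(A0/A))``.

    Strictly increasing in ``A``; equals ``P0`` at the nominal area and
    saturates at ``P0 + f`` as the vessel distends.  Accepts scalars or arrays.
    """
    A = np.asarray(A, dtype=float)
    if np.any(A <= 0) or np.any(np.asarray(A0) <= 0):
        raise ValueError("areas must be positive")
    out = P0 + f * (1.0 - np.sqrt(A0 / A))
    return float(out) if out.ndim == 0 else out


def tube_law_area(P, A0, f, P0):
    """Inverse tube law: ``A = A0 / (1 - (P - P0)/f)^2`` for ``P - P0 < f``."""
    P = np.asarray(P, dtype=float)
    if np.any(P - P0 >= f):
        raise ValueError("P - P0 >= f: unphysical over-distension")
    out = A0 / (1.0 - (P - P0) / f) ** 2
    return float(out) if out.ndim == 0 else out


def wave_speed(A, A0, f, rho):
    """Local pressure-wave speed ``c = sqrt((f / 2 rho) sqrt(A0 / A))`` (cm/s).

    Follows from ``c^2 = (A/rho) dP/dA`` applied to the tube law; decreases
    with distension under this wall model.
    """
    A = np.asarray(A, dtype=float)
    if np.any(A <= 0):
        raise ValueError("area must be positive")
    out = np.sqrt(f / (2.0 * rho) * np.sqrt(A0 / A))
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Body-size personalization
# ---------------------------------------------------------------------------

def scale_tree(tree: ArterialTree, scaling: BodyScaling) -> ArterialTree:
    """Scale geometry and terminal elements to subject height.

    Lengths and radii are multiplied by ``S = height/175``; terminal
    resistances by ``1/S^3`` and terminal compliances by ``S^3`` (a vascular
    bed scales volumetrically with body size).
    """
    S = scaling.S
    new = {}
    for sid, s in tree.segments.items():
        kw = dict(L=s.L * S, r_in=s.r_in * S, r_out=s.r_out * S)
        if s.is_terminal:
            kw["terminal_R"] = s.terminal_R / S**3
            kw["terminal_C"] = s.terminal_C * S**3
        new[sid] = replace(s, **kw)
    return ArterialTree(new, tree.root_id, tree.measurement_site)


def scale_terminals(tree: ArterialTree, S_R: float, S_C: float) -> ArterialTree:
    """Multiply every terminal R_T by ``S_R`` and every C_T by ``S_C``.

    These are the two vascular parameters adjusted during subject-specific
    calibration, applied on top of body-size scaling.
    """
    if S_R <= 0 or S_C <= 0:
        raise ValueError("S_R and S_C must be positive")
    new = {}
    for sid, s in tree.segments.items():
        if s.is_terminal:
            new[sid] = replace(s, terminal_R=s.terminal_R * S_R, terminal_C=s.terminal_C * S_C)
        else:
            new[sid] = s
    return ArterialTree(new, tree.root_id, tree.measurement_site)


# ---------------------------------------------------------------------------
# Tree file I/O
# ---------------------------------------------------------------------------

_TREE_COLUMNS = ["id", "name", "parent", "length_cm", "r_in_cm", "r_out_cm", "RT", "CT"]


def load_tree(path_or_buf, measurement_site: tuple[int, float] | None = None) -> ArterialTree:
    """Load a tree definition CSV.

    One row per segment with columns ``id, name, parent, length_cm, r_in_cm,
    r_out_cm, RT, CT``; ``parent`` empty for the root; ``RT`` (mmHg s/ml) and
    ``CT`` (ml/mmHg) present only on terminal rows.  If ``measurement_site``
    is not given, the midpoint of the first segment whose name contains
    "radial" is used.
    """
    df = pd.read_csv(path_or_buf, comment="#")
    missing = set(_TREE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"tree file missing columns: {sorted(missing)}")
    daughters: dict[int, list[int]] = {}
    roots = []
    for _, row in df.iterrows():
        if pd.isna(row["parent"]):
            roots.append(int(row["id"]))
        else:
            daughters.setdefault(int(row["parent"]), []).append(int(row["id"]))
    if len(roots) != 1:
        raise ValueError(f"tree file must have exactly one root, found {len(roots)}")
    segments = {}
    for _, row in df.iterrows():
        sid = int(row["id"])
        ds = tuple(daughters.get(sid, []))
        rt, ct = row["RT"], row["CT"]
        terminal = len(ds) == 0
        if terminal and (pd.isna(rt) or pd.isna(ct)):
            raise ValueError(f"terminal segment {sid} lacks RT/CT")
        segments[sid] = VesselSegment(
            id=sid,
            name=str(row["name"]),
            L=float(row["length_cm"]),
            r_in=float(row["r_in_cm"]),
            r_out=float(row["r_out_cm"]),
            daughters=ds,
            terminal_R=float(rt) * MMHG if terminal else None,
            terminal_C=float(ct) / MMHG if terminal else None,
        )
    if measurement_site is None:
        radial = [s.id for s in segments.values() if "radial" in s.name.lower()]
        if not radial:
            raise ValueError("no segment named '*radial*'; pass measurement_site explicitly")
        measurement_site = (min(radial), 0.5)
    return ArterialTree(segments, roots[0], measurement_site)


def _data_path(name: str) -> Path:
    return Path(resources.files("pulsevol").joinpath("data", name))


def default_tree() -> ArterialTree:
    """The shipped 55-segment systemic arterial tree (175 cm reference subject)."""
    return load_tree(_data_path("arterial_tree_55.csv"))


def toy_tree() -> ArterialTree:
    """A 7-segment reduced tree (aorta, arm with radial/ulnar, trunk, visceral, leg).

    Used for fast tests and examples; same physics, ~30x cheaper than the
    55-segment tree.
    """
    return load_tree(_data_path("arterial_tree_7.csv"))
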