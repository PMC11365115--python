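"""Composite arc geometry of a rim pore in a hemifusion diaphragm (HD).

A hemifusion diaphragm is the single-bilayer patch where two apposing
membranes have merged their contacting leaflets.  A *rim pore* sits at the
edge of that patch: its boundary is composed of three circular arcs that
share the same two vertices, placed at (+-a, 0),

* the ``h``-arc -- the remainder of the HD rim (three-bilayer junction),
  radius ``Rh``, always the major arc of its circle,
* the ``e``-arc -- the membrane-edge line bounding the HD side of the pore,
  radius ``Re``,
* the ``p``-arc -- the fusion-pore-like line bounding the outer side,
  radius ``Rp``.

The ``e`` and ``p`` arcs may each be the *minor* arc (recessed pore) or the
*reflex* arc (pore bulges through a semicircle; protruding pores).

Membrane-area bookkeeping.  Outside the outer boundary (h+p) the membrane
is double, inside the HD it is single and the open pore carries none, so
the *planar deficit* relative to two intact apposing membranes is
``A_out + A_pore``.  At finite half-separation ``d`` the junction and
fusion-pore lines additionally consume membrane in the walls that connect
the two planes -- by default area ``2 d`` per unit length of either line
(two half-height walls along ``h``, one full-height wall along ``p``).
Walls are membrane sinks, so at fixed total membrane area the conserved
combination is

    A_out + A_pore - d (c_h L_h + c_p L_p)  =  const,

with ``c_h = c_p = 2`` by default.  ``SystemSpec.Ah0`` is the planar area
of the pore-free reference HD, ``pi Rh0(d)^2``; the conserved constant is
then ``Ah0 - c_h d 2 pi Rh0``.  At ``d = 0`` this reduces to the familiar
``A_out + A_pore = Ah0``.

All lengths are in arbitrary consistent units; the saddle-search layer
normalizes to ``Ah0 = pi`` (pore-free HD radius 1) and ``lambda_h = 1``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LineTensions",
    "WallModel",
    "SystemSpec",
    "PoreGeometry",
    "InfeasibleGeometryError",
    "build_geometry",
    "free_energy",
    "constraint_residual",
    "no_pore_reference",
    "system_from_d_ratio",
]

MINOR = "minor"
REFLEX = "reflex"


class InfeasibleGeometryError(ValueError):
    """No pore half-width ``a`` satisfies the membrane-area constraint."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LineTensions:
    """Line tensions of the three rim-pore boundary segments.

    ``lambda_h`` is the three-bilayer junction, ``lambda_e`` the membrane
    edge and ``lambda_p`` the fusion-pore-like line.  Normalization by
    ``lambda_h`` preserves the two ratios, which are all the geometry
    depends on.
    """

    lambda_e: float
    lambda_p: float
    lambda_h: float = 1.0

    def __post_init__(self) -> None:
        if not (self.lambda_e > 0 and self.lambda_p > 0 and self.lambda_h > 0):
            raise ValueError("line tensions must be strictly positive")

    def normalized(self) -> "LineTensions":
        """Return an equivalent set with ``lambda_h = 1`` (ratios preserved)."""
        h = self.lambda_h
        return LineTensions(self.lambda_e / h, self.lambda_p / h, 1.0)

    @property
    def ratios(self) -> tuple[float, float]:
        return (self.lambda_e / self.lambda_h, self.lambda_p / self.lambda_h)


@dataclass(frozen=True)
class WallModel:
    """Finite-``d`` wall-area bookkeeping.

    Wall area consumed per unit line length is ``c_h * d`` along the
    three-bilayer junction and ``c_p * d`` along the fusion-pore line.  The
    defaults correspond to two half-height walls (one per apposing
    membrane) along ``h`` and one full wall of height ``2d`` along ``p``.
    """

    kind: str = "linear"
    c_h: float = 2.0
    c_p: float = 2.0


@dataclass(frozen=True)
class SystemSpec:
    """Reference area and half-separation of the apposing membranes.

    ``Ah0`` is the planar area of the pore-free reference HD at this ``d``
    (so ``Rh0(d) = sqrt(Ah0 / pi)`` identically); ``d`` is half the
    distance between the centers of the two apposing membranes.
    """

    Ah0: float = math.pi
    d: float = 0.0
    wall: WallModel = field(default_factory=WallModel)

    def __post_init__(self) -> None:
        if self.Ah0 <= 0:
            raise ValueError("Ah0 must be positive")
        if self.d < 0:
            raise ValueError("d must be non-negative")

    @property
    def Rh0(self) -> float:
        """Radius of the pore-free reference HD."""
        return math.sqrt(self.Ah0 / math.pi)

    @property
    def conserved_target(self) -> float:
        """Value of ``A_out + A_pore - A_wall`` shared by all feasible geometries."""
        return self.Ah0 - self.wall.c_h * self.d * 2.0 * math.pi * self.Rh0


def system_from_d_ratio(d_over_rh0: float, wall: WallModel | None = None) -> SystemSpec:
    """System normalized so the pore-free HD has unit radius at this ``d``."""
    return SystemSpec(Ah0=math.pi, d=float(d_over_rh0), wall=wall or WallModel())


@dataclass(frozen=True)
class PoreGeometry:
    """A rim-pore geometry (three arcs through the vertices at ``(+-a, 0)``)."""

    Rh: float
    Re: float
    Rp: float
    a: float
    bow_e: str = MINOR
    bow_p: str = MINOR
    # derived quantities
    theta_h: float = 0.0
    theta_e: float = 0.0
    theta_p: float = 0.0
    L_h: float = 0.0
    L_e: float = 0.0
    L_p: float = 0.0
    A_out: float = 0.0
    A_pore: float = 0.0
    A_wall: float = 0.0
    Lambda_extra: float = 0.0

    @property
    def is_pore_free(self) -> bool:
        return self.a == 0.0

    def arc_closure_residual(self) -> float:
        """Max relative distance between reconstructed arc endpoints and vertices."""
        if self.is_pore_free:
            return 0.0
        worst = 0.0
        for R, bow in ((self.Rh, REFLEX), (self.Re, self.bow_e), (self.Rp, self.bow_p)):
            c = math.sqrt(max(R * R - self.a * self.a, 0.0))
            yc = -c if bow == MINOR else c
            th = math.asin(min(self.a / R, 1.0))
            y_end = yc + R * math.cos(th) * (1.0 if bow == MINOR else -1.0)
            for sx in (+1.0, -1.0):
                pt = np.array([R * math.sin(th) * sx, y_end])
                dist = min(
                    np.hypot(pt[0] - self.a, pt[1]), np.hypot(pt[0] + self.a, pt[1])
                )
                worst = max(worst, dist / max(self.a, R))
        return worst


# ---------------------------------------------------------------------------
# per-arc primitives
# ---------------------------------------------------------------------------
# For an arc of radius R through (+-a, 0) with half-angle
#   phi = theta        (minor arc),   theta = arcsin(a / R)
#   phi = pi - theta   (reflex arc)
# the arc length and the (positive) circular-segment area between the chord
# and the arc are
#   L   = 2 phi R
#   seg = R^2 (phi - sin(phi) cos(phi))
# with sin(phi) = a/R and cos(phi) = +-sqrt(R^2 - a^2)/R.  The h-arc always
# uses the reflex form (it is the major part of the HD circle).


def _arc_quantities(R, a, reflex: bool):
    """Return (L, seg, theta) for scalar or ndarray ``R``/``a``."""
    R = np.asarray(R, dtype=float)
    a = np.asarray(a, dtype=float)
    s = np.clip(a / R, 0.0, 1.0)
    theta = np.arcsin(s)
    c = np.sqrt(np.maximum(R * R - a * a, 0.0))
    if reflex:
        phi = np.pi - theta
        L = 2.0 * phi * R
        seg = R * R * phi + a * c
    else:
        phi = theta
        L = 2.0 * phi * R
        seg = R * R * phi - a * c
    return L, seg, theta


def _arc_derivs(R, a, reflex: bool):
    """Analytic derivatives (dL/dR, dL/da, dseg/dR, dseg/da).

    Note ``dseg/dR = R * dL/dR`` for both bow types.
    """
    R = np.asarray(R, dtype=float)
    a = np.asarray(a, dtype=float)
    theta = np.arcsin(np.clip(a / R, 0.0, 1.0))
    c = np.sqrt(np.maximum(R * R - a * a, 0.0))
    if reflex:
        dL_dR = 2.0 * (np.pi - theta) + 2.0 * a / c
        dL_da = -2.0 * R / c
        dseg_da = -2.0 * a * a / c
    else:
        dL_dR = 2.0 * theta - 2.0 * a / c
        dL_da = 2.0 * R / c
        dseg_da = 2.0 * a * a / c
    return dL_dR, dL_da, R * dL_dR, dseg_da


def conserved_area(Rh, Re, Rp, a, bow_e=MINOR, bow_p=MINOR, system: SystemSpec | None = None):
    """Planar deficit minus wall area; equal to ``system.conserved_target``
    on feasible geometries.  Vectorized over ndarray inputs."""
    system = system or SystemSpec()
    L_h, seg_h, _ = _arc_quantities(Rh, a, reflex=True)
    L_e, seg_e, _ = _arc_quantities(Re, a, reflex=(bow_e == REFLEX))
    L_p, seg_p, _ = _arc_quantities(Rp, a, reflex=(bow_p == REFLEX))
    area = seg_h + 2.0 * seg_p + seg_e
    if system.d > 0:
        area = area - system.d * (system.wall.c_h * L_h + system.wall.c_p * L_p)
    return area


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def constraint_residual(geom: PoreGeometry, system: SystemSpec) -> float:
    """Signed residual of the fixed-membrane-area constraint.

    Zero on feasible geometries; continuous and (over the bracketing
    interval used by :func:`build_geometry`) monotone in ``a``.
    """
    if geom.is_pore_free:
        L_h, seg_h, _ = _arc_quantities(geom.Rh, 0.0, reflex=True)
        area = seg_h - system.d * system.wall.c_h * L_h
        return float(area - system.conserved_target)
    area = conserved_area(
        geom.Rh, geom.Re, geom.Rp, geom.a, geom.bow_e, geom.bow_p, system
    )
    return float(area - system.conserved_target)


def _solve_half_width(Rh, Re, Rp, bow_e, bow_p, system: SystemSpec) -> float:
    """First root of the area constraint in ``a`` over ``(0, min(Re, Rp, 0.999 Rh))``.

    A dense scan brackets the first sign change from ``a -> 0``; bisection
    then polishes it to ~1e-15 relative.
    """
    amax = min(Re, Rp, 0.999 * Rh)
    if amax <= 0:
        raise InfeasibleGeometryError("degenerate bracketing interval")
    target = system.conserved_target
    grid = amax * np.linspace(1e-9, 1.0 - 1e-12, 400)
    res = conserved_area(Rh, Re, Rp, grid, bow_e, bow_p, system) - target
    sign = np.sign(res)
    flips = np.nonzero(sign[:-1] * sign[1:] <= 0)[0]
    if len(flips) == 0:
        raise InfeasibleGeometryError(
            f"area constraint has no root for Rh={Rh}, Re={Re}, Rp={Rp} "
            f"(bows {bow_e}/{bow_p}, Ah0={system.Ah0}, d={system.d})"
        )
    lo, hi = grid[flips[0]], grid[flips[0] + 1]
    f_lo = res[flips[0]]
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        f_mid = float(
            conserved_area(Rh, Re, Rp, mid, bow_e, bow_p, system) - target
        )
        if f_lo * f_mid <= 0:
            hi = mid
        else:
            lo, f_lo = mid, f_mid
        if hi - lo < 1e-15 * amax:
            break
    return 0.5 * (lo + hi)


def build_geometry(
    Rh: float,
    Re: float,
    Rp: float,
    bow_e: str = MINOR,
    bow_p: str = MINOR,
    system: SystemSpec | None = None,
    a: float | None = None,
) -> PoreGeometry:
    """Assemble a rim-pore geometry with ``a`` fixed by the area constraint.

    Passing ``a = 0.0`` explicitly requests the pore-free branch (a circular
    HD of radius ``Rh``); otherwise ``a`` is solved by bracketed bisection of
    :func:`constraint_residual`.  Raises :class:`InfeasibleGeometryError`
    when no root exists.
    """
    system = system or SystemSpec()
    if Rh <= 0 or Re <= 0 or Rp <= 0:
        raise ValueError("radii must be positive")
    if bow_e not in (MINOR, REFLEX) or bow_p not in (MINOR, REFLEX):
        raise ValueError("bow flags must be 'minor' or 'reflex'")
    if a is not None and a == 0.0:
        L_h, seg_h, _ = _arc_quantities(Rh, 0.0, reflex=True)
        return PoreGeometry(
            Rh=Rh, Re=Re, Rp=Rp, a=0.0, bow_e=bow_e, bow_p=bow_p,
            L_h=float(L_h), L_e=0.0, L_p=0.0,
            A_out=float(seg_h), A_pore=0.0,
            A_wall=float(system.d * system.wall.c_h * L_h),
        )
    if a is None:
        a = _solve_half_width(Rh, Re, Rp, bow_e, bow_p, system)
    a = float(a)
    if not (0 < a <= min(Re, Rp) and a < Rh):
        raise InfeasibleGeometryError("half-width outside the admissible interval")
    L_h, seg_h, th_h = _arc_quantities(Rh, a, reflex=True)
    L_e, seg_e, th_e = _arc_quantities(Re, a, reflex=(bow_e == REFLEX))
    L_p, seg_p, th_p = _arc_quantities(Rp, a, reflex=(bow_p == REFLEX))
    return PoreGeometry(
        Rh=Rh, Re=Re, Rp=Rp, a=a, bow_e=bow_e, bow_p=bow_p,
        theta_h=float(th_h), theta_e=float(th_e), theta_p=float(th_p),
        L_h=float(L_h), L_e=float(L_e), L_p=float(L_p),
        A_out=float(seg_h + seg_p), A_pore=float(seg_e + seg_p),
        A_wall=float(system.d * (system.wall.c_h * L_h + system.wall.c_p * L_p)),
    )


def free_energy(geom: PoreGeometry, lt: LineTensions) -> float:
    """Boundary free energy ``F = lambda_h L_h + lambda_e L_e + lambda_p L_p``.

    Additive in the arcs and homogeneous of degree one under uniform length
    rescaling at fixed tension ratios.  ``Lambda_extra`` carries any
    configured protrusion correction (zero in the default arcs-only model).
    """
    return (
        lt.lambda_h * geom.L_h
        + lt.lambda_e * geom.L_e
        + lt.lambda_p * geom.L_p
        + geom.Lambda_extra
    )


def no_pore_reference(system: SystemSpec, lt: LineTensions | None = None) -> tuple[float, float]:
    """Pore-free HD radius ``Rh0(d)`` and its free energy ``lambda_h 2 pi Rh0``."""
    lam_h = 1.0 if lt is None else lt.lambda_h
    Rh0 = system.Rh0
    return Rh0, lam_h * 2.0 * math.pi * Rh0
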