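"""Constrained saddle points (critical rim pores) of the boundary free energy.

The free energy ``F = lambda_h L_h + lambda_e L_e + lambda_p L_p`` is
stationarized over the three radii with the pore half-width ``a`` slaved to
the fixed-membrane-area constraint.  Stationarity is equivalent to

* the Laplace force balances across each line (with wall corrections at
  finite separation ``d``)::

      Rh = lambda_h / Sigma + c_h d
      Re = lambda_e / Sigma
      Rp = lambda_p / (2 Sigma) + c_p d / 2

  where ``Sigma`` is the Lagrange multiplier of the area constraint, i.e.
  the membrane tension, and

* a tangential force balance at the two pore vertices,
  ``s_e c_e + 2 s_p c_p = c_h`` with ``c_x = sqrt(Rx^2 - a^2)`` and
  ``s = +1`` (minor arc) or ``-1`` (reflex arc).

Because the radii are explicit in ``Sigma``, the search reduces to a damped
Newton iteration in ``(Sigma, a)`` on (vertex balance, area constraint).
At ``d = 0`` the vertex balance decouples into a scalar equation for
``u = a Sigma`` that is solved semi-analytically and used to seed the
Newton polish and the finite-``d`` continuation.

Critical rim pores are index-1 saddles: the constrained Hessian in the
``(Rh, Re, Rp)`` chart has exactly one negative eigenvalue, whose
eigenvector is dominated by the HD radius ``Rh``; excluding ``Rh``
(mechanically pinning the HD rim) leaves a positive-definite Hessian, i.e.
a metastable pore.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .geometry import (
    MINOR,
    REFLEX,
    InfeasibleGeometryError,
    LineTensions,
    PoreGeometry,
    SystemSpec,
    _arc_derivs,
    build_geometry,
    conserved_area,
    free_energy,
    no_pore_reference,
)

__all__ = [
    "RegionClass",
    "SaddleResult",
    "NonConvergenceWarning",
    "find_saddle",
    "constrained_hessian",
    "laplace_check",
    "classify_region",
    "scan_phase_diagram",
    "brute_force_oracle",
]

GRAD_TOL = 1e-10  # stationarity tolerance in normalized units (Ah0 = pi, lambda_h = 1)

_BRANCHES = ((MINOR, MINOR), (REFLEX, MINOR), (MINOR, REFLEX))


class NonConvergenceWarning(UserWarning):
    """Saddle search did not converge and absence could not be verified."""


class RegionClass(str, Enum):
    """Classification of line-tension space by rim-pore behavior."""

    UNZIP_UNSTABLE = "UNZIP_UNSTABLE"          # lambda_e + lambda_p < lambda_h
    EDGE_UNBALANCED = "EDGE_UNBALANCED"        # lambda_e > lambda_p + lambda_h
    DETACH_PREFERRED = "DETACH_PREFERRED"      # lambda_p > lambda_e + lambda_h
    CRITICAL_RECESSED = "CRITICAL_RECESSED"
    CRITICAL_PROTRUDING_OUT = "CRITICAL_PROTRUDING_OUT"
    CRITICAL_PROTRUDING_IN = "CRITICAL_PROTRUDING_IN"


@dataclass
class SaddleResult:
    """A stationary rim pore with its stability analysis."""

    geometry: PoreGeometry
    Sigma: float
    F: float
    dF: float
    pore_area_fraction: float
    region: RegionClass
    hessian_eigenvalues: np.ndarray = field(default_factory=lambda: np.full(3, np.nan))
    hessian_eigenvalues_fixed_Rh: np.ndarray = field(default_factory=lambda: np.full(2, np.nan))
    unstable_eigenvector: np.ndarray = field(default_factory=lambda: np.full(3, np.nan))
    grad_norm: float = np.nan
    status: str = "converged"
    n_stationary_points: int = 1
    tensions: LineTensions | None = None
    system: SystemSpec | None = None


# ---------------------------------------------------------------------------
# constraint chart: F(Rh, Re, Rp) with a slaved to the area constraint
# ---------------------------------------------------------------------------


def _solve_a_near(Rh, Re, Rp, bow_e, bow_p, system, a_ref):
    """Constraint root in ``a`` closest to ``a_ref`` (for chart derivatives)."""
    amax = min(Re, Rp, 0.999 * Rh)
    if amax <= 0:
        raise InfeasibleGeometryError("degenerate interval")
    target = system.conserved_target
    grid = amax * np.linspace(1e-9, 1.0 - 1e-12, 400)
    res = conserved_area(Rh, Re, Rp, grid, bow_e, bow_p, system) - target
    sign = np.sign(res)
    flips = np.nonzero(sign[:-1] * sign[1:] <= 0)[0]
    if len(flips) == 0:
        raise InfeasibleGeometryError("no constraint root")
    mids = 0.5 * (grid[flips] + grid[flips + 1])
    k = flips[np.argmin(np.abs(mids - a_ref))]
    lo, hi, f_lo = grid[k], grid[k + 1], res[k]
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        f_mid = float(conserved_area(Rh, Re, Rp, mid, bow_e, bow_p, system) - target)
        if f_lo * f_mid <= 0:
            hi = mid
        else:
            lo, f_lo = mid, f_mid
        if hi - lo < 1e-15 * amax:
            break
    return 0.5 * (lo + hi)


def _chart_F_and_grad(Rh, Re, Rp, a, bow_e, bow_p, lt: LineTensions, system: SystemSpec):
    """Free energy and its analytic gradient in the (Rh, Re, Rp) chart.

    ``a`` must already satisfy the constraint for the given radii.
    """
    d, ch, cp = system.d, system.wall.c_h, system.wall.c_p
    dLh_dR, dLh_da, dsh_dR, dsh_da = _arc_derivs(Rh, a, reflex=True)
    dLe_dR, dLe_da, dse_dR, dse_da = _arc_derivs(Re, a, reflex=(bow_e == REFLEX))
    dLp_dR, dLp_da, dsp_dR, dsp_da = _arc_derivs(Rp, a, reflex=(bow_p == REFLEX))
    # constraint derivatives (conserved_area = seg_h + 2 seg_p + seg_e - walls)
    dC_dRh = dsh_dR - d * ch * dLh_dR
    dC_dRe = dse_dR
    dC_dRp = 2.0 * dsp_dR - d * cp * dLp_dR
    dC_da = (dsh_da + 2.0 * dsp_da + dse_da) - d * (ch * dLh_da + cp * dLp_da)
    dF_da = lt.lambda_h * dLh_da + lt.lambda_e * dLe_da + lt.lambda_p * dLp_da
    grad = np.array(
        [
            lt.lambda_h * dLh_dR - dF_da * dC_dRh / dC_da,
            lt.lambda_e * dLe_dR - dF_da * dC_dRe / dC_da,
            lt.lambda_p * dLp_dR - dF_da * dC_dRp / dC_da,
        ],
        dtype=float,
    )
    geom = build_geometry(Rh, Re, Rp, bow_e, bow_p, system, a=a)
    return free_energy(geom, lt), grad


def _chart_grad_at(x, bow_e, bow_p, lt, system, a_ref):
    a = _solve_a_near(x[0], x[1], x[2], bow_e, bow_p, system, a_ref)
    _, g = _chart_F_and_grad(x[0], x[1], x[2], a, bow_e, bow_p, lt, system)
    return g, a


# ---------------------------------------------------------------------------
# stationarity in (Sigma, a)
# ---------------------------------------------------------------------------


def _radii(Sigma, lt: LineTensions, system: SystemSpec):
    d, ch, cp = system.d, system.wall.c_h, system.wall.c_p
    Rh = lt.lambda_h / Sigma + ch * d
    Re = lt.lambda_e / Sigma
    Rp = lt.lambda_p / (2.0 * Sigma) + cp * d / 2.0
    return Rh, Re, Rp


def _vertex_balance(Rh, Re, Rp, a, bow_e, bow_p):
    se = 1.0 if bow_e == MINOR else -1.0
    sp = 1.0 if bow_p == MINOR else -1.0
    ce = math.sqrt(max(Re * Re - a * a, 0.0))
    cp_ = math.sqrt(max(Rp * Rp - a * a, 0.0))
    ch_ = math.sqrt(max(Rh * Rh - a * a, 0.0))
    return se * ce + 2.0 * sp * cp_ - ch_


def _stationarity_residual(x, bow_e, bow_p, lt, system):
    Sigma, a = x
    if Sigma <= 0:
        return None
    Rh, Re, Rp = _radii(Sigma, lt, system)
    if not (0 < a < min(Re, Rp, Rh)):
        return None
    e1 = _vertex_balance(Rh, Re, Rp, a, bow_e, bow_p)
    e2 = float(conserved_area(Rh, Re, Rp, a, bow_e, bow_p, system)) - system.conserved_target
    return np.array([e1, e2])


def _newton_sigma_a(x0, bow_e, bow_p, lt, system, tol=1e-13, max_iter=60):
    """Damped Newton on (vertex balance, area constraint); None on failure."""
    x = np.asarray(x0, dtype=float)
    r = _stationarity_residual(x, bow_e, bow_p, lt, system)
    if r is None:
        return None
    scale = np.array([1.0, system.Ah0])
    for _ in range(max_iter):
        if np.max(np.abs(r / scale)) < tol:
            return x
        J = np.empty((2, 2))
        for j in range(2):
            h = 1e-7 * max(abs(x[j]), 1e-3)
            xp, xm = x.copy(), x.copy()
            xp[j] += h
            xm[j] -= h
            rp = _stationarity_residual(xp, bow_e, bow_p, lt, system)
            rm = _stationarity_residual(xm, bow_e, bow_p, lt, system)
            if rp is None or rm is None:
                return None
            J[:, j] = (rp - rm) / (2 * h)
        try:
            step = np.linalg.solve(J, -r)
        except np.linalg.LinAlgError:
            return None
        lam = 1.0
        best = None
        for _ in range(25):
            xt = x + lam * step
            rt = _stationarity_residual(xt, bow_e, bow_p, lt, system)
            if rt is not None and np.max(np.abs(rt / scale)) < np.max(np.abs(r / scale)):
                best = (xt, rt)
                break
            lam *= 0.5
        if best is None:
            return x if np.max(np.abs(r / scale)) < 1e-9 else None
        x, r = best
    return x if np.max(np.abs(r / scale)) < 1e-9 else None


def _u_roots_d0(lt: LineTensions, bow_e, bow_p, n=4001):
    """Roots of the d=0 vertex balance in u = a*Sigma for one bow branch."""
    se = 1.0 if bow_e == MINOR else -1.0
    sp = 1.0 if bow_p == MINOR else -1.0
    le, lp, lh = lt.lambda_e, lt.lambda_p, lt.lambda_h
    umax = min(le, lp / 2.0, lh)

    def g(u):
        return (
            se * np.sqrt(np.maximum(le * le - u * u, 0.0))
            + sp * np.sqrt(np.maximum(lp * lp - 4.0 * u * u, 0.0))
            - np.sqrt(np.maximum(lh * lh - u * u, 0.0))
        )

    us = umax * np.linspace(1e-9, 1.0 - 1e-12, n)
    vals = g(us)
    roots = []
    sign = np.sign(vals)
    for k in np.nonzero(sign[:-1] * sign[1:] < 0)[0]:
        lo, hi = us[k], us[k + 1]
        flo = vals[k]
        for _ in range(100):
            mid = 0.5 * (lo + hi)
            fm = float(g(np.array([mid]))[0])
            if flo * fm <= 0:
                hi = mid
            else:
                lo, flo = mid, fm
        roots.append(0.5 * (lo + hi))
    # semicircular endpoint root (p- or e-arc exactly a half-circle); at the
    # endpoint one square root vanishes identically, so evaluate g there
    if abs(float(g(np.array([umax]))[0])) < 1e-9 * max(lh, 1.0):
        roots.append(umax)
    return roots


def _candidates_d0(lt: LineTensions, system: SystemSpec):
    """Stationary (Sigma, a, bows) triples at d = 0 via the scalar u-equation."""
    out = []
    for bow_e, bow_p in _BRANCHES:
        for u in _u_roots_d0(lt, bow_e, bow_p):
            # unit-tension-scale geometry: Sigma = 1
            Rh, Re, Rp = lt.lambda_h, lt.lambda_e, lt.lambda_p / 2.0
            if not (0 < u < min(Re, Rp, Rh) or math.isclose(u, min(Re, Rp))):
                continue
            a1 = min(u, min(Re, Rp) * (1 - 1e-14))
            area1 = float(conserved_area(Rh, Re, Rp, a1, bow_e, bow_p, SystemSpec(Ah0=system.Ah0)))
            if area1 <= 0:
                continue
            s = math.sqrt(system.Ah0 / area1)  # rescale to meet the constraint
            out.append((1.0 / s, a1 * s, bow_e, bow_p))
    return out


def _candidates_finite_d(lt: LineTensions, system: SystemSpec):
    """Continuation from d = 0 plus a direct Sigma-scan at the target d."""
    cands = []
    d = system.d
    n_steps = max(2, int(d / 0.05) + 2)
    for Sigma0, a0, bow_e, bow_p in _candidates_d0(lt, SystemSpec(Ah0=system.Ah0)):
        x = np.array([Sigma0, a0])
        ok = True
        for dk in np.linspace(0.0, d, n_steps)[1:]:
            sysk = SystemSpec(Ah0=system.Ah0, d=dk, wall=system.wall)
            xk = _newton_sigma_a(x, bow_e, bow_p, lt, sysk)
            if xk is None:
                ok = False
                break
            x = xk
        if ok:
            cands.append((x[0], x[1], bow_e, bow_p))
    # direct scan (captures saddles that only exist at finite d)
    Rh0 = system.Rh0
    for bow_e, bow_p in _BRANCHES:
        for Sigma in np.geomspace(0.2 / Rh0, 5.0 / Rh0, 80):
            Rh, Re, Rp = _radii(Sigma, lt, system)
            amax = min(Re, Rp, Rh) * (1 - 1e-9)
            a_grid = amax * np.linspace(1e-6, 1.0, 200)
            bal = np.array([_vertex_balance(Rh, Re, Rp, a, bow_e, bow_p) for a in a_grid])
            sgn = np.sign(bal)
            for k in np.nonzero(sgn[:-1] * sgn[1:] < 0)[0]:
                a0 = 0.5 * (a_grid[k] + a_grid[k + 1])
                x = _newton_sigma_a(np.array([Sigma, a0]), bow_e, bow_p, lt, system)
                if x is not None:
                    cands.append((x[0], x[1], bow_e, bow_p))
    return cands


def _deterministic_seeds(lt: LineTensions, system: SystemSpec):
    """Eight fixed multi-start seeds spanning the plausible (Sigma, a) range."""
    Rh0 = system.Rh0
    seeds = []
    for fs in (0.6, 0.9, 1.2, 1.6):
        for fa in (0.25, 0.6):
            Sigma = fs / Rh0
            Rh, Re, Rp = _radii(Sigma, lt, system)
            seeds.append((Sigma, fa * min(Re, Rp, Rh)))
    return seeds


def _analytic_exclusion(lt: LineTensions, system: SystemSpec) -> bool:
    """True when the boundary inequalities rule out any critical rim pore.

    At the default equal wall coefficients the unzipping and detachment
    boundaries are d-independent; the edge-unbalance boundary only moves
    outward with d, so it can exclude saddles only at d = 0.
    """
    le, lp, lh = lt.lambda_e, lt.lambda_p, lt.lambda_h
    if system.wall.c_h == system.wall.c_p or system.d == 0:
        if le + lp <= lh or lp >= le + lh:
            return True
    if system.d == 0 and le >= lp + lh:
        return True
    return False


def _classify_geometry(geom: PoreGeometry) -> RegionClass:
    if geom.bow_p == REFLEX or math.isclose(geom.a, geom.Rp, rel_tol=1e-6):
        return RegionClass.CRITICAL_PROTRUDING_OUT
    if geom.bow_e == REFLEX or math.isclose(geom.a, geom.Re, rel_tol=1e-6):
        return RegionClass.CRITICAL_PROTRUDING_IN
    return RegionClass.CRITICAL_RECESSED


def find_saddle(
    lt: LineTensions,
    system: SystemSpec | None = None,
    compute_hessian: bool = True,
) -> SaddleResult | None:
    """Locate the critical rim pore for the given tensions, if one exists.

    Returns ``None`` where no saddle point exists (the blank regions of the
    phase diagram).  Non-convergence that cannot be confirmed as absence
    raises a :class:`NonConvergenceWarning` and also returns ``None``.
    Among multiple index-1 stationary points the one with the smallest pore
    area fraction is reported (the critical pore).
    """
    system = system or SystemSpec()
    lt = lt.normalized()
    if system.d == 0:
        raw = _candidates_d0(lt, system)
        raw = [
            (c if (p := _newton_sigma_a(np.array(c[:2]), c[2], c[3], lt, system)) is None
             else (p[0], p[1], c[2], c[3]))
            for c in raw
        ]
    else:
        raw = _candidates_finite_d(lt, system)
        if not raw:
            for bow_e, bow_p in _BRANCHES:
                for seed in _deterministic_seeds(lt, system):
                    x = _newton_sigma_a(np.array(seed), bow_e, bow_p, lt, system)
                    if x is not None:
                        raw.append((x[0], x[1], bow_e, bow_p))
    # deduplicate
    uniq: list[tuple] = []
    for c in raw:
        if not any(
            abs(c[0] - u[0]) < 1e-7 and abs(c[1] - u[1]) < 1e-7 and c[2:] == u[2:]
            for u in uniq
        ):
            uniq.append(c)

    results = []
    for Sigma, a, bow_e, bow_p in uniq:
        try:
            Rh, Re, Rp = _radii(Sigma, lt, system)
            a = min(a, min(Re, Rp) * (1 - 1e-15))
            geom = build_geometry(Rh, Re, Rp, bow_e, bow_p, system, a=a)
            res = _make_result(geom, Sigma, lt, system, compute_hessian)
        except (InfeasibleGeometryError, ValueError):
            continue
        if res is not None:
            results.append(res)
    if not results:
        if not _analytic_exclusion(lt, system):
            warnings.warn(
                f"no saddle found at ratios {lt.ratios}, d={system.d}; "
                "absence not verified analytically",
                NonConvergenceWarning,
            )
        return None
    results.sort(key=lambda r: r.pore_area_fraction)
    best = results[0]
    best.n_stationary_points = len(results)
    return best


def _make_result(geom, Sigma, lt, system, compute_hessian) -> SaddleResult | None:
    F = free_energy(geom, lt)
    _, F0 = no_pore_reference(system, lt)
    frac = geom.A_pore / system.Ah0
    if not (0 < frac < 1):
        return None
    try:
        _, grad = _chart_F_and_grad(
            geom.Rh, geom.Re, geom.Rp, geom.a, geom.bow_e, geom.bow_p, lt, system
        )
        grad_norm = float(np.linalg.norm(grad))
    except (FloatingPointError, ZeroDivisionError):
        grad_norm = np.nan
    res = SaddleResult(
        geometry=geom,
        Sigma=Sigma,
        F=F,
        dF=F - F0,
        pore_area_fraction=frac,
        region=_classify_geometry(geom),
        grad_norm=grad_norm,
        tensions=lt,
        system=system,
    )
    # exactly semicircular arcs (a = Rp or a = Re) sit at a coordinate
    # singularity of the chart; skip the curvature analysis there
    near_singular = geom.a > (1.0 - 1e-8) * min(geom.Re, geom.Rp)
    if compute_hessian and not near_singular:
        try:
            evals, evecs = constrained_hessian(geom, lt, system, fix_Rh=False)
            if np.sum(evals < 0) != 1:
                return None  # not index-1: not a critical pore
            res.hessian_eigenvalues = evals
            res.unstable_eigenvector = evecs[:, 0]
            evals_f, _ = constrained_hessian(geom, lt, system, fix_Rh=True)
            res.hessian_eigenvalues_fixed_Rh = evals_f
        except (InfeasibleGeometryError, ValueError, np.linalg.LinAlgError):
            res.status = "converged-hessian-singular"
    elif near_singular:
        res.status = "converged-hessian-singular"
    return res


# ---------------------------------------------------------------------------
# stability analysis
# ---------------------------------------------------------------------------


def constrained_hessian(
    geom: PoreGeometry,
    lt: LineTensions,
    system: SystemSpec | None = None,
    fix_Rh: bool = False,
    step: float = 1e-5,
):
    """Hessian eigensystem of ``F`` in the constrained ``(Rh, Re, Rp)`` chart.

    Central finite differences of the analytic chart gradient; requires a
    stationary input geometry (raises ``ValueError`` otherwise).  With
    ``fix_Rh`` the HD radius is excluded (2x2 block over ``Re, Rp``),
    emulating a mechanically pinned rim.
    """
    system = system or SystemSpec()
    lt = lt.normalized()
    x0 = np.array([geom.Rh, geom.Re, geom.Rp])
    _, g0 = _chart_F_and_grad(
        geom.Rh, geom.Re, geom.Rp, geom.a, geom.bow_e, geom.bow_p, lt, system
    )
    scale = free_energy(geom, lt) / system.Rh0
    if np.linalg.norm(g0) > 1e-5 * scale:
        raise ValueError(
            f"geometry is not stationary (|grad| = {np.linalg.norm(g0):.3e})"
        )
    H = np.empty((3, 3))
    for j in range(3):
        h = step * max(x0[j], 0.1 * system.Rh0)
        xp, xm = x0.copy(), x0.copy()
        xp[j] += h
        xm[j] -= h
        gp, _ = _chart_grad_at(xp, geom.bow_e, geom.bow_p, lt, system, geom.a)
        gm, _ = _chart_grad_at(xm, geom.bow_e, geom.bow_p, lt, system, geom.a)
        H[:, j] = (gp - gm) / (2 * h)
    H = 0.5 * (H + H.T)
    if fix_Rh:
        evals, evecs = np.linalg.eigh(H[1:, 1:])
        return evals, evecs
    return np.linalg.eigh(H)


def laplace_check(result: SaddleResult) -> tuple[float, np.ndarray]:
    """Membrane tension and the three Laplace-relation residuals.

    ``Sigma`` is extracted from the HD relation; the residuals are
    ``|Re Sigma / lambda_e - 1|``, ``|(2 Rp - c_p d) Sigma / lambda_p - 1|``
    and ``|(Rh - c_h d) Sigma / lambda_h - 1|`` (zero by construction for
    the last).  All must vanish to solver tolerance at a converged saddle.
    """
    lt, system, geom = result.tensions, result.system, result.geometry
    d, ch, cp = system.d, system.wall.c_h, system.wall.c_p
    Sigma = lt.lambda_h / (geom.Rh - ch * d)
    res = np.array(
        [
            abs(geom.Re * Sigma / lt.lambda_e - 1.0),
            abs((2.0 * geom.Rp - cp * d) * Sigma / lt.lambda_p - 1.0),
            abs((geom.Rh - ch * d) * Sigma / lt.lambda_h - 1.0),
        ]
    )
    return Sigma, res


# ---------------------------------------------------------------------------
# region classification and phase diagram
# ---------------------------------------------------------------------------


def classify_region(lt: LineTensions, system: SystemSpec | None = None) -> RegionClass:
    """Assign the line-tension point to one of the six behavior classes.

    At ``d = 0`` the boundaries are the analytic inequalities; the boundary
    between recessed and protruding-inward pores is the semicircular-edge
    separatrix ``3 lambda_e^2 = lambda_p^2 - lambda_h^2``.  At finite ``d``
    the critical-region boundaries are determined by saddle existence and
    the subclass is read off the found geometry.
    """
    system = system or SystemSpec()
    lt = lt.normalized()
    le, lp, lh = lt.lambda_e, lt.lambda_p, lt.lambda_h
    if system.d > 0:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", NonConvergenceWarning)
            res = find_saddle(lt, system, compute_hessian=False)
        if res is not None:
            return _classify_geometry(res.geometry)
    if le + lp < lh:
        return RegionClass.UNZIP_UNSTABLE
    if le > lp + lh:
        return RegionClass.EDGE_UNBALANCED
    if lp > le + lh:
        return RegionClass.DETACH_PREFERRED
    if system.d > 0:
        # critical inequalities hold but no saddle was found: nearest boundary
        margins = {
            RegionClass.UNZIP_UNSTABLE: le + lp - lh,
            RegionClass.EDGE_UNBALANCED: lp + lh - le,
            RegionClass.DETACH_PREFERRED: le + lh - lp,
        }
        return min(margins, key=margins.get)
    if le >= lh:  # lambda_e = lambda_h is the onset of the outward bulge
        return RegionClass.CRITICAL_PROTRUDING_OUT
    if lp > lh and 3.0 * le * le < lp * lp - lh * lh:
        return RegionClass.CRITICAL_PROTRUDING_IN
    return RegionClass.CRITICAL_RECESSED


def scan_phase_diagram(
    lambda_e_values,
    lambda_p_values,
    system: SystemSpec | None = None,
    compute_hessian: bool = True,
) -> pd.DataFrame:
    """Sweep a rectangular grid of tension ratios; one row per cell.

    Rows are emitted row-major (``lambda_e`` outer, ``lambda_p`` inner).
    Per-cell failures are recorded in the ``status`` column and never abort
    the scan.
    """
    system = system or SystemSpec()
    rows = []
    for le in np.atleast_1d(lambda_e_values):
        for lp in np.atleast_1d(lambda_p_values):
            row = {
                "lambda_e": float(le),
                "lambda_p": float(lp),
                "region": None,
                "area_fraction": np.nan,
                "Sigma_Rh0_over_lambda_h": np.nan,
                "eig_min": np.nan,
                "eig_min_fixed_Rh": np.nan,
                "status": "absent",
            }
            try:
                lt = LineTensions(float(le), float(lp))
                row["region"] = classify_region(lt, system).value
                with warnings.catch_warnings(record=True) as caught:
                    warnings.simplefilter("always", NonConvergenceWarning)
                    res = find_saddle(lt, system, compute_hessian=compute_hessian)
                if res is not None:
                    row["area_fraction"] = res.pore_area_fraction
                    row["Sigma_Rh0_over_lambda_h"] = res.Sigma * system.Rh0
                    row["eig_min"] = float(res.hessian_eigenvalues[0])
                    row["eig_min_fixed_Rh"] = float(res.hessian_eigenvalues_fixed_Rh[0])
                    row["status"] = "converged"
                elif any(issubclass(w.category, NonConvergenceWarning) for w in caught):
                    row["status"] = "absent-with-warning"
            except Exception as exc:  # per-cell failures must not abort
                row["status"] = f"error: {exc}"
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# brute-force grid oracle (test instrument)
# ---------------------------------------------------------------------------


def _vectorized_half_width(Rh, Re, Rp, bow_e, bow_p, system, n_probe=32, n_bisect=60):
    """Constraint root in ``a`` for flat arrays of radii; NaN where none."""
    amax = np.minimum(np.minimum(Re, Rp), 0.999 * Rh)
    target = system.conserved_target
    fracs = np.linspace(1e-9, 1.0 - 1e-12, n_probe)
    res = np.empty((n_probe, Rh.size))
    for i, f in enumerate(fracs):
        res[i] = conserved_area(Rh, Re, Rp, f * amax, bow_e, bow_p, system) - target
    sgn = np.sign(res)
    flip = sgn[:-1] * sgn[1:] <= 0
    has = flip.any(axis=0)
    first = np.argmax(flip, axis=0)
    lo = fracs[first] * amax
    hi = fracs[first + 1] * amax
    f_lo = res[first, np.arange(Rh.size)]
    for _ in range(n_bisect):
        mid = 0.5 * (lo + hi)
        f_mid = conserved_area(Rh, Re, Rp, mid, bow_e, bow_p, system) - target
        left = f_lo * f_mid <= 0
        hi = np.where(left, mid, hi)
        lo = np.where(left, lo, mid)
        f_lo = np.where(left, f_lo, f_mid)
    a = 0.5 * (lo + hi)
    a[~has] = np.nan
    return a


def _oracle_F_grid(axes, bow_e, bow_p, lt, system):
    Rh, Re, Rp = np.meshgrid(*axes, indexing="ij")
    shape = Rh.shape
    Rh, Re, Rp = Rh.ravel(), Re.ravel(), Rp.ravel()
    a = _vectorized_half_width(Rh, Re, Rp, bow_e, bow_p, system)
    ok = np.isfinite(a)
    F = np.full(Rh.size, np.nan)
    if ok.any():
        reflex_e, reflex_p = bow_e == REFLEX, bow_p == REFLEX
        from .geometry import _arc_quantities

        L_h, _, _ = _arc_quantities(Rh[ok], a[ok], reflex=True)
        L_e, _, _ = _arc_quantities(Re[ok], a[ok], reflex=reflex_e)
        L_p, _, _ = _arc_quantities(Rp[ok], a[ok], reflex=reflex_p)
        F[ok] = lt.lambda_h * L_h + lt.lambda_e * L_e + lt.lambda_p * L_p
    return F.reshape(shape), a.reshape(shape)


def _discrete_saddle_index(F, spacings, a_grid=None):
    """Grid index of the best discrete index-1 stationary point, or None.

    Points where the constraint root ``a`` kinks (the chart folds onto a
    different solution branch, producing spurious creases in ``F``) are
    masked out via a second-difference jump test on ``a``.
    """
    smooth = np.ones(F.shape, dtype=bool)
    if a_grid is not None:
        scale = np.nanmax(a_grid) if np.isfinite(a_grid).any() else 1.0
        for ax in range(3):
            d1 = 0.5 * np.abs(np.roll(a_grid, -1, axis=ax) - np.roll(a_grid, 1, axis=ax))
            d2 = np.abs(
                np.roll(a_grid, -1, axis=ax) - 2 * a_grid + np.roll(a_grid, 1, axis=ax)
            )
            smooth &= d2 <= 0.5 * d1 + 1e-3 * scale
    g2 = np.zeros_like(F)
    hess_diag = []
    for ax, h in enumerate(spacings):
        gp = (np.roll(F, -1, axis=ax) - np.roll(F, 1, axis=ax)) / (2 * h)
        g2 = g2 + gp * gp
        hess_diag.append((np.roll(F, -1, axis=ax) - 2 * F + np.roll(F, 1, axis=ax)) / h**2)
    # mixed second derivatives
    def mixed(ax1, ax2):
        s = lambda k1, k2: np.roll(np.roll(F, k1, axis=ax1), k2, axis=ax2)
        return (s(-1, -1) - s(-1, 1) - s(1, -1) + s(1, 1)) / (
            4 * spacings[ax1] * spacings[ax2]
        )

    H = np.zeros(F.shape + (3, 3))
    for i in range(3):
        H[..., i, i] = hess_diag[i]
    H[..., 0, 1] = H[..., 1, 0] = mixed(0, 1)
    H[..., 0, 2] = H[..., 2, 0] = mixed(0, 2)
    H[..., 1, 2] = H[..., 2, 1] = mixed(1, 2)
    valid = np.isfinite(g2) & np.all(np.isfinite(H), axis=(-2, -1)) & smooth
    # exclude wrap-around and boundary cells
    interior = np.zeros_like(valid)
    interior[1:-1, 1:-1, 1:-1] = True
    valid &= interior
    if not valid.any():
        return None
    evals = np.full(F.shape + (3,), np.nan)
    evals[valid] = np.linalg.eigvalsh(H[valid])
    index1 = valid & (np.sum(evals < 0, axis=-1) == 1)
    if not index1.any():
        return None
    g2m = np.where(index1, g2, np.inf)
    return np.unravel_index(np.argmin(g2m), F.shape)


def _discrete_g_H(F, idx, spacings):
    """Central-difference gradient and Hessian of the grid data at ``idx``."""
    i, j, k = idx
    g = np.empty(3)
    H = np.empty((3, 3))
    s = spacings
    g[0] = (F[i + 1, j, k] - F[i - 1, j, k]) / (2 * s[0])
    g[1] = (F[i, j + 1, k] - F[i, j - 1, k]) / (2 * s[1])
    g[2] = (F[i, j, k + 1] - F[i, j, k - 1]) / (2 * s[2])
    H[0, 0] = (F[i + 1, j, k] - 2 * F[i, j, k] + F[i - 1, j, k]) / s[0] ** 2
    H[1, 1] = (F[i, j + 1, k] - 2 * F[i, j, k] + F[i, j - 1, k]) / s[1] ** 2
    H[2, 2] = (F[i, j, k + 1] - 2 * F[i, j, k] + F[i, j, k - 1]) / s[2] ** 2
    H[0, 1] = H[1, 0] = (
        F[i + 1, j + 1, k] - F[i + 1, j - 1, k] - F[i - 1, j + 1, k] + F[i - 1, j - 1, k]
    ) / (4 * s[0] * s[1])
    H[0, 2] = H[2, 0] = (
        F[i + 1, j, k + 1] - F[i + 1, j, k - 1] - F[i - 1, j, k + 1] + F[i - 1, j, k - 1]
    ) / (4 * s[0] * s[2])
    H[1, 2] = H[2, 1] = (
        F[i, j + 1, k + 1] - F[i, j + 1, k - 1] - F[i, j - 1, k + 1] + F[i, j - 1, k - 1]
    ) / (4 * s[1] * s[2])
    return g, H


def brute_force_oracle(
    lt: LineTensions,
    system: SystemSpec | None = None,
    resolution: int = 50,
    levels: int = 4,
    branches=None,
) -> SaddleResult | None:
    """Exhaustive grid search for the critical rim pore (test instrument).

    Evaluates ``F`` on an ``(Rh, Re, Rp)`` grid with ``a`` solved per point,
    picks the discrete index-1 stationary point by neighborhood analysis
    and zooms in ``levels`` times.  Slower but algorithmically independent
    of :func:`find_saddle`.
    """
    system = system or SystemSpec()
    lt = lt.normalized()
    if branches is None:
        cls = classify_region(lt, SystemSpec(Ah0=system.Ah0, wall=system.wall))
        branches = {
            RegionClass.CRITICAL_RECESSED: [(MINOR, MINOR)],
            RegionClass.CRITICAL_PROTRUDING_IN: [(REFLEX, MINOR)],
            RegionClass.CRITICAL_PROTRUDING_OUT: [(MINOR, REFLEX)],
        }.get(cls, list(_BRANCHES))
    Rh0 = system.Rh0
    d, ch, cp = system.d, system.wall.c_h, system.wall.c_p
    best = None
    for bow_e, bow_p in branches:
        # the feasible set is a thin slab in Rh (the pore-free limit pins
        # Rh_max at Rh0 for minor p-arcs), so the Rh axis gets tight bounds
        # and double resolution on the first level
        rh_hi = 1.0005 * Rh0 if bow_p == MINOR else 1.35 * Rh0
        centers = np.array(
            [np.nan, lt.lambda_e * Rh0, lt.lambda_p * Rh0 / 2.0 + cp * d / 2.0]
        )
        los = np.array([0.75 * Rh0, max(0.45 * centers[1], 1e-3 * Rh0),
                        max(0.45 * centers[2], 1e-3 * Rh0)])
        his = np.array([rh_hi, 1.7 * centers[1], 1.7 * centers[2]])
        pt = None
        gnorm = np.inf
        for level in range(levels):
            ns = [2 * resolution if level == 0 else resolution, resolution, resolution]
            axes = [np.linspace(lo, hi, n) for lo, hi, n in zip(los, his, ns)]
            spacings = np.array([ax[1] - ax[0] for ax in axes])
            F, a_grid = _oracle_F_grid(axes, bow_e, bow_p, lt, system)
            idx = _discrete_saddle_index(F, spacings, a_grid)
            if idx is None:
                break
            pt = np.array([axes[k][idx[k]] for k in range(3)])
            a_ref = float(a_grid[idx])
            # sub-grid Newton correction from the discrete stencil (the
            # saddle sits in a strongly anisotropic valley; the raw argmin
            # localizes poorly along the soft mode)
            g, H = _discrete_g_H(F, idx, spacings)
            gnorm = float(np.linalg.norm(g))
            try:
                delta = np.linalg.solve(H, -g)
            except np.linalg.LinAlgError:
                delta = np.zeros(3)
            delta = np.clip(delta, -40 * spacings, 40 * spacings)
            pt = pt + delta
            half = np.maximum(3 * spacings, 1.5 * np.abs(delta))
            los = np.maximum(pt - half, 1e-4 * Rh0)
            his = pt + half
        if pt is None:
            continue

        def _F_point(x, a_near):
            a_x = _solve_a_near(x[0], x[1], x[2], bow_e, bow_p, system, a_near)
            gm = build_geometry(x[0], x[1], x[2], bow_e, bow_p, system, a=a_x)
            return free_energy(gm, lt), a_x

        # validate the corrected point with its own small stencil: genuine
        # saddles have a vanishing gradient there, chart-fold creases do not
        _, F0_ref = no_pore_reference(system, lt)
        try:
            g_fin = np.empty(3)
            for i in range(3):
                h = max(spacings[i] / 4.0, 1e-7 * Rh0)
                xp, xm = pt.copy(), pt.copy()
                xp[i] += h
                xm[i] -= h
                fp, _ = _F_point(xp, a_ref)
                fm, _ = _F_point(xm, a_ref)
                g_fin[i] = (fp - fm) / (2 * h)
            if np.linalg.norm(g_fin) * Rh0 / F0_ref > 1e-3:
                continue  # crease artifact of the folded chart, not a saddle
            a = _solve_a_near(pt[0], pt[1], pt[2], bow_e, bow_p, system, a_ref)
            geom = build_geometry(pt[0], pt[1], pt[2], bow_e, bow_p, system, a=a)
        except (InfeasibleGeometryError, ValueError):
            continue
        Sigma = lt.lambda_h / (geom.Rh - ch * d)
        F_val = free_energy(geom, lt)
        _, F0 = no_pore_reference(system, lt)
        cand = SaddleResult(
            geometry=geom,
            Sigma=Sigma,
            F=F_val,
            dF=F_val - F0,
            pore_area_fraction=geom.A_pore / system.Ah0,
            region=_classify_geometry(geom),
            status="oracle",
            tensions=lt,
            system=system,
        )
        if best is None or cand.pore_area_fraction < best.pore_area_fraction:
            best = cand
    return best
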