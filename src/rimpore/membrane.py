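"""Physical membrane observables from SCFT solutions.

Workflows built on the :mod:`rimpore.scft` engine:

* tensionless flat bilayer (1D): hydrophobic thickness ``D``, area per
  lipid, the tensionless lipid chemical potential ``mu*``;
* bending modulus ``kappa``: quadratic fit of the excess free energy per
  area of cylindrically bent, position-pinned tensionless bilayers;
* monolayer spontaneous curvature ``c0``: first moment of the lateral
  stress profile across one monolayer, divided by the monolayer bending
  modulus ``kappa/2``;
* line tensions ``lambda_e`` (membrane edge), ``lambda_h`` (three-bilayer
  junction) and ``lambda_p`` (fusion-pore cross-section) from 2D
  grand-canonical excess free energies at the tensionless chemical
  potential, with a pressure-anisotropy integral as an independent
  cross-check;
* the zero-tension pore fate rule: a rim pore on a tensionless junction
  grows when ``lambda_e + lambda_p < lambda_h`` and shrinks otherwise.

All energies are in the invariant-polymerization-index scale per R0-based
units (lengths R0, areas R0^2): line tensions carry units of energy/R0,
``kappa`` of energy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .scft import (
    ChainModel,
    FieldState,
    Grid,
    SCFTNonConvergence,
    bulk_grand_potential_density,
    free_energy_functional,
    propagate_chain,
    solve_scft,
    stress_difference_profile,
    _deriv4,
    _simpson_weights,
)

__all__ = [
    "MembraneProps",
    "NoBilayerError",
    "FlatBilayer",
    "tensionless_bilayer",
    "bending_modulus",
    "monolayer_spontaneous_curvature",
    "line_tension",
    "line_tension_ratios",
    "zero_tension_pore_fate",
    "membrane_properties",
]

# default numerical workhorse settings (documented in the methods note)
GRID_SPACING = 1.0 / 16.0
BOX_1D = 8.0
BOX_2D = (12.0, 4.5)  # lower half of the mirror-symmetric cross-section
DS_2D = 0.01
PIN_STIFFNESS = 0.2  # harmonic pinning of the bent bilayer's radial position


class NoBilayerError(RuntimeError):
    """The seeded bilayer relaxed to a homogeneous state (chiN too small)."""


@dataclass
class MembraneProps:
    """Bundle of membrane observables at one (f, chiN, d)."""

    D: float
    Sigma: float
    kappa: float
    c0: float                      # 1/R0
    lambda_e: float
    lambda_h: float
    lambda_p: float
    d: float                       # half-separation used for h and p, in R0
    f: float
    chiN: float

    @property
    def c0_D(self) -> float:
        return self.c0 * self.D

    @property
    def ratios(self) -> tuple[float, float]:
        return (self.lambda_e / self.lambda_h, self.lambda_p / self.lambda_h)


# ---------------------------------------------------------------------------
# flat tensionless bilayer
# ---------------------------------------------------------------------------


@dataclass
class FlatBilayer:
    chain: ChainModel
    grid: Grid
    state: FieldState
    mu_star: float        # tensionless lipid chemical potential (z_s = 1 gauge)
    D: float
    area_per_lipid: float
    Sigma: float


def _measure_thickness(phi_B: np.ndarray, x: np.ndarray) -> tuple[float, float]:
    """Hydrophobic width at half the central plateau of the tail density."""
    plateau = float(phi_B.max())
    half = plateau / 2.0
    idx = np.where(phi_B >= half)[0]
    if len(idx) < 2 or idx[0] == 0 or idx[-1] == len(x) - 1:
        raise NoBilayerError("tail density has no localized plateau")
    i0, i1 = idx[0], idx[-1]
    xl = np.interp(half, [phi_B[i0 - 1], phi_B[i0]], [x[i0 - 1], x[i0]])
    xr = np.interp(half, [phi_B[i1 + 1], phi_B[i1]], [x[i1 + 1], x[i1]])
    return float(xr - xl), plateau


def _grand_excess(state: FieldState) -> float:
    """Grand potential of a state minus the matched uniform bulk.

    Uses the state's own activities; subtracts the external pinning energy
    when present, so the value is the intrinsic excess.
    """
    om = free_energy_functional(
        FieldState(
            grid=state.grid,
            chain=state.chain,
            w_A=state.w_A,
            w_B=state.w_B,
            ensemble="grand",
            z_l=state.z_l,
            z_s=state.z_s,
            external_lipid=state.external_lipid,
        )
    )
    if state.external_lipid is not None:
        st = state
        if st.phi_A is None:
            st.refresh()
        om -= float(
            np.sum(st.external_lipid * (st.phi_A + st.phi_B) * st.grid.cell_volumes)
        )
    om_b, _ = bulk_grand_potential_density(state.chain, math.log(state.z_l), state.z_s)
    return om - om_b * state.grid.volume


def tensionless_bilayer(
    chain: ChainModel,
    box: float = BOX_1D,
    spacing: float = GRID_SPACING,
    tol: float = 1e-8,
) -> FlatBilayer:
    """Solve the 1D flat bilayer and tune the lipid chemical potential to
    zero lateral tension (secant iteration on the excess grand potential
    per area).  Raises :class:`NoBilayerError` below the self-assembly
    threshold."""
    n = int(round(box / spacing))
    grid = Grid(lengths=(box,), shape=(n,), bc=("neumann",))
    x = grid.axis_coords(0)
    dcore = np.abs(x - box / 2) - 0.55
    phi_seed = 0.96 * 0.5 * (1 - np.tanh(dcore / 0.12))
    st = FieldState(
        grid=grid,
        chain=chain,
        w_A=chain.chiN * phi_seed,
        w_B=chain.chiN * (1 - phi_seed),
        ensemble="canonical",
        phi_lipid_bar=0.18,
    )
    sol = solve_scft(st, tol=1e-8, max_iter=4000, raise_on_failure=False)
    s = sol.state
    if float(s.phi_B.max() - s.phi_B.min()) < 0.2:
        raise NoBilayerError(
            f"no bilayer self-assembles at chiN={chain.chiN}, f={chain.f}"
        )
    gauge = -math.log(s.z_s) / chain.alpha  # move to the z_s = 1 gauge
    mu = math.log(s.z_l) + gauge
    w_B, w_A = s.w_B + gauge, s.w_A + gauge

    def sigma_at(mu_try, w_B, w_A):
        stg = FieldState(
            grid=grid, chain=chain, w_A=w_A.copy(), w_B=w_B.copy(),
            ensemble="grand", z_l=math.exp(mu_try), z_s=1.0,
        )
        solg = solve_scft(stg, tol=tol, max_iter=4000, raise_on_failure=False)
        return _grand_excess(solg.state), solg.state

    mu_a, mu_b = mu, mu + 0.3
    S_a, st_a = sigma_at(mu_a, w_B, w_A)
    S_b, st_b = sigma_at(mu_b, st_a.w_B, st_a.w_A)
    for _ in range(12):
        if abs(S_b - S_a) < 1e-15:
            break
        mu_c = mu_b - S_b * (mu_b - mu_a) / (S_b - S_a)
        S_c, st_c = sigma_at(mu_c, st_b.w_B, st_b.w_A)
        mu_a, S_a = mu_b, S_b
        mu_b, S_b, st_b = mu_c, S_c, st_c
        if abs(S_c) < 1e-8:
            break
    D, _ = _measure_thickness(st_b.phi_B, x)
    lipid_per_area = float(np.sum(st_b.phi_A + st_b.phi_B) * grid.spacing[0])
    return FlatBilayer(
        chain=chain, grid=grid, state=st_b, mu_star=mu_b, D=D,
        area_per_lipid=2.0 / lipid_per_area, Sigma=S_b,
    )


# ---------------------------------------------------------------------------
# bending modulus (cylindrically bent, position-pinned bilayers)
# ---------------------------------------------------------------------------


def bending_modulus(
    chain: ChainModel,
    flat: FlatBilayer | None = None,
    radii: tuple[float, ...] = (25.0, 12.5, 25.0 / 3.0, 6.25, 5.0),
    spacing: float = 1.0 / 32.0,
    return_fit: bool = False,
):
    """Bending modulus from the excess free energy of bent bilayers.

    Each bilayer is wrapped on a cylinder of radius ``Rc`` (1D radial
    SCFT at the flat tensionless chemical potential).  The radial drift of
    a tensionless cylinder is a soft mode with a weak outward force, so
    the position is pinned by a weak harmonic external potential on the
    lipids; the pinning energy is subtracted exactly and the realized
    center radius is measured from the profile.  ``kappa`` is the
    quadratic coefficient of E/A vs curvature^2 (a quartic term absorbs
    the higher-order residue).
    """
    flat = flat or tensionless_bilayer(chain)
    box = flat.grid.lengths[0]
    n = int(round(box / spacing))
    xf = flat.grid.axis_coords(0)

    def pinned_run(r0: float):
        grid = Grid(
            lengths=(box,), shape=(n,), bc=("neumann",),
            geometry="radial", r0=r0,
        )
        r = grid.axis_coords(0)
        center = r0 + box / 2
        w_B = np.interp(r - grid.r0, xf, flat.state.w_B)
        w_A = np.interp(r - grid.r0, xf, flat.state.w_A)
        pin = 0.5 * PIN_STIFFNESS * (r - center) ** 2
        st = FieldState(
            grid=grid, chain=chain, w_A=w_A, w_B=w_B,
            ensemble="grand", z_l=math.exp(flat.mu_star), z_s=1.0,
            external_lipid=pin,
        )
        sol = solve_scft(st, tol=1e-8, max_iter=4000, raise_on_failure=False)
        Rm = _bilayer_center(sol.state.phi_B, r)
        return _grand_excess(sol.state) / (2.0 * math.pi * Rm), Rm

    # flat reference in the same radial scheme (same grid, stepper and pin):
    # its residual tension and pin-distortion energy cancel in the
    # subtraction below, isolating the pure bending cost
    sigma_ref, _ = pinned_run(1e6)
    data = []
    for Rc in radii:
        E_per_A, Rm = pinned_run(Rc - box / 2)
        data.append((1.0 / Rm, E_per_A - sigma_ref))
    c2 = np.array([c * c for c, _ in data])
    e = np.array([E for _, E in data])
    A = np.vstack([c2, c2 * c2]).T
    coef, *_ = np.linalg.lstsq(A, e, rcond=None)
    kappa = 2.0 * coef[0]
    pred = A @ coef
    ss_tot = float(np.sum((e - e.mean()) ** 2))
    r2 = 1.0 - float(np.sum((e - pred) ** 2)) / ss_tot if ss_tot > 0 else 1.0
    if return_fit:
        return kappa, {"curvatures2": c2, "energy_per_area": e, "r2": r2}
    return kappa


def _bilayer_center(phi_B: np.ndarray, r: np.ndarray) -> float:
    plateau = phi_B.max()
    half = plateau / 2.0
    idx = np.where(phi_B >= half)[0]
    i0, i1 = idx[0], idx[-1]
    rl = np.interp(half, [phi_B[i0 - 1], phi_B[i0]], [r[i0 - 1], r[i0]])
    rr = np.interp(half, [phi_B[i1 + 1], phi_B[i1]], [r[i1 + 1], r[i1]])
    return 0.5 * (rl + rr)


# ---------------------------------------------------------------------------
# monolayer spontaneous curvature
# ---------------------------------------------------------------------------


def monolayer_torque(chain: ChainModel, flat: FlatBilayer | None = None) -> float:
    """First moment of the lateral stress across one monolayer.

    The stress profile s(z) = P_T - P_N of the flat tensionless bilayer is
    integrated as ``tau = int_(z>z_mid) (z - z_mid) s(z) dz`` with the
    bilayer midplane ``z_mid`` from the tail-density plateau.  The full
    bilayer moment vanishes by mirror symmetry; the monolayer moment is
    the bending torque whose sign and magnitude set the spontaneous
    curvature.
    """
    flat = flat or tensionless_bilayer(chain)
    # refine the profile for the stress integrals
    n = 2 * flat.grid.shape[0]
    grid = Grid(lengths=flat.grid.lengths, shape=(n,), bc=("neumann",))
    x = grid.axis_coords(0)
    w_B = np.interp(x, flat.grid.axis_coords(0), flat.state.w_B)
    w_A = np.interp(x, flat.grid.axis_coords(0), flat.state.w_A)
    st = FieldState(
        grid=grid, chain=chain, w_A=w_A, w_B=w_B,
        ensemble="grand", z_l=math.exp(flat.mu_star), z_s=1.0,
    )
    sol = solve_scft(st, tol=1e-9, max_iter=3000, raise_on_failure=False)
    s = stress_difference_profile(sol.state)
    mid = _bilayer_center(sol.state.phi_B, x)
    h = grid.spacing[0]
    mask = x >= mid
    return float(np.sum((x[mask] - mid) * s[mask]) * h)


def monolayer_spontaneous_curvature(
    chain: ChainModel,
    flat: FlatBilayer | None = None,
    kappa: float | None = None,
) -> float:
    """Monolayer spontaneous curvature ``c0 = 2 tau / kappa`` (1/R0).

    ``tau`` is the monolayer stress torque and ``kappa/2`` the monolayer
    bending modulus.  The sign convention is that larger head groups
    (smaller ``f``) give positive ``c0`` (monolayer curving toward its
    tails), so ``c0`` decreases with the tail fraction.
    """
    flat = flat or tensionless_bilayer(chain)
    tau = monolayer_torque(chain, flat)
    if kappa is None:
        kappa = bending_modulus(chain, flat)
    return 2.0 * tau / kappa


# ---------------------------------------------------------------------------
# 2D line-defect configurations
# ---------------------------------------------------------------------------


def _dist_segment(X, Y, x0, y0, x1, y1):
    vx, vy = x1 - x0, y1 - y0
    L2 = vx * vx + vy * vy
    t = np.clip(((X - x0) * vx + (Y - y0) * vy) / L2, 0.0, 1.0)
    return np.hypot(X - (x0 + t * vx), Y - (y0 + t * vy))


def _skeleton_distance(kind: str, grid: Grid, d: float):
    """Distance to the membrane mid-surface skeleton of a line configuration.

    All three configurations are mirror-symmetric about the membrane
    midplane, so only the lower half is solved: the symmetry plane is the
    reflecting wall at the TOP edge of the 2D box and the excess free
    energy of the full configuration is twice the half-box value.
    """
    Lx, Hy = grid.lengths
    x = grid.axis_coords(0)
    y = grid.axis_coords(1)
    X, Y = np.meshgrid(x, y, indexing="ij")
    if kind == "e":
        # half-bilayer on the mirror plane, ending at x_e (the reflecting
        # wall at x = 0 continues the membrane to the left)
        xe = Lx - 5.0
        return _dist_segment(X, Y, 0.0, Hy, xe, Hy)
    if kind == "h":
        # one apposing bilayer at distance d below the mirror plane (its
        # partner is the mirror image) merging into the half HD bilayer on
        # the plane; the merge is seeded as a Y so the membranes are
        # connected from the start (a disconnected seed relaxes into a
        # metastable pair of membrane edges instead of the junction)
        xj = Lx / 2.0
        xm = xj - 1.25 * d
        d1 = _dist_segment(X, Y, 0.0, Hy - d, xm, Hy - d)
        d2 = _dist_segment(X, Y, xm, Hy - d, xj, Hy)
        d3 = _dist_segment(X, Y, xj, Hy, Lx, Hy)
        return np.minimum.reduce([d1, d2, d3])
    if kind == "p":
        # bilayer at distance d below the mirror plane for x > xw, closed
        # by a quarter-turn wall (the mirror completes the half-cylinder)
        xw = Lx - 7.0
        d1 = _dist_segment(X, Y, xw, Hy - d, Lx, Hy - d)
        d2 = np.abs(np.hypot(X - xw, Y - Hy) - d)
        d2 = np.where(X <= xw, d2, np.inf)
        return np.minimum(d1, d2)
    raise ValueError(f"unknown line kind {kind!r}")


def _fields_from_skeleton(dist, flat: FlatBilayer):
    """Compose 2D seed fields from the converged flat 1D profile."""
    x1 = flat.grid.axis_coords(0)
    mid = _bilayer_center(flat.state.phi_B, x1)
    off = np.abs(x1 - mid)
    order = np.argsort(off)
    off_s = off[order]
    w_B = np.interp(dist, off_s, flat.state.w_B[order])
    w_A = np.interp(dist, off_s, flat.state.w_A[order])
    return w_B, w_A


@dataclass
class LineTensionResult:
    kind: str
    value: float                  # energy / R0 length of line
    value_anisotropy: float       # pressure-anisotropy cross-check
    d: float
    state: FieldState = field(repr=False, default=None)


def line_tension_anisotropy(state: FieldState) -> float:
    """Line tension from the pressure-anisotropy integral.

    For a line defect along the invariant z-direction of a 2D cross
    section, ``lambda = int dA (sigma_xx - sigma_zz)`` with x the
    direction along the (tensionless) membranes; only the Gaussian-chain
    conformational stress survives in the difference.
    """
    chain = state.chain
    if state.phi_A is None:
        state.refresh()
    props = propagate_chain(
        state.w_B, state.w_A, state.grid, chain, u_lipid=state.external_lipid
    )
    nb, na, ns = chain.block_steps()
    ds = chain.contour_step
    h = state.grid.spacing[0]
    bc = state.grid.bc[0]

    def dx(a):
        return _deriv4(a, h, bc, axis=-2)

    wl = _simpson_weights(nb + na)
    lip = ds * np.tensordot(wl, dx(props.q) * dx(props.qdag), axes=(0, 0))
    dqs = dx(props.qs)
    solv = ds * np.tensordot(_simpson_weights(ns), dqs * dqs[::-1], axes=(0, 0))
    dens = -(1.0 / 3.0) * (state.z_l * lip + (state.z_s / chain.alpha) * solv)
    return -float(np.sum(dens * state.grid.cell_volumes))


def line_tension(
    kind: str,
    chain: ChainModel,
    d: float = 0.0,
    flat: FlatBilayer | None = None,
    box: tuple[float, float] = BOX_2D,
    spacing: float = GRID_SPACING,
    contour_step: float = DS_2D,
    tol: float = 1e-6,
    max_iter: int = 800,
) -> LineTensionResult:
    """Line tension of one boundary type from a 2D cross-section.

    ``kind`` is 'e' (membrane edge), 'h' (three-bilayer junction) or 'p'
    (fusion-pore wall); ``d`` is the half-separation of the apposing
    membranes (required for 'h' and 'p').  The configuration is seeded
    from the flat tensionless bilayer profile along a skeleton and relaxed
    grand-canonically at the tensionless chemical potential, so every
    membrane leg carries zero tension and the total excess grand potential
    per unit length of the line is the line tension itself.
    """
    if kind in ("h", "p") and d <= 0:
        raise ValueError(f"kind {kind!r} requires a positive half-separation d")
    chain2 = ChainModel(
        f=chain.f, chiN=chain.chiN, alpha=chain.alpha, contour_step=contour_step
    )
    # the tensionless chemical potential must be tuned at the same contour
    # step as the 2D run: a mismatch leaves the membranes slightly tense
    # and the soft defect position then creeps instead of converging
    if flat is None or flat.chain.contour_step != contour_step:
        flat = tensionless_bilayer(chain2)
    nx, ny = (int(round(L / spacing)) for L in box)
    grid = Grid(lengths=box, shape=(nx, ny), bc=("neumann", "neumann"))
    dist = _skeleton_distance(kind, grid, d)
    w_B, w_A = _fields_from_skeleton(dist, flat)
    st = FieldState(
        grid=grid, chain=chain2, w_A=w_A, w_B=w_B,
        ensemble="grand", z_l=math.exp(flat.mu_star), z_s=1.0,
    )
    sol = solve_scft(st, tol=tol, max_iter=max_iter, raise_on_failure=False)
    state = sol.state
    if state.phi_B.max() < 0.5:
        raise NoBilayerError(f"the {kind!r} configuration dissolved during relaxation")
    lam = 2.0 * _grand_excess(state)           # mirror completes the cross-section
    lam_aniso = 2.0 * line_tension_anisotropy(state)
    return LineTensionResult(
        kind=kind, value=lam, value_anisotropy=lam_aniso, d=d, state=state
    )


def line_tension_ratios(
    chain: ChainModel,
    d: float,
    flat: FlatBilayer | None = None,
    **kwargs,
) -> dict:
    """The dimensionless pair (lambda_e/lambda_h, lambda_p/lambda_h).

    ``d`` in R0.  Returns the absolute tensions and metadata as well; the
    ratio pair feeds directly into the rim-pore saddle search.
    """
    ds2 = kwargs.get("contour_step", DS_2D)
    if flat is None or flat.chain.contour_step != ds2:
        flat = tensionless_bilayer(
            ChainModel(f=chain.f, chiN=chain.chiN, alpha=chain.alpha, contour_step=ds2)
        )
    lam_e = line_tension("e", chain, 0.0, flat=flat, **kwargs)
    lam_h = line_tension("h", chain, d, flat=flat, **kwargs)
    lam_p = line_tension("p", chain, d, flat=flat, **kwargs)
    return {
        "lambda_e": lam_e.value,
        "lambda_h": lam_h.value,
        "lambda_p": lam_p.value,
        "lambda_e_over_h": lam_e.value / lam_h.value,
        "lambda_p_over_h": lam_p.value / lam_h.value,
        "cross_check_anisotropy": {
            "e": lam_e.value_anisotropy,
            "h": lam_h.value_anisotropy,
            "p": lam_p.value_anisotropy,
        },
        "f": chain.f,
        "chiN": chain.chiN,
        "d": d,
        "D": flat.D,
    }


def zero_tension_pore_fate(
    chain: ChainModel | None = None,
    d: float = 0.0,
    tensions: tuple[float, float, float] | None = None,
    **kwargs,
) -> str:
    """Fate of a rim pore on a tensionless linear junction.

    Unzipping the junction trades h-line for e- plus p-line, so the pore
    GROWS when ``lambda_e + lambda_p < lambda_h`` and SHRINKS otherwise.
    Pass precomputed ``tensions = (lambda_e, lambda_p, lambda_h)`` to skip
    the SCFT evaluation.
    """
    if tensions is None:
        res = line_tension_ratios(chain, d, **kwargs)
        tensions = (res["lambda_e"], res["lambda_p"], res["lambda_h"])
    lam_e, lam_p, lam_h = tensions
    return "GROWS" if lam_e + lam_p < lam_h else "SHRINKS"


def membrane_properties(chain: ChainModel, d: float, **kwargs) -> MembraneProps:
    """Full observable bundle: thickness, kappa, c0 and the line tensions."""
    flat = tensionless_bilayer(chain)
    kappa = bending_modulus(chain, flat)
    c0 = monolayer_spontaneous_curvature(chain, flat, kappa)
    lt = line_tension_ratios(chain, d, flat=flat, **kwargs)
    return MembraneProps(
        D=flat.D,
        Sigma=flat.Sigma,
        kappa=kappa,
        c0=c0,
        lambda_e=lt["lambda_e"],
        lambda_h=lt["lambda_h"],
        lambda_p=lt["lambda_p"],
        d=d,
        f=chain.f,
        chiN=chain.chiN,
    )
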