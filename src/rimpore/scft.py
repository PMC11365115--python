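"""Self-consistent field theory of lipid bilayers in implicit-ish solvent.

Lipids are Gaussian AB diblock copolymers: a tail block of contour
fraction ``f`` (species B) and a head block of fraction ``1 - f`` (species
A).  Water is a short A-like homopolymer of relative length ``alpha``
(N/10 segments by default).  Heads and water repel tails with
Flory-Huggins strength ``chi N``; heads and water are mutually athermal,
so a single field ``w_O`` acts on both "other" species while ``w_B`` acts
on tails.

Units: lengths in the lipid end-to-end distance ``R0 = b sqrt(N)``; the
modified diffusion equation for the chain propagator reads
``dq/ds = (1/6) lap q - w q`` with contour variable ``s`` in [0, 1] for
lipids and [0, alpha] for solvent.  Free energies are quoted per ``R0^3``
of volume in the invariant-polymerization-index energy scale (written
``Nbar kT``): all reported numbers are the dimensionless coefficients of
that scale.

Geometries: 1D planar, 1D cylindrical-radial (for bent bilayers) and 2D
Cartesian cross-sections (for line defects).  Reflecting (Neumann)
boundaries are realized spectrally with cosine transforms; periodic
boundaries with FFTs; the radial geometry uses Crank-Nicolson stepping.

The self-consistency loop updates the exchange and pressure fields by
Anderson-accelerated mixing; iteration is fully deterministic, so results
are bit-reproducible for identical inputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import fft as sfft
from scipy.linalg import solve_banded

__all__ = [
    "ChainModel",
    "Grid",
    "Propagators",
    "FieldState",
    "SCFTSolution",
    "SCFTNonConvergence",
    "propagate_chain",
    "compute_densities",
    "solve_scft",
    "free_energy_functional",
    "homogeneous_reference",
    "bulk_grand_potential_density",
    "stress_difference_profile",
]

DEFAULT_TOL = 1e-6


class SCFTNonConvergence(RuntimeError):
    """Self-consistency loop exceeded the iteration cap."""

    def __init__(self, msg, residual_history=None):
        super().__init__(msg)
        self.residual_history = residual_history or []


# ---------------------------------------------------------------------------
# model and grid
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChainModel:
    """Molecular parameters of the lipid/solvent mixture."""

    f: float = 0.8            # hydrophobic tail volume fraction of the lipid
    chiN: float = 30.0        # head-tail / water-tail repulsion strength
    alpha: float = 0.1        # solvent chain length relative to the lipid
    contour_step: float = 0.005

    def __post_init__(self) -> None:
        if not 0 < self.f < 1:
            raise ValueError("f must be in (0, 1)")
        if self.chiN <= 0:
            raise ValueError("chiN must be positive")
        if self.contour_step > 0.01 + 1e-12:
            raise ValueError("contour step must be <= 0.01")

    def block_steps(self) -> tuple[int, int, int]:
        ds = self.contour_step
        nb = round(self.f / ds)
        na = round((1.0 - self.f) / ds)
        ns = round(self.alpha / ds)
        for n, frac in ((nb, self.f), (na, 1 - self.f), (ns, self.alpha)):
            if n < 2 or n % 2 or abs(n * ds - frac) > 1e-9:
                raise ValueError(
                    "contour step must divide each block into an even "
                    "number of intervals (Simpson quadrature)"
                )
        return nb, na, ns


@dataclass(frozen=True)
class Grid:
    """Cell-centered computational grid.

    ``geometry`` is 'planar' (1D/2D Cartesian) or 'radial' (1D cylindrical,
    with ``r0`` the inner cell edge).  Boundary conditions are per-axis:
    'neumann' (reflecting) or 'periodic'.
    """

    lengths: tuple[float, ...]
    shape: tuple[int, ...]
    bc: tuple[str, ...] = ()
    geometry: str = "planar"
    r0: float = 0.0

    def __post_init__(self) -> None:
        if not self.bc:
            object.__setattr__(self, "bc", ("neumann",) * len(self.shape))
        if len(self.lengths) != len(self.shape) or len(self.bc) != len(self.shape):
            raise ValueError("inconsistent grid specification")
        if self.geometry == "radial" and len(self.shape) != 1:
            raise ValueError("radial geometry is one-dimensional")
        for b in self.bc:
            if b not in ("neumann", "periodic"):
                raise ValueError(f"unknown boundary condition {b!r}")

    @property
    def ndim(self) -> int:
        return len(self.shape)

    @property
    def spacing(self) -> tuple[float, ...]:
        return tuple(L / n for L, n in zip(self.lengths, self.shape))

    def axis_coords(self, ax: int) -> np.ndarray:
        h = self.spacing[ax]
        x = (np.arange(self.shape[ax]) + 0.5) * h
        if self.geometry == "radial":
            x = x + self.r0
        return x

    @property
    def cell_volumes(self) -> np.ndarray:
        """Integration weights (2*pi*r*dr for radial geometry)."""
        if self.geometry == "radial":
            r = self.axis_coords(0)
            return 2.0 * np.pi * r * self.spacing[0]
        vol = np.prod(self.spacing)
        return np.full(self.shape, vol)

    @property
    def volume(self) -> float:
        return float(np.sum(self.cell_volumes))


# ---------------------------------------------------------------------------
# propagator stepping
# ---------------------------------------------------------------------------


class _SpectralStepper:
    """Strang-split stepping of dq/ds = (1/6) lap q - w q on planar grids."""

    def __init__(self, grid: Grid, ds: float):
        self.grid = grid
        self.ds = ds
        k2 = np.zeros(grid.shape)
        for ax, (L, n, bc) in enumerate(zip(grid.lengths, grid.shape, grid.bc)):
            if bc == "neumann":
                k = np.pi * np.arange(n) / L
            else:
                k = 2.0 * np.pi * sfft.fftfreq(n, d=L / n)
            sh = [1] * grid.ndim
            sh[ax] = n
            k2 = k2 + (k**2).reshape(sh)
        self.diffuse = np.exp(-k2 * ds / 6.0)
        self._any_periodic = any(b == "periodic" for b in grid.bc)

    def _to_spectral(self, q):
        for ax, bc in enumerate(self.grid.bc):
            if bc == "neumann":
                q = sfft.dct(q, type=2, axis=ax, norm="ortho")
            else:
                q = sfft.fft(q, axis=ax)
        return q

    def _from_spectral(self, q):
        for ax, bc in reversed(list(enumerate(self.grid.bc))):
            if bc == "neumann":
                q = sfft.idct(q, type=2, axis=ax, norm="ortho")
            else:
                q = sfft.ifft(q, axis=ax)
        return q.real if np.iscomplexobj(q) else q

    def make_half(self, w):
        return np.exp(-0.5 * self.ds * w)

    def step(self, q, half):
        q = q * half
        q = self._from_spectral(self._to_spectral(q) * self.diffuse)
        return q * half


class _RadialCN:
    """Strang-split stepping on a 1D cylindrical grid.

    Potential half-steps are exact exponentials (as in the spectral path);
    the radial diffusion ``(1/6)(q'' + q'/r)`` is advanced by Crank-Nicolson
    in conservative flux form, so the reflecting (no-flux) ends are exact
    and the matrices are field-independent and factorized once.
    """

    def __init__(self, grid: Grid, ds: float):
        self.grid = grid
        self.ds = ds
        n = grid.shape[0]
        h = grid.spacing[0]
        r = grid.axis_coords(0)
        r_minus = (r - h / 2).copy()
        r_plus = (r + h / 2).copy()
        # reflecting ends: no flux through the first and last cell edges
        r_minus[0] = 0.0
        r_plus[-1] = 0.0
        coef = ds / (2.0 * 6.0 * h * h)
        lo = -coef * r_minus / r
        up = -coef * r_plus / r
        di = coef * (r_plus + r_minus) / r
        self.rhs_lo, self.rhs_up, self.rhs_di = -lo, -up, -di
        ab = np.zeros((3, n))
        ab[0, 1:] = up[:-1]
        ab[1] = 1.0 + di
        ab[2, :-1] = lo[1:]
        self.ab = ab
        self.n = n

    def make_half(self, w):
        return np.exp(-0.5 * self.ds * w)

    def step(self, q, half):
        q = q * half
        rhs = q * (1.0 + self.rhs_di)
        rhs[:-1] += self.rhs_up[:-1] * q[1:]
        rhs[1:] += self.rhs_lo[1:] * q[:-1]
        q = solve_banded((1, 1), self.ab, rhs)
        return q * half


def _make_stepper(grid: Grid, ds: float):
    if grid.geometry == "radial":
        return _RadialCN(grid, ds)
    return _SpectralStepper(grid, ds)


# ---------------------------------------------------------------------------
# chain propagation and densities
# ---------------------------------------------------------------------------


@dataclass
class Propagators:
    q: np.ndarray         # lipid forward, shape (ns_lipid+1, *grid)
    qdag: np.ndarray      # lipid backward (from the head end)
    qs: np.ndarray        # solvent forward
    Q_lipid: float
    Q_solvent: float


def _simpson_weights(n):
    if n % 2 != 0:
        raise ValueError("Simpson rule needs an even number of intervals")
    w = np.ones(n + 1)
    w[1:-1:2] = 4.0
    w[2:-1:2] = 2.0
    return w / 3.0


def propagate_chain(
    w_B: np.ndarray,
    w_O: np.ndarray,
    grid: Grid,
    chain: ChainModel,
    u_lipid: np.ndarray | None = None,
):
    """Forward/backward lipid propagators and the solvent propagator.

    The lipid contour runs tail-first: species B on s in [0, f], species A
    on [f, 1].  Solvent feels ``w_O``.  ``u_lipid`` is an optional external
    potential acting on every lipid segment (used e.g. to pin the radial
    position of a bent bilayer, whose drift is otherwise a zero mode).
    Partition functions are volume-averaged single-chain weights.
    """
    nb, na, ns = chain.block_steps()
    ds = chain.contour_step
    stepper = _make_stepper(grid, ds)
    if u_lipid is None:
        wBl, wOl = w_B, w_O
    else:
        wBl, wOl = w_B + u_lipid, w_O + u_lipid
    hB, hO = stepper.make_half(wBl), stepper.make_half(wOl)
    hS = stepper.make_half(w_O) if u_lipid is not None else hO

    q = np.empty((nb + na + 1,) + grid.shape)
    q[0] = 1.0
    for i in range(nb):
        q[i + 1] = stepper.step(q[i], hB)
    for i in range(nb, nb + na):
        q[i + 1] = stepper.step(q[i], hO)

    qdag = np.empty_like(q)
    qdag[-1] = 1.0
    for i in range(na):
        qdag[-2 - i] = stepper.step(qdag[-1 - i], hO)
    for i in range(na, na + nb):
        qdag[-2 - i] = stepper.step(qdag[-1 - i], hB)

    qs = np.empty((ns + 1,) + grid.shape)
    qs[0] = 1.0
    for i in range(ns):
        qs[i + 1] = stepper.step(qs[i], hS)

    vol = grid.cell_volumes
    V = grid.volume
    Q_l = float(np.sum(q[-1] * vol) / V)
    Q_s = float(np.sum(qs[-1] * vol) / V)
    if Q_l <= 0 or Q_s <= 0 or np.min(q[-1]) < -1e-5:
        raise FloatingPointError("propagator lost positivity; reduce the contour step")
    return Propagators(q=q, qdag=qdag, qs=qs, Q_lipid=Q_l, Q_solvent=Q_s)


def compute_densities(props: Propagators, chain: ChainModel, z_l: float, z_s: float):
    """Monomer volume fractions from the propagators at given activities."""
    nb, na, ns = chain.block_steps()
    ds = chain.contour_step
    prod = props.q * props.qdag
    wB = _simpson_weights(nb)
    wA = _simpson_weights(na)
    wS = _simpson_weights(ns)
    phi_B = z_l * ds * np.tensordot(wB, prod[: nb + 1], axes=(0, 0))
    phi_A = z_l * ds * np.tensordot(wA, prod[nb:], axes=(0, 0))
    qq = props.qs * props.qs[::-1]
    phi_S = (z_s / chain.alpha) * ds * np.tensordot(wS, qq, axes=(0, 0))
    return phi_A, phi_B, phi_S


# ---------------------------------------------------------------------------
# field state and free energy
# ---------------------------------------------------------------------------


@dataclass
class FieldState:
    """Fields, densities and diagnostics on a grid.

    ``w_A`` acts on head segments and (identically) on solvent; ``w_B`` on
    tails.  ``xi`` is the incompressibility pressure implied by the fields.
    """

    grid: Grid
    chain: ChainModel
    w_A: np.ndarray
    w_B: np.ndarray
    ensemble: str = "grand"       # 'grand' or 'canonical'
    z_l: float = 1.0              # lipid activity (grand) ...
    z_s: float = 1.0              # solvent activity
    phi_lipid_bar: float = 0.0    # ... or mean lipid fraction (canonical)
    external_lipid: np.ndarray | None = None
    phi_A: np.ndarray | None = None
    phi_B: np.ndarray | None = None
    phi_S: np.ndarray | None = None
    xi: np.ndarray | None = None
    Q_lipid: float = np.nan
    Q_solvent: float = np.nan
    residual: float = np.inf
    iterations: int = 0

    @property
    def w_O(self):
        return self.w_A

    def refresh(self) -> "FieldState":
        """Recompute propagators, activities and densities for the fields."""
        props = propagate_chain(
            self.w_B, self.w_A, self.grid, self.chain, u_lipid=self.external_lipid
        )
        if self.ensemble == "canonical":
            z_l = self.phi_lipid_bar / props.Q_lipid
            z_s = (1.0 - self.phi_lipid_bar) / props.Q_solvent
        else:
            z_l, z_s = self.z_l, self.z_s
        phi_A, phi_B, phi_S = compute_densities(props, self.chain, z_l, z_s)
        self.z_l, self.z_s = z_l, z_s
        self.phi_A, self.phi_B, self.phi_S = phi_A, phi_B, phi_S
        self.Q_lipid, self.Q_solvent = props.Q_lipid, props.Q_solvent
        self.xi = 0.5 * (self.w_B + self.w_A - self.chain.chiN)
        return self


@dataclass
class SCFTSolution:
    state: FieldState
    free_energy_density: float     # per R0^3, Nbar kT scale
    free_energy: float             # integrated over the box
    residual_history: list = field(default_factory=list)

    @property
    def ensemble(self) -> str:
        return self.state.ensemble


def free_energy_functional(state: FieldState, per_volume: bool = False) -> float:
    """Mean-field free energy of a (refreshed) field state.

    Canonical:  F = interaction - fields - pressure + translational entropy
    of both molecule types; grand canonical: the Legendre transform with
    the activities ``z_l``, ``z_s`` (solvent entropy per chain of length
    ``alpha``).  At a homogeneous state this reduces exactly to
    :func:`homogeneous_reference` (canonical) by construction.
    """
    if state.phi_A is None:
        state.refresh()
    chain, grid = state.chain, state.grid
    vol = grid.cell_volumes
    V = grid.volume
    phi_O = state.phi_A + state.phi_S
    phi_tot = phi_O + state.phi_B
    local = (
        chain.chiN * state.phi_B * phi_O
        - state.w_B * state.phi_B
        - state.w_A * phi_O
        - state.xi * (1.0 - phi_tot)
    )
    e_local = float(np.sum(local * vol)) / V
    if state.ensemble == "canonical":
        pl = state.phi_lipid_bar
        ps = 1.0 - pl
        ent = 0.0
        if pl > 0:
            ent += pl * math.log(pl / state.Q_lipid)
        if ps > 0:
            ent += (ps / chain.alpha) * math.log(ps / state.Q_solvent)
        dens = e_local + ent
    else:
        dens = e_local - state.z_l * state.Q_lipid - (state.z_s / chain.alpha) * state.Q_solvent
    return dens if per_volume else dens * V


def homogeneous_reference(chain: ChainModel, phi_lipid: float) -> float:
    """Closed-form canonical free-energy density of the uniform mixture."""
    if not 0 <= phi_lipid <= 1:
        raise ValueError("composition must lie in [0, 1]")
    phi_B = chain.f * phi_lipid
    phi_s = 1.0 - phi_lipid
    out = chain.chiN * phi_B * (1.0 - phi_B)
    if phi_lipid > 0:
        out += phi_lipid * math.log(phi_lipid)
    if phi_s > 0:
        out += (phi_s / chain.alpha) * math.log(phi_s)
    return out


def bulk_grand_potential_density(
    chain: ChainModel, mu_l: float, z_s: float = 1.0
) -> tuple[float, float]:
    """Grand-potential density and lipid fraction of the uniform bulk.

    The bulk in all membrane calculations is nearly pure solvent with a
    dilute dissolved-lipid tail set by the lipid chemical potential
    ``mu_l = ln z_l``.
    """
    z_l = math.exp(mu_l)

    def mismatch(phi_l):
        phi_B = chain.f * phi_l
        phi_s = 1.0 - phi_l
        w_O = -math.log(max(phi_s, 1e-300) / z_s) / chain.alpha
        w_B = w_O + chain.chiN * (1.0 - 2.0 * phi_B)
        return math.log(z_l) - (
            math.log(max(phi_l, 1e-300)) + chain.f * w_B + (1 - chain.f) * w_O
        )

    # dilute branch: scan upward from vanishing lipid content
    lo, hi = 1e-12, 0.5
    flo = mismatch(lo)
    phi = lo
    grid = np.geomspace(lo, hi, 200)
    vals = [mismatch(p) for p in grid]
    for k in range(len(grid) - 1):
        if vals[k] * vals[k + 1] <= 0:
            a, b = grid[k], grid[k + 1]
            fa = vals[k]
            for _ in range(200):
                m = 0.5 * (a + b)
                fm = mismatch(m)
                if fa * fm <= 0:
                    b = m
                else:
                    a, fa = m, fm
            phi = 0.5 * (a + b)
            break
    phi_B = chain.f * phi
    phi_s = 1.0 - phi
    w_O = -math.log(phi_s / z_s) / chain.alpha
    w_B = w_O + chain.chiN * (1.0 - 2.0 * phi_B)
    phi_O = 1.0 - phi_B
    omega = (
        chain.chiN * phi_B * phi_O
        - w_B * phi_B
        - w_O * phi_O
        - phi
        - phi_s / chain.alpha
    )
    return omega, phi


# ---------------------------------------------------------------------------
# self-consistency loop
# ---------------------------------------------------------------------------


def _residuals(state: FieldState, zeta: float):
    chain = state.chain
    phi_O = state.phi_A + state.phi_S
    comp = state.phi_B + phi_O - 1.0
    xi = 0.5 * (state.w_B + state.w_A - chain.chiN)
    r_B = chain.chiN * phi_O + xi - state.w_B + zeta * comp
    r_O = chain.chiN * state.phi_B + xi - state.w_A + zeta * comp
    return r_B, r_O, comp


def solve_scft(
    initial: FieldState,
    tol: float = DEFAULT_TOL,
    max_iter: int = 4000,
    mixing: float = 0.1,
    anderson_depth: int = 8,
    anderson_start: int = 20,
    zeta: float = 30.0,
    raise_on_failure: bool = True,
) -> SCFTSolution:
    """Iterate the fields to self-consistency (deterministic mixing).

    Simple mixing for the first ``anderson_start`` sweeps, then Anderson
    acceleration over the stacked field residuals.  Convergence requires
    both the field residuals and the incompressibility violation to drop
    below ``tol`` (maximum norm).
    """
    state = initial
    shape = state.grid.shape
    nfield = int(np.prod(shape))
    hist_x: list[np.ndarray] = []
    hist_r: list[np.ndarray] = []
    history = []
    best = np.inf
    best_fields = None
    best_overall = np.inf
    for it in range(max_iter):
        state.refresh()
        r_B, r_O, comp = _residuals(state, zeta)
        res = max(np.max(np.abs(r_B)), np.max(np.abs(r_O)), zeta * np.max(np.abs(comp)))
        history.append(res)
        if res < best_overall:
            best_overall = res
            best_fields = (state.w_B.copy(), state.w_A.copy())
        if res > 3.0 * best and hist_x:
            hist_x.clear()
            hist_r.clear()  # Anderson went unstable: restart from scratch
            best = res
        best = min(best, res)
        state.residual = float(max(np.max(np.abs(r_B)), np.max(np.abs(r_O))))
        state.iterations = it
        if res < tol * max(1.0, zeta):
            if np.max(np.abs(comp)) < tol and state.residual < tol:
                sol_dens = free_energy_functional(state, per_volume=True)
                return SCFTSolution(
                    state=state,
                    free_energy_density=sol_dens,
                    free_energy=sol_dens * state.grid.volume,
                    residual_history=history,
                )
        x = np.concatenate([state.w_B.ravel(), state.w_A.ravel()])
        r = np.concatenate([r_B.ravel(), r_O.ravel()])
        hist_x.append(x)
        hist_r.append(r)
        if len(hist_x) > anderson_depth + 1:
            hist_x.pop(0)
            hist_r.pop(0)
        if it < anderson_start or len(hist_x) < 3:
            x_new = x + mixing * r
        else:
            m = len(hist_r) - 1
            dR = np.stack([hist_r[k + 1] - hist_r[k] for k in range(m)], axis=1)
            dX = np.stack([hist_x[k + 1] - hist_x[k] for k in range(m)], axis=1)
            try:
                gamma, *_ = np.linalg.lstsq(dR, r, rcond=1e-10)
                if np.linalg.norm(gamma) > 50.0:
                    gamma *= 50.0 / np.linalg.norm(gamma)
                x_new = x + mixing * r - (dX + mixing * dR) @ gamma
            except np.linalg.LinAlgError:
                x_new = x + mixing * r
        state.w_B = x_new[:nfield].reshape(shape)
        state.w_A = x_new[nfield:].reshape(shape)
    if raise_on_failure:
        raise SCFTNonConvergence(
            f"no self-consistency after {max_iter} sweeps (residual {history[-1]:.3e})",
            residual_history=history,
        )
    # return the best state seen, not the last point of a mixing cycle
    if best_fields is not None:
        state.w_B, state.w_A = best_fields
    state.refresh()
    r_B, r_O, _ = _residuals(state, zeta)
    state.residual = float(max(np.max(np.abs(r_B)), np.max(np.abs(r_O))))
    dens = free_energy_functional(state, per_volume=True)
    return SCFTSolution(state, dens, dens * state.grid.volume, history)


# ---------------------------------------------------------------------------
# stress profile (1D planar): tangential minus normal
# ---------------------------------------------------------------------------


def _deriv4(arr, h, bc, axis=-1):
    """Fourth-order central derivative with mirror (neumann) or wrap padding."""
    arr = np.moveaxis(arr, axis, -1)
    if bc == "neumann":
        pad = np.concatenate([arr[..., 1::-1], arr, arr[..., :-3:-1]], axis=-1)
    else:
        pad = np.concatenate([arr[..., -2:], arr, arr[..., :2]], axis=-1)
    out = (
        pad[..., :-4] - 8.0 * pad[..., 1:-3] + 8.0 * pad[..., 3:-1] - pad[..., 4:]
    ) / (12.0 * h)
    return np.moveaxis(out, -1, axis)


def stress_difference_profile(state: FieldState) -> np.ndarray:
    """Lateral-stress profile s(z) = P_T(z) - P_N(z) of a 1D planar state.

    Only the Gaussian-chain conformational stress contributes to the
    anisotropy; the local (ideal + interaction + pressure) terms are
    isotropic.  The integral of s over the box equals minus the membrane
    tension; its first moment over one monolayer gives the torque that
    defines the monolayer spontaneous curvature.
    """
    if state.grid.ndim != 1 or state.grid.geometry != "planar":
        raise ValueError("stress profile requires a 1D planar state")
    if state.phi_A is None:
        state.refresh()
    chain = state.chain
    ds = chain.contour_step
    nb, na, ns = chain.block_steps()
    h = state.grid.spacing[0]
    bc = state.grid.bc[0]

    def ddz(arr):
        return _deriv4(arr, h, bc, axis=-1)

    props = propagate_chain(state.w_B, state.w_A, state.grid, state.chain)
    wl = _simpson_weights(nb + na) if (nb + na) % 2 == 0 else None
    # integrate d_z q * d_z qdag over the full lipid contour
    dq = ddz(props.q)
    dqd = ddz(props.qdag)
    if wl is None:
        lip = np.trapezoid(dq * dqd, dx=ds, axis=0)
    else:
        lip = ds * np.tensordot(wl, dq * dqd, axes=(0, 0))
    dqs = ddz(props.qs)
    sol = ds * np.tensordot(_simpson_weights(ns), dqs * dqs[::-1], axes=(0, 0))
    return -(1.0 / 3.0) * (state.z_l * lip + (state.z_s / chain.alpha) * sol)
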