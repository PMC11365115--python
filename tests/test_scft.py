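"""SCFT engine: propagators, self-consistency, free-energy functional."""

import math

import numpy as np
import pytest
import scipy.linalg as sla

from rimpore.scft import (
    ChainModel,
    FieldState,
    Grid,
    SCFTNonConvergence,
    free_energy_functional,
    homogeneous_reference,
    propagate_chain,
    solve_scft,
)

CHAIN = ChainModel()  # f = 0.8, chiN = 30, alpha = 0.1, ds = 0.005


# --- chain model ------------------------------------------------------------


def test_chain_model_validation():
    with pytest.raises(ValueError):
        ChainModel(f=1.2)
    with pytest.raises(ValueError):
        ChainModel(chiN=-1.0)
    with pytest.raises(ValueError):
        ChainModel(contour_step=0.02)
    with pytest.raises(ValueError):
        ChainModel(contour_step=0.004).block_steps()  # alpha/ds odd


# --- propagators ------------------------------------------------------------


def test_free_chain_propagator_is_unity():
    grid = Grid(lengths=(8.0,), shape=(128,), bc=("periodic",))
    zero = np.zeros(grid.shape)
    p = propagate_chain(zero, zero, grid, CHAIN)
    assert np.allclose(p.q[-1], 1.0, atol=1e-12)
    assert p.Q_lipid == pytest.approx(1.0)
    assert p.Q_solvent == pytest.approx(1.0)


def test_uniform_potential_gives_boltzmann_partition_function():
    grid = Grid(lengths=(8.0,), shape=(64,), bc=("neumann",))
    w = np.full(grid.shape, 0.7)
    p = propagate_chain(w, w, grid, CHAIN)
    assert p.Q_lipid == pytest.approx(math.exp(-0.7), rel=1e-10)
    assert p.Q_solvent == pytest.approx(math.exp(-0.7 * CHAIN.alpha), rel=1e-10)


def _dense_expm_endpoint(w, L, s_total):
    """Independent oracle: dense matrix exponential of the spectral
    evolution operator (1/6) d2/dx2 - w on a periodic grid."""
    n = len(w)
    k = 2 * np.pi * np.fft.fftfreq(n, d=L / n)
    F = np.fft.fft(np.eye(n), axis=0)
    D2 = np.real(np.linalg.inv(F) @ np.diag(-(k**2)) @ F)
    return sla.expm((D2 / 6.0 - np.diag(w)) * s_total) @ np.ones(n)


def test_propagator_matches_operator_exponential_oracle():
    grid = Grid(lengths=(4.0,), shape=(32,), bc=("periodic",))
    x = grid.axis_coords(0)
    w = 1.5 * np.sin(2 * np.pi * x / 4.0)
    p = propagate_chain(w, w, grid, CHAIN)
    q_exact = _dense_expm_endpoint(w, 4.0, 1.0)
    err = np.max(np.abs(p.q[-1] - q_exact)) / np.max(q_exact)
    assert err < 1e-5


def test_contour_step_convergence_is_second_order():
    grid = Grid(lengths=(4.0,), shape=(32,), bc=("periodic",))
    x = grid.axis_coords(0)
    w = 1.5 * np.sin(2 * np.pi * x / 4.0)
    q_exact = _dense_expm_endpoint(w, 4.0, 1.0)
    errs = []
    for ds in (0.01, 0.005):
        chain = ChainModel(contour_step=ds)
        p = propagate_chain(w, w, grid, chain)
        errs.append(np.max(np.abs(p.q[-1] - q_exact)))
    ratio = errs[0] / errs[1]
    assert 2.5 < ratio < 6.5  # Strang splitting: error ~ ds^2


# --- homogeneous limit ------------------------------------------------------


def test_homogeneous_reference_limits():
    assert homogeneous_reference(CHAIN, 0.0) == 0.0  # pure solvent
    chain0 = ChainModel(f=0.8, chiN=1e-300)
    ideal = 0.5 * math.log(0.5) + (0.5 / 0.1) * math.log(0.5)
    assert homogeneous_reference(chain0, 0.5) == pytest.approx(ideal, rel=1e-9)


def test_solver_reproduces_homogeneous_reference_exactly():
    """From a uniform seed the canonical solve stays uniform and its free
    energy density equals the closed-form mixture value to 1e-10."""
    grid = Grid(lengths=(1.0,), shape=(4,), bc=("periodic",))
    st = FieldState(
        grid=grid, chain=CHAIN, w_A=np.zeros(4), w_B=np.zeros(4),
        ensemble="canonical", phi_lipid_bar=0.5,
    )
    sol = solve_scft(st, tol=1e-12, max_iter=2000)
    assert sol.free_energy_density == pytest.approx(
        homogeneous_reference(CHAIN, 0.5), abs=1e-10
    )


def test_nonconvergence_carries_residual_history():
    grid = Grid(lengths=(1.0,), shape=(4,), bc=("periodic",))
    st = FieldState(
        grid=grid, chain=CHAIN, w_A=np.zeros(4), w_B=np.full(4, 20.0),
        ensemble="canonical", phi_lipid_bar=0.5,
    )
    with pytest.raises(SCFTNonConvergence) as exc:
        solve_scft(st, tol=1e-14, max_iter=3)
    assert len(exc.value.residual_history) == 3


# --- bilayer solution properties --------------------------------------------


@pytest.fixture(scope="module")
def bilayer_1d():
    """Canonical 1D bilayer at chiN = 30, f = 0.8 (symmetric seed)."""
    grid = Grid(lengths=(8.0,), shape=(128,), bc=("neumann",))
    x = grid.axis_coords(0)
    core = 0.96 * 0.5 * (1 - np.tanh((np.abs(x - 4.0) - 0.55) / 0.12))
    st = FieldState(
        grid=grid, chain=CHAIN, w_A=CHAIN.chiN * core, w_B=CHAIN.chiN * (1 - core),
        ensemble="canonical", phi_lipid_bar=0.18,
    )
    return solve_scft(st, tol=1e-9, max_iter=4000)


def test_bilayer_converges_with_incompressibility(bilayer_1d):
    s = bilayer_1d.state
    assert s.residual < 1e-9
    total = s.phi_A + s.phi_B + s.phi_S
    assert np.max(np.abs(total - 1.0)) < 1e-6
    assert np.all(s.phi_B > -1e-9) and np.all(s.phi_B < 1.0 + 1e-9)
    assert s.phi_B.max() > 0.9  # segregated tail core


def test_bilayer_profile_is_mirror_symmetric(bilayer_1d):
    phi = bilayer_1d.state.phi_B
    assert np.max(np.abs(phi - phi[::-1])) < 1e-8


def test_free_energy_extensive_under_tangential_tiling(bilayer_1d):
    """Tiling the converged profile into a twice-wider periodic 2D box
    exactly doubles the extensive free energy."""
    s = bilayer_1d.state
    n = s.grid.shape[0]
    for tangential in (1, 2):
        grid2 = Grid(
            lengths=(1.0 * tangential, 8.0), shape=(8 * tangential, n),
            bc=("periodic", "neumann"),
        )
        st2 = FieldState(
            grid=grid2, chain=CHAIN,
            w_A=np.tile(s.w_A, (8 * tangential, 1)),
            w_B=np.tile(s.w_B, (8 * tangential, 1)),
            ensemble="grand", z_l=s.z_l, z_s=s.z_s,
        )
        st2.refresh()
        if tangential == 1:
            f1 = free_energy_functional(st2)
        else:
            f2 = free_energy_functional(st2)
    assert f2 == pytest.approx(2.0 * f1, rel=1e-10)


def test_solver_is_deterministic(bilayer_1d):
    grid = Grid(lengths=(8.0,), shape=(128,), bc=("neumann",))
    x = grid.axis_coords(0)
    core = 0.96 * 0.5 * (1 - np.tanh((np.abs(x - 4.0) - 0.55) / 0.12))

    def run():
        st = FieldState(
            grid=grid, chain=CHAIN, w_A=CHAIN.chiN * core, w_B=CHAIN.chiN * (1 - core),
            ensemble="canonical", phi_lipid_bar=0.18,
        )
        return solve_scft(st, tol=1e-9, max_iter=4000)

    a, b = run(), run()
    assert a.free_energy == b.free_energy  # bit-identical
    assert np.array_equal(a.state.w_B, b.state.w_B)


def test_grid_refinement_converges(bilayer_1d):
    """Free energy differences shrink under grid refinement."""
    chain = CHAIN
    results = {}
    for n in (64, 128, 256):
        grid = Grid(lengths=(8.0,), shape=(n,), bc=("neumann",))
        x = grid.axis_coords(0)
        core = 0.96 * 0.5 * (1 - np.tanh((np.abs(x - 4.0) - 0.55) / 0.12))
        st = FieldState(
            grid=grid, chain=chain, w_A=chain.chiN * core, w_B=chain.chiN * (1 - core),
            ensemble="canonical", phi_lipid_bar=0.18,
        )
        results[n] = solve_scft(st, tol=1e-9, max_iter=4000).free_energy
    assert abs(results[128] - results[256]) < abs(results[64] - results[256])
    assert abs(results[128] - results[256]) < 1e-3 * abs(results[256])


# --- radial geometry ---------------------------------------------------------


def test_radial_stepper_conserves_mass_and_matches_uniform_decay():
    grid = Grid(
        lengths=(8.0,), shape=(128,), bc=("neumann",), geometry="radial", r0=2.0
    )
    r = grid.axis_coords(0)
    p = propagate_chain(np.zeros(128), np.zeros(128), grid, CHAIN)
    # free chain: no potential, reflecting ends -> q stays 1 identically
    assert np.max(np.abs(p.q[-1] - 1.0)) < 1e-10
    w = np.full(128, 0.7)
    p = propagate_chain(w, w, grid, CHAIN)
    assert p.Q_lipid == pytest.approx(math.exp(-0.7), rel=1e-6)


def test_radial_matches_planar_in_large_radius_limit(bilayer_1d):
    s = bilayer_1d.state
    grid_r = Grid(
        lengths=(8.0,), shape=(128,), bc=("neumann",), geometry="radial", r0=1e6
    )
    p_pl = propagate_chain(s.w_B, s.w_A, s.grid, CHAIN)
    p_ra = propagate_chain(s.w_B, s.w_A, grid_r, CHAIN)
    # CN vs spectral stepping differ at the discretization level only
    assert p_ra.Q_lipid == pytest.approx(p_pl.Q_lipid, rel=1e-2)
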