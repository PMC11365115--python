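"""Critical rim pores: saddle search, stability, classification, diagrams."""

import math
import warnings

import numpy as np
import pytest

from rimpore.geometry import (
    LineTensions,
    SystemSpec,
    build_geometry,
    constraint_residual,
    no_pore_reference,
    system_from_d_ratio,
)
from rimpore.saddle import (
    NonConvergenceWarning,
    RegionClass,
    brute_force_oracle,
    classify_region,
    constrained_hessian,
    find_saddle,
    laplace_check,
    scan_phase_diagram,
)

SYS0 = SystemSpec()


@pytest.fixture(scope="module")
def saddle_09_05():
    res = find_saddle(LineTensions(0.9, 0.5), SYS0)
    assert res is not None
    return res


# --- existence and absence --------------------------------------------------


def test_unzipping_region_has_no_saddle():
    """lambda_e + lambda_p < lambda_h: the rim unzips, no critical pore."""
    with warnings.catch_warnings():
        warnings.simplefilter("error")
        assert find_saddle(LineTensions(0.4, 0.4), SYS0) is None


def test_saddle_exists_in_recessed_interior(saddle_09_05):
    res = saddle_09_05
    assert res.region is RegionClass.CRITICAL_RECESSED
    assert 0 < res.pore_area_fraction < 1
    _, F0 = no_pore_reference(SYS0)
    assert res.grad_norm < 1e-8 * F0 / SYS0.Rh0
    assert abs(constraint_residual(res.geometry, SYS0)) < 1e-8 * SYS0.Ah0


def test_saddle_matches_brute_force_oracle(saddle_09_05):
    orc = brute_force_oracle(LineTensions(0.9, 0.5), SYS0, resolution=50, levels=4)
    assert orc is not None
    assert orc.pore_area_fraction == pytest.approx(
        saddle_09_05.pore_area_fraction, rel=1e-3
    )
    g, og = saddle_09_05.geometry, orc.geometry
    assert (og.Rh, og.Re, og.Rp) == pytest.approx((g.Rh, g.Re, g.Rp), rel=1e-3)


def test_oracle_reports_absence_where_no_saddle():
    assert brute_force_oracle(LineTensions(0.4, 0.4), SYS0) is None


def test_oracle_refinement_self_consistency():
    """Halving the grid spacing moves the oracle by less than the coarse
    discretization scale (Richardson-style sanity check)."""
    lt = LineTensions(0.8, 0.6)
    coarse = brute_force_oracle(lt, SYS0, resolution=50, levels=2)
    fine = brute_force_oracle(lt, SYS0, resolution=100, levels=2)
    assert coarse is not None and fine is not None
    assert abs(fine.pore_area_fraction - coarse.pore_area_fraction) < 5e-4


# --- Laplace relations ------------------------------------------------------


def test_laplace_relations_hold_at_saddle(saddle_09_05):
    Sigma, res = laplace_check(saddle_09_05)
    assert Sigma > 0
    assert np.all(res < 1e-6)
    g = saddle_09_05.geometry
    assert g.Rh == pytest.approx(1.0 / Sigma, rel=1e-9)  # lambda_h = 1, d = 0
    assert g.Re == pytest.approx(0.9 / Sigma, rel=1e-9)
    assert g.Rp == pytest.approx(0.5 / (2 * Sigma), rel=1e-9)


def test_equal_edge_and_junction_tensions_give_semicircular_p_arc():
    """At lambda_e = lambda_h the Laplace radii satisfy Re = Rh and the
    p-arc closes into a half circle, Rp = a."""
    res = find_saddle(LineTensions(1.0, 0.6), SYS0)
    assert res is not None
    g = res.geometry
    assert g.Re == pytest.approx(g.Rh, rel=1e-9)
    assert g.Rp == pytest.approx(g.a, rel=1e-9)


# --- Hessian stability analysis ---------------------------------------------


def test_saddle_is_index_one_and_rh_dominated(saddle_09_05):
    res = saddle_09_05
    evals = res.hessian_eigenvalues
    assert evals[0] < 0 and np.all(evals[1:] > 0)
    # unstable mode dominated by the HD radius
    assert np.argmax(np.abs(res.unstable_eigenvector)) == 0
    # pinning Rh stabilizes the pore
    assert np.all(res.hessian_eigenvalues_fixed_Rh > 0)


@pytest.mark.parametrize("ratios", [(1.2, 0.9), (0.6, 1.1), (0.7, 0.7)])
def test_stability_pattern_across_regions(ratios):
    res = find_saddle(LineTensions(*ratios), SYS0)
    assert res is not None
    assert res.hessian_eigenvalues[0] < 0
    assert np.sum(res.hessian_eigenvalues < 0) == 1
    assert np.all(res.hessian_eigenvalues_fixed_Rh > 0)


def test_hessian_matches_finite_difference_oracle(saddle_09_05):
    """Independent Richardson-extrapolated FD Hessian of F restricted to the
    constraint chart (a re-solved from scratch at every evaluation)."""
    from rimpore.geometry import free_energy

    g = saddle_09_05.geometry
    lt = LineTensions(0.9, 0.5)
    x0 = np.array([g.Rh, g.Re, g.Rp])

    def F(x):
        gg = build_geometry(x[0], x[1], x[2], g.bow_e, g.bow_p, SYS0)
        return free_energy(gg, lt)

    def fd_hessian(h):
        H = np.empty((3, 3))
        for i in range(3):
            for j in range(3):
                if i == j:
                    xp, xm = x0.copy(), x0.copy()
                    xp[i] += h
                    xm[i] -= h
                    H[i, i] = (F(xp) - 2 * F(x0) + F(xm)) / h**2
                else:
                    xpp, xpm, xmp, xmm = (x0.copy() for _ in range(4))
                    xpp[[i, j]] += h
                    xmm[[i, j]] -= h
                    xpm[i] += h
                    xpm[j] -= h
                    xmp[i] -= h
                    xmp[j] += h
                    H[i, j] = (F(xpp) - F(xpm) - F(xmp) + F(xmm)) / (4 * h**2)
        return H

    h = 2e-3
    H_fd = (4 * fd_hessian(h / 2) - fd_hessian(h)) / 3.0  # O(h^4)
    evals_fd = np.linalg.eigvalsh(0.5 * (H_fd + H_fd.T))
    evals = saddle_09_05.hessian_eigenvalues
    scale = np.max(np.abs(evals))
    assert np.all(np.abs(evals - evals_fd) < 1e-4 * scale)


def test_hessian_rejects_non_stationary_geometry():
    g = build_geometry(0.95, 0.8, 0.4, system=SYS0)
    with pytest.raises(ValueError):
        constrained_hessian(g, LineTensions(0.9, 0.5), SYS0)


# --- region classification --------------------------------------------------


@pytest.mark.parametrize(
    "ratios,expected",
    [
        ((0.4, 0.4), RegionClass.UNZIP_UNSTABLE),
        ((1.5, 0.3), RegionClass.EDGE_UNBALANCED),
        ((0.3, 1.5), RegionClass.DETACH_PREFERRED),
        ((0.9, 0.5), RegionClass.CRITICAL_RECESSED),
        ((1.2, 0.9), RegionClass.CRITICAL_PROTRUDING_OUT),
        ((0.55, 1.5), RegionClass.CRITICAL_PROTRUDING_IN),
        ((1.0, 0.6), RegionClass.CRITICAL_PROTRUDING_OUT),
    ],
)
def test_region_classification(ratios, expected):
    assert classify_region(LineTensions(*ratios), SYS0) is expected


def test_classification_agrees_with_saddle_presence_on_grid():
    """Away from boundaries, critical classes host a saddle and the three
    unstable classes do not."""
    margin = 0.06
    for le in np.linspace(0.25, 1.6, 7):
        for lp in np.linspace(0.25, 1.6, 7):
            dists = [abs(le + lp - 1), abs(le - lp - 1), abs(lp - le - 1)]
            if min(dists) < margin:
                continue
            cls = classify_region(LineTensions(le, lp), SYS0)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", NonConvergenceWarning)
                found = find_saddle(LineTensions(le, lp), SYS0, compute_hessian=False)
            expect_saddle = cls in (
                RegionClass.CRITICAL_RECESSED,
                RegionClass.CRITICAL_PROTRUDING_OUT,
                RegionClass.CRITICAL_PROTRUDING_IN,
            )
            assert (found is not None) == expect_saddle, (le, lp, cls)


def test_protruding_classification_matches_found_geometry():
    res = find_saddle(LineTensions(1.2, 0.9), SYS0)
    assert res.geometry.bow_p == "reflex"
    res = find_saddle(LineTensions(0.55, 1.5), SYS0)
    assert res.geometry.bow_e == "reflex"


def test_semicircular_edge_separatrix_consistent_with_geometry():
    """On either side of 3*lambda_e^2 = lambda_p^2 - lambda_h^2 the found
    e-arc switches between minor and reflex."""
    lp = 1.5
    le_star = math.sqrt((lp**2 - 1.0) / 3.0)
    below = find_saddle(LineTensions(le_star * 0.94, lp), SYS0, compute_hessian=False)
    above = find_saddle(LineTensions(le_star * 1.06, lp), SYS0, compute_hessian=False)
    assert below.geometry.bow_e == "reflex"
    assert above.geometry.bow_e == "minor"


# --- boundary and finite-d behavior ----------------------------------------


def test_area_fraction_vanishes_at_unzipping_boundary():
    """Ap/Ah0 -> 0 continuously as lambda_e + lambda_p -> lambda_h+."""
    fracs = []
    for le in [0.6, 0.55, 0.52, 0.51, 0.505]:
        res = find_saddle(LineTensions(le, 0.5), SYS0, compute_hessian=False)
        fracs.append(res.pore_area_fraction)
    assert np.all(np.diff(fracs) < 0)
    assert fracs[-1] < 1e-4


def test_area_fraction_decreases_with_separation():
    fracs = []
    for d in (0.0, 0.1, 0.3):
        res = find_saddle(
            LineTensions(0.9, 0.5), system_from_d_ratio(d), compute_hessian=False
        )
        fracs.append(res.pore_area_fraction)
    assert fracs[0] > fracs[1] > fracs[2]


def test_critical_region_extends_to_larger_edge_tension_with_separation():
    def exists(le, d):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", NonConvergenceWarning)
            return (
                find_saddle(
                    LineTensions(le, 0.9), system_from_d_ratio(d), compute_hessian=False
                )
                is not None
            )

    les = np.arange(1.2, 2.6, 0.1)
    bounds = []
    for d in (0.0, 0.1, 0.3):
        present = [le for le in les if exists(le, d)]
        bounds.append(max(present))
    assert bounds[0] < bounds[1] <= bounds[2]


def test_finite_d_results_continuous_at_d_zero():
    res0 = find_saddle(LineTensions(0.9, 0.5), SYS0, compute_hessian=False)
    diffs = []
    for d in (1e-3, 1e-4):
        res = find_saddle(
            LineTensions(0.9, 0.5), system_from_d_ratio(d), compute_hessian=False
        )
        diffs.append(abs(res.pore_area_fraction / res0.pore_area_fraction - 1))
    assert diffs[1] < 1e-4
    # leading deviation is linear in d
    assert 3 < diffs[0] / diffs[1] < 30


# --- phase diagram scan -----------------------------------------------------


def test_phase_scan_rows_and_absent_cells():
    les = np.array([0.3, 0.8, 1.2])
    lps = np.array([0.3, 0.7, 1.1])
    table = scan_phase_diagram(les, lps, SYS0, compute_hessian=False)
    assert len(table) == 9
    # row-major: lambda_e outer, lambda_p inner
    assert list(table["lambda_e"][:3]) == [0.3, 0.3, 0.3]
    unzip = table[table.lambda_e + table.lambda_p < 1.0]
    assert (unzip["status"] != "converged").all()
    assert np.isnan(unzip["area_fraction"]).all()
    ok = table[table["status"] == "converged"]
    assert len(ok) > 0
    assert (ok["area_fraction"] > 0).all()


def test_phase_scan_matches_oracle_on_coarse_grid():
    """Converged scan cells agree with the brute-force oracle to 1e-3."""
    les = np.linspace(0.6, 1.2, 5)
    lps = np.linspace(0.4, 1.2, 5)
    table = scan_phase_diagram(les, lps, SYS0, compute_hessian=False)
    checked = 0
    for _, row in table.iterrows():
        lt = LineTensions(row.lambda_e, row.lambda_p)
        orc = brute_force_oracle(lt, SYS0, resolution=50, levels=4)
        if row["status"] == "converged":
            assert orc is not None, (row.lambda_e, row.lambda_p)
            assert orc.pore_area_fraction == pytest.approx(
                row.area_fraction, rel=1e-3
            ), (row.lambda_e, row.lambda_p)
            checked += 1
        else:
            assert orc is None, (row.lambda_e, row.lambda_p)
    assert checked >= 10
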