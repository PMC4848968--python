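"""Electrostatics: Coulomb closed forms, grid construction, PB solver
oracles (Born ion, dense direct solve, uniform-medium Coulomb)."""

import itertools

import numpy as np
import pytest
from scipy.sparse import lil_matrix
from scipy.sparse.linalg import spsolve

from mutddg.electrostatics import (
    COULOMB_K,
    DielectricModel,
    _boundary_potential,
    _interp_phi,
    build_grid,
    build_grid_arrays,
    coulomb_energy,
    nonpolar_solvation,
    solve_pb,
)
from mutddg.forcefield import build_topology, default_parameters
from mutddg.structure import Atom, ProteinStructure, ResidueID
from mutddg.synth import make_peptide


def charged_pair(r, q1=1.0, q2=1.0, aa=("LYS", "LYS"), name="NZ"):
    """Two isolated side-chain-like atoms; charges set via a stub topology."""
    rid1 = ResidueID("A", 1, "", aa[0])
    rid2 = ResidueID("B", 1, "", aa[1])
    s = ProteinStructure(
        [
            Atom(name, name[0], rid1, np.zeros(3)),
            Atom(name, name[0], rid2, np.array([r, 0.0, 0.0])),
        ]
    )
    top = build_topology(s, default_parameters())
    top.charges[:] = (q1, q2)
    return s, top


def test_coulomb_closed_form_unit_dielectric():
    s, top = charged_pair(1.0)
    model = DielectricModel(eps_charged=1.0)  # LYS is in the charged class
    e = coulomb_energy(s, model=model, top=top)
    assert e == pytest.approx(332.0636, rel=1e-6)


def test_coulomb_closed_form_eps20():
    s, top = charged_pair(1.0)
    model = DielectricModel(eps_charged=20.0)
    assert coulomb_energy(s, model=model, top=top) == pytest.approx(
        332.0636 / 20.0, rel=1e-6
    )


def test_coulomb_geometric_mean_dielectric():
    # one charged-class (eps 22) and one other-class (eps 20) residue
    rid1 = ResidueID("A", 1, "", "LYS")
    rid2 = ResidueID("B", 1, "", "ALA")
    s = ProteinStructure(
        [
            Atom("NZ", "N", rid1, np.zeros(3)),
            Atom("CB", "C", rid2, np.array([2.0, 0.0, 0.0])),
        ]
    )
    top = build_topology(s, default_parameters())
    top.charges[:] = (1.0, -1.0)
    e = coulomb_energy(s, model=DielectricModel(), top=top)
    assert e == pytest.approx(-332.0636 / (np.sqrt(22.0 * 20.0) * 2.0), rel=1e-6)


def test_neutral_pair_zero():
    s, top = charged_pair(2.0, 0.0, 0.0)
    assert coulomb_energy(s, top=top) == 0.0


def test_coulomb_matches_brute_force(helix_mixed):
    params = default_parameters()
    top = build_topology(helix_mixed, params)
    model = DielectricModel()
    xyz = helix_mixed.coords()
    eps_at = np.array([model.residue_eps(a.res.aa) for a in helix_mixed.atoms])
    total = 0.0
    for i in range(len(xyz)):
        for j in range(i + 1, len(xyz)):
            if top.exclusion[i, j]:
                continue
            r = float(np.linalg.norm(xyz[i] - xyz[j]))
            total += (
                COULOMB_K
                * top.charges[i]
                * top.charges[j]
                / (np.sqrt(eps_at[i] * eps_at[j]) * r)
            )
    assert coulomb_energy(helix_mixed, params, model, top) == pytest.approx(
        total, abs=1e-9
    )


# ---------------------------------------------------------------------------
# grid and solver


def ion_grids(q=1.0, R=2.0, eps_in=1.0, eps_out=80.0, scale=1.0):
    args = (
        np.zeros((1, 3)),
        np.array([R]),
        np.array([q]),
        np.array([eps_in]),
    )
    solv = build_grid_arrays(*args, eps_solvent=eps_out, scale=scale)
    unif = build_grid_arrays(*args, eps_solvent=eps_out, scale=scale, uniform=True)
    return solv, unif


def reaction_field(q=1.0, R=2.0, eps_in=1.0, eps_out=80.0, scale=1.0):
    solv, unif = ion_grids(q, R, eps_in, eps_out, scale)
    ps = solve_pb(solv)
    pu = solve_pb(unif)
    pt = np.zeros((1, 3))
    dphi = _interp_phi(solv, ps, pt) - _interp_phi(unif, pu, pt)
    return float(0.5 * COULOMB_K * q * dphi[0])


def test_grid_charge_conservation():
    solv, _ = ion_grids()
    assert solv.charge.sum() == pytest.approx(1.0, abs=1e-9)


def test_grid_perfil_box_size():
    solv, _ = ion_grids(R=5.0)  # extent 10 A
    n = solv.shape[0]
    edge = (n - 1) * solv.spacing
    assert edge == pytest.approx(10.0 / 0.70, abs=1.0 + solv.spacing)


def test_node_dielectric_inside_charged_residue():
    pep = make_peptide("AKA", "extended")
    model = DielectricModel()
    grid = build_grid(pep, model=model, scale=1.0)
    # the node nearest NZ must carry the charged-class dielectric
    nz = [a.xyz for a in pep.atoms if a.name == "NZ"][0]
    idx = np.round((nz - grid.origin) / grid.spacing).astype(int)
    assert grid.eps[tuple(idx)] == model.eps_charged


def test_zero_charges_zero_potential():
    grid = build_grid_arrays(
        np.zeros((1, 3)), np.array([2.0]), np.array([0.0]), np.array([1.0])
    )
    phi = solve_pb(grid)
    assert np.all(phi == 0.0)


def test_uniform_medium_matches_coulomb_potential():
    g = build_grid_arrays(
        np.zeros((1, 3)),
        np.array([2.0]),
        np.array([1.0]),
        np.array([4.0]),
        eps_solvent=4.0,
        scale=2.0,
        extent=24.0,
    )
    phi = solve_pb(g, tol=1e-8)
    n = g.shape[0]
    for r in (3.0, 5.0, 8.0):
        i = int(round((r - g.origin[0]) / g.spacing))
        rr = abs(g.origin[0] + i * g.spacing)
        exact = 1.0 / (4.0 * rr)
        assert phi[i, n // 2, n // 2] == pytest.approx(exact, rel=0.05)


def test_sor_matches_dense_direct_solve():
    """Same FD system solved by scipy sparse LU agrees to 1e-8."""
    g = build_grid_arrays(
        np.array([[0.0, 0.0, 0.0], [1.5, 0.5, 0.0]]),
        np.array([2.0, 1.5]),
        np.array([1.0, -0.5]),
        np.array([2.0, 20.0]),
        eps_solvent=80.0,
        scale=1.0,
        extent=9.0,
    )
    phi = solve_pb(g, tol=1e-12, max_iter=100000)
    n = g.shape[0]
    assert n <= 15
    h = g.spacing

    def hmean(a, b):
        return 2 * a * b / (a + b)

    def idx(i, j, k):
        return (i * n + j) * n + k

    A = lil_matrix((n**3, n**3))
    b = np.zeros(n**3)
    phib = _boundary_potential(g)
    for i, j, k in itertools.product(range(n), repeat=3):
        I = idx(i, j, k)
        if i in (0, n - 1) or j in (0, n - 1) or k in (0, n - 1):
            A[I, I] = 1.0
            b[I] = phib[i, j, k]
            continue
        diag = 0.0
        for di, dj, dk in [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]:
            ef = hmean(g.eps[i, j, k], g.eps[i + di, j + dj, k + dk])
            A[I, idx(i + di, j + dj, k + dk)] = ef
            diag += ef
        A[I, I] = -diag
        b[I] = -4 * np.pi * g.charge[i, j, k] / h
    direct = spsolve(A.tocsr(), b).reshape(n, n, n)
    assert np.max(np.abs(phi - direct)) / np.max(np.abs(direct)) < 1e-8


def born_exact(q=1.0, R=2.0, eps_in=1.0, eps_out=80.0):
    return -COULOMB_K * q * q / (2.0 * R) * (1.0 / eps_in - 1.0 / eps_out)


def test_born_ion_scale1_within_10pct():
    assert reaction_field(scale=1.0) == pytest.approx(born_exact(), rel=0.10)


def test_born_ion_scale2_within_5pct():
    assert reaction_field(scale=2.0) == pytest.approx(born_exact(), rel=0.05)


def test_grid_refinement_changes_energy_under_3pct():
    e1 = reaction_field(scale=1.0)
    e2 = reaction_field(scale=2.0)
    assert abs(e2 - e1) / abs(e2) < 0.03


def test_reaction_field_quadratic_in_charge():
    e1 = reaction_field(q=1.0, scale=2.0)
    e2 = reaction_field(q=2.0, scale=2.0)
    assert e2 == pytest.approx(4.0 * e1, rel=0.01)


def test_no_dielectric_contrast_zero():
    e = reaction_field(eps_in=20.0, eps_out=20.0, scale=2.0)
    assert e == pytest.approx(0.0, abs=0.2)


def test_reaction_field_negative_for_charged_solute():
    assert reaction_field(scale=1.0) < 0.0


def test_nonpolar_solvation():
    assert nonpolar_solvation(0.0) == pytest.approx(0.86)
    assert nonpolar_solvation(1000.0) == pytest.approx(5.86)
    assert nonpolar_solvation(1000.0) / 1000.0 == pytest.approx(0.00586)
    with pytest.raises(ValueError):
        nonpolar_solvation(-1.0)
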