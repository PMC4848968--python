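"""Shared closed-form physics oracles used by the acceptance checks."""

import itertools

import numpy as np
from scipy.sparse import lil_matrix
from scipy.sparse.linalg import spsolve

from mutddg.electrostatics import (
    COULOMB_K,
    DielectricModel,
    _boundary_potential,
    _interp_phi,
    build_grid_arrays,
    coulomb_energy,
    solve_pb,
)
from mutddg.forcefield import build_topology, default_parameters, vdw_energy
from mutddg.structure import Atom, ProteinStructure, ResidueID


def coulomb_pair_energy(r: float, eps: float) -> float:
    """+1e/+1e pair at separation r with both atoms in a class of dielectric
    eps, computed through the package's Coulomb operator."""
    s = ProteinStructure(
        [
            Atom("NZ", "N", ResidueID("A", 1, "", "LYS"), np.zeros(3)),
            Atom("NZ", "N", ResidueID("B", 1, "", "LYS"), np.array([r, 0.0, 0.0])),
        ]
    )
    top = build_topology(s, default_parameters())
    top.charges[:] = (1.0, 1.0)
    return coulomb_energy(s, model=DielectricModel(eps_charged=eps), top=top)


def lj_pair_energy(r: float, eps: float, rmin: float) -> float:
    """Two carbon-class atoms through the package's LJ operator, rescaled to
    the requested well parameters."""
    s = ProteinStructure(
        [
            Atom("CA", "C", ResidueID("A", 1, "", "GLY"), np.zeros(3)),
            Atom("CA", "C", ResidueID("B", 1, "", "GLY"), np.array([r, 0.0, 0.0])),
        ]
    )
    params = default_parameters()
    top = build_topology(s, params)
    top.eps[:] = eps
    top.rmin_half[:] = rmin / 2.0
    return vdw_energy(s, params, top=top)


def reaction_field(q: float = 1.0, R: float = 2.0, eps_in: float = 1.0,
                   eps_out: float = 80.0, scale: float = 1.0) -> float:
    args = (np.zeros((1, 3)), np.array([R]), np.array([q]), np.array([eps_in]))
    solv = build_grid_arrays(*args, eps_solvent=eps_out, scale=scale)
    unif = build_grid_arrays(*args, eps_solvent=eps_out, scale=scale, uniform=True)
    ps = solve_pb(solv)
    pu = solve_pb(unif)
    pt = np.zeros((1, 3))
    dphi = _interp_phi(solv, ps, pt) - _interp_phi(unif, pu, pt)
    return float(0.5 * COULOMB_K * q * dphi[0])


def born_exact(q: float = 1.0, R: float = 2.0, eps_in: float = 1.0,
               eps_out: float = 80.0) -> float:
    return -COULOMB_K * q * q / (2.0 * R) * (1.0 / eps_in - 1.0 / eps_out)


def sor_vs_dense_max_rel_err() -> float:
    """Max relative disagreement between the SOR solve and a sparse-LU direct
    solve of the identical finite-difference system (grid <= 15^3)."""
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
        for di, dj, dk in [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                           (0, 0, 1), (0, 0, -1)]:
            ef = hmean(g.eps[i, j, k], g.eps[i + di, j + dj, k + dk])
            A[I, idx(i + di, j + dj, k + dk)] = ef
            diag += ef
        A[I, I] = -diag
        b[I] = -4 * np.pi * g.charge[i, j, k] / h
    direct = spsolve(A.tocsr(), b).reshape(n, n, n)
    return float(np.max(np.abs(phi - direct)) / np.max(np.abs(direct)))
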