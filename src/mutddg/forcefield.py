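"""Heavy-atom molecular-mechanics model: parameters, topology and energies.

Hydrogens are never built; hydrogen partial charges are folded onto their
parent heavy atom in the bundled parameter table.  Bonded equilibrium values
(bond lengths, angles, impropers) are measured from a reference build of each
residue's own internal-coordinate template, so an ideally built structure sits
at the bottom of its bonded energy surface by construction.  Force constants
are documented module constants.

Energy conventions (CHARMM-style, kcal/mol):
    bond     k (r - r0)^2
    angle    k (theta - theta0)^2        [theta in rad]
    dihedral k (1 + cos(n phi - delta))
    improper k (psi - psi0)^2            [psi in rad]
    LJ       eps [(rmin/r)^12 - 2 (rmin/r)^6], Lorentz-Berthelot combining
1-2 and 1-3 nonbonded pairs are excluded; 1-4 pairs are unscaled (factor 1.0).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Dict, List, Tuple

import numpy as np

from .geometry import bond_angle, dihedral, place_atom
from .residues import (
    as_three_letter,
    build_sidechain,
    default_chis,
    load_hydropathy,
    sidechain_bonds,
)
from .structure import ProteinStructure

# force constants
K_BOND = 300.0        # kcal/mol/A^2
K_ANGLE = 60.0        # kcal/mol/rad^2
K_IMPROPER = 30.0     # kcal/mol/rad^2
K_OMEGA = 3.0         # kcal/mol, 2-fold barrier of the peptide bond
SCALE_14 = 1.0        # 1-4 LJ/Coulomb scaling (unscaled)

# ideal backbone constants shared with the peptide generator
BB_N_CA = 1.458
BB_CA_C = 1.525
BB_C_O = 1.231
BB_C_N = 1.329
ANG_N_CA_C = 111.2
ANG_CA_C_O = 120.5
ANG_CA_C_N = 116.2
ANG_O_C_N = 123.2
ANG_C_N_CA = 121.7

FORMAL_CHARGE = {"ASP": -1.0, "GLU": -1.0, "LYS": 1.0, "ARG": 1.0}


class ParameterError(KeyError):
    """An atom has no entry in the parameter set."""


@dataclass
class AtomParams:
    charge: float
    eps: float
    rmin_half: float
    pb_radius: float


def reference_monomer(aa: str) -> Dict[str, np.ndarray]:
    """Ideal-geometry single residue (backbone + side chain, default chis)."""
    aa = as_three_letter(aa)
    pos: Dict[str, np.ndarray] = {
        "N": np.zeros(3),
        "CA": np.array([BB_N_CA, 0.0, 0.0]),
    }
    pos["C"] = place_atom(
        np.array([0.0, 0.0, 1.0]), pos["N"], pos["CA"], BB_CA_C, ANG_N_CA_C, 0.0
    )
    pos["O"] = place_atom(pos["N"], pos["CA"], pos["C"], BB_C_O, ANG_CA_C_O, -40.0)
    pos.update(build_sidechain(aa, pos, default_chis(aa)))
    return pos


# Planarity / chirality impropers per residue: quadruples of atom names whose
# torsion is restrained to the reference-monomer value.
_IMPROPERS: Dict[str, List[Tuple[str, str, str, str]]] = {
    "ASP": [("CB", "CG", "OD1", "OD2")],
    "GLU": [("CG", "CD", "OE1", "OE2")],
    "ASN": [("CB", "CG", "OD1", "ND2")],
    "GLN": [("CG", "CD", "OE1", "NE2")],
    "ARG": [("NE", "CZ", "NH1", "NH2")],
}


@lru_cache(maxsize=32)
def _residue_geometry(aa: str):
    """Measured intra-residue equilibrium geometry from the reference build."""
    aa = as_three_letter(aa)
    pos = reference_monomer(aa)
    bonds = [("N", "CA"), ("CA", "C"), ("C", "O")] + sidechain_bonds(aa)
    bond_r0 = {
        frozenset(b): float(np.linalg.norm(pos[b[0]] - pos[b[1]])) for b in bonds
    }
    # angle equilibria for every bonded triple within the residue
    adj: Dict[str, set] = {}
    for a, b in bonds:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    angle_t0 = {}
    for j, nbrs in adj.items():
        for i in nbrs:
            for k in nbrs:
                if i < k:
                    angle_t0[(i, j, k)] = bond_angle(pos[i], pos[j], pos[k])
    impropers = [("N", "CA", "C", "CB")] if aa != "GLY" else []
    impropers += _IMPROPERS.get(aa, [])
    imp_psi0 = {q: dihedral(*(pos[a] for a in q)) for q in impropers}
    return bond_r0, angle_t0, imp_psi0, adj


class ParameterSet:
    """Bundled per-atom nonbonded parameters plus derived bonded tables."""

    def __init__(self) -> None:
        self.atoms: Dict[Tuple[str, str], AtomParams] = {}
        text = (resources.files("mutddg") / "data" / "params.tsv").read_text()
        for line in text.splitlines()[1:]:
            res, atom, q, eps, rmh, pbr = line.split("\t")
            self.atoms[(res, atom)] = AtomParams(
                float(q), float(eps), float(rmh), float(pbr)
            )
        self._normalize_charges()

    def _normalize_charges(self) -> None:
        # exact formal charge per residue: remainder goes onto CB (CA for GLY)
        by_res: Dict[str, List[str]] = {}
        for res, atom in self.atoms:
            by_res.setdefault(res, []).append(atom)
        for res, names in by_res.items():
            total = sum(self.atoms[(res, a)].charge for a in names)
            target = FORMAL_CHARGE.get(res, 0.0)
            sink = "CB" if "CB" in names else "CA"
            self.atoms[(res, sink)].charge += target - total

    def get(self, res_aa: str, atom_name: str) -> AtomParams:
        try:
            return self.atoms[(res_aa, atom_name)]
        except KeyError:
            raise ParameterError(
                f"no parameters for atom {atom_name!r} of residue {res_aa!r}"
            ) from None

    # bonded tables (spec contract); equilibria from the residue templates
    def bond_table(self, aa: str) -> Dict[frozenset, Tuple[float, float]]:
        r0, _, _, _ = _residue_geometry(aa)
        return {pair: (K_BOND, v) for pair, v in r0.items()}

    def angle_table(self, aa: str) -> Dict[tuple, Tuple[float, float]]:
        _, t0, _, _ = _residue_geometry(aa)
        return {trip: (K_ANGLE, v) for trip, v in t0.items()}

    def improper_table(self, aa: str) -> Dict[tuple, Tuple[float, float]]:
        _, _, psi0, _ = _residue_geometry(aa)
        return {quad: (K_IMPROPER, v) for quad, v in psi0.items()}


@lru_cache(maxsize=1)
def default_parameters() -> ParameterSet:
    return ParameterSet()


@dataclass
class Topology:
    """Indexed bonded terms and nonbonded bookkeeping for one structure."""

    n_atoms: int
    bonds: np.ndarray          # (nb, 2) int
    bond_k: np.ndarray
    bond_r0: np.ndarray
    angles: np.ndarray         # (na, 3) int
    angle_k: np.ndarray
    angle_t0: np.ndarray       # degrees
    dihedrals: np.ndarray      # (nd, 4) int
    dihedral_k: np.ndarray
    dihedral_n: np.ndarray
    dihedral_d: np.ndarray     # degrees
    impropers: np.ndarray      # (ni, 4) int
    improper_k: np.ndarray
    improper_psi0: np.ndarray  # degrees
    charges: np.ndarray
    eps: np.ndarray
    rmin_half: np.ndarray
    pb_radius: np.ndarray
    exclusion: np.ndarray      # (n, n) bool, True = excluded (1-2/1-3 or self)
    pairs14: np.ndarray        # (n, n) bool


def build_topology(structure: ProteinStructure, params: ParameterSet) -> Topology:
    atoms = structure.atoms
    n = len(atoms)
    index: Dict[Tuple[Tuple[str, int, str], str], int] = {}
    for i, a in enumerate(atoms):
        index[(a.res.key(), a.name)] = i

    charges = np.zeros(n)
    eps = np.zeros(n)
    rmh = np.zeros(n)
    pbr = np.zeros(n)
    for i, a in enumerate(atoms):
        p = params.get(a.res.aa, a.name)
        charges[i], eps[i], rmh[i], pbr[i] = p.charge, p.eps, p.rmin_half, p.pb_radius

    bonds: List[Tuple[int, int]] = []
    bond_r0: List[float] = []
    residues = structure.residues()

    def idx(rid_key, name):
        return index.get((rid_key, name))

    for rid, ratoms in residues:
        table = params.bond_table(rid.aa)
        for pair, (_, r0) in table.items():
            a, b = tuple(pair)
            ia, ib = idx(rid.key(), a), idx(rid.key(), b)
            if ia is not None and ib is not None:
                bonds.append((ia, ib))
                bond_r0.append(r0)

    # peptide bonds between consecutive residues of the same chain
    peptide_pairs: List[Tuple[int, int]] = []  # (res index, res index)
    for k in range(len(residues) - 1):
        rid1, a1 = residues[k]
        rid2, a2 = residues[k + 1]
        if rid1.chain != rid2.chain:
            continue
        ic = idx(rid1.key(), "C")
        jn = idx(rid2.key(), "N")
        if ic is None or jn is None:
            continue
        d = float(np.linalg.norm(atoms[ic].xyz - atoms[jn].xyz))
        if d < 2.0:
            bonds.append((ic, jn))
            bond_r0.append(BB_C_N)
            peptide_pairs.append(k)

    bonds_arr = np.array(bonds, int).reshape(-1, 2)
    adj: Dict[int, set] = {i: set() for i in range(n)}
    for i, j in bonds:
        adj[i].add(j)
        adj[j].add(i)

    # angles
    angles: List[Tuple[int, int, int]] = []
    angle_t0: List[float] = []
    inter_angle = {
        ("CA", "C", "N"): ANG_CA_C_N,
        ("O", "C", "N"): ANG_O_C_N,
        ("C", "N", "CA"): ANG_C_N_CA,
        ("C", "N", "CD"): 125.0,  # proline
    }
    for j in range(n):
        nbrs = sorted(adj[j])
        for ai in range(len(nbrs)):
            for bi in range(ai + 1, len(nbrs)):
                i, k = nbrs[ai], nbrs[bi]
                ri, rj, rk = atoms[i].res, atoms[j].res, atoms[k].res
                if ri.key() == rj.key() == rk.key():
                    table = params.angle_table(rj.aa)
                    key = tuple(sorted((atoms[i].name, atoms[k].name)))
                    t0 = table.get((key[0], atoms[j].name, key[1]))
                    if t0 is None:
                        continue
                    angles.append((i, j, k))
                    angle_t0.append(t0[1])
                else:
                    names = (atoms[i].name, atoms[j].name, atoms[k].name)
                    t0 = inter_angle.get(names) or inter_angle.get(names[::-1])
                    if t0 is not None:
                        angles.append((i, j, k))
                        angle_t0.append(t0)

    # dihedrals: only the peptide omega torsion carries a barrier
    dihedrals: List[Tuple[int, int, int, int]] = []
    dihedral_k: List[float] = []
    for k in peptide_pairs:
        rid1, _ = residues[k]
        rid2, _ = residues[k + 1]
        quad = (
            idx(rid1.key(), "CA"),
            idx(rid1.key(), "C"),
            idx(rid2.key(), "N"),
            idx(rid2.key(), "CA"),
        )
        if None not in quad:
            dihedrals.append(quad)  # type: ignore[arg-type]
            dihedral_k.append(K_OMEGA)

    # impropers: intra-residue (chirality, sp2 planarity) + peptide planarity
    impropers: List[Tuple[int, int, int, int]] = []
    imp_psi0: List[float] = []
    for rid, ratoms in residues:
        for quad, (_, psi0) in params.improper_table(rid.aa).items():
            ids = tuple(idx(rid.key(), a) for a in quad)
            if None not in ids:
                impropers.append(ids)  # type: ignore[arg-type]
                imp_psi0.append(psi0)
    for k in peptide_pairs:
        rid1, _ = residues[k]
        rid2, _ = residues[k + 1]
        quad = (
            idx(rid1.key(), "CA"),
            idx(rid1.key(), "C"),
            idx(rid1.key(), "O"),
            idx(rid2.key(), "N"),
        )
        if None not in quad:
            impropers.append(quad)  # type: ignore[arg-type]
            imp_psi0.append(180.0)

    # exclusions
    excl = np.eye(n, dtype=bool)
    p14 = np.zeros((n, n), bool)
    for i, j in bonds:
        excl[i, j] = excl[j, i] = True
    for j in range(n):
        nbrs = sorted(adj[j])
        for a in nbrs:
            for b in nbrs:
                if a != b:
                    excl[a, b] = excl[b, a] = True
    # 1-4: bonded path of length 3
    for i, j in bonds:
        for a in adj[i] - {j}:
            for b in adj[j] - {i}:
                if a != b and not excl[a, b]:
                    p14[a, b] = p14[b, a] = True

    return Topology(
        n_atoms=n,
        bonds=bonds_arr,
        bond_k=np.full(len(bonds), K_BOND),
        bond_r0=np.array(bond_r0),
        angles=np.array(angles, int).reshape(-1, 3),
        angle_k=np.full(len(angles), K_ANGLE),
        angle_t0=np.array(angle_t0),
        dihedrals=np.array(dihedrals, int).reshape(-1, 4),
        dihedral_k=np.array(dihedral_k),
        dihedral_n=np.full(len(dihedrals), 2.0),
        dihedral_d=np.full(len(dihedrals), 180.0),
        impropers=np.array(impropers, int).reshape(-1, 4),
        improper_k=np.full(len(impropers), K_IMPROPER),
        improper_psi0=np.array(imp_psi0),
        charges=charges,
        eps=eps,
        rmin_half=rmh,
        pb_radius=pbr,
        exclusion=excl,
        pairs14=p14,
    )


@dataclass
class EnergyBreakdown:
    bond: float = 0.0
    angle: float = 0.0
    dihedral: float = 0.0
    improper: float = 0.0
    vdw: float = 0.0
    coulomb: float = 0.0
    solv_polar: float = 0.0
    solv_nonpolar: float = 0.0
    sas: float = 0.0

    @property
    def internal(self) -> float:
        return self.bond + self.angle + self.dihedral + self.improper


def _wrap_deg(x: np.ndarray) -> np.ndarray:
    return (x + 180.0) % 360.0 - 180.0


def _dihedrals_vec(xyz: np.ndarray, quads: np.ndarray) -> np.ndarray:
    if len(quads) == 0:
        return np.zeros(0)
    p0, p1, p2, p3 = (xyz[quads[:, k]] for k in range(4))
    b0, b1, b2 = p0 - p1, p2 - p1, p3 - p2
    b1n = b1 / np.linalg.norm(b1, axis=1, keepdims=True)
    v = b0 - np.sum(b0 * b1n, axis=1, keepdims=True) * b1n
    w = b2 - np.sum(b2 * b1n, axis=1, keepdims=True) * b1n
    x = np.sum(v * w, axis=1)
    y = np.sum(np.cross(b1n, v) * w, axis=1)
    return np.degrees(np.arctan2(y, x))


def bonded_energy(xyz: np.ndarray, top: Topology) -> EnergyBreakdown:
    e = EnergyBreakdown()
    if len(top.bonds):
        d = np.linalg.norm(xyz[top.bonds[:, 0]] - xyz[top.bonds[:, 1]], axis=1)
        e.bond = float(np.sum(top.bond_k * (d - top.bond_r0) ** 2))
    if len(top.angles):
        i, j, k = top.angles.T
        u = xyz[i] - xyz[j]
        v = xyz[k] - xyz[j]
        cosang = np.sum(u * v, axis=1) / (
            np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1)
        )
        theta = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        e.angle = float(
            np.sum(top.angle_k * np.radians(theta - top.angle_t0) ** 2)
        )
    if len(top.dihedrals):
        phi = _dihedrals_vec(xyz, top.dihedrals)
        e.dihedral = float(
            np.sum(
                top.dihedral_k
                * (1.0 + np.cos(np.radians(top.dihedral_n * phi - top.dihedral_d)))
            )
        )
    if len(top.impropers):
        psi = _dihedrals_vec(xyz, top.impropers)
        e.improper = float(
            np.sum(top.improper_k * np.radians(_wrap_deg(psi - top.improper_psi0)) ** 2)
        )
    return e


def internal_energy(
    structure: ProteinStructure, params: ParameterSet | None = None
) -> EnergyBreakdown:
    """Bonded (internal) energy: bond + angle + dihedral + improper terms."""
    params = params or default_parameters()
    top = build_topology(structure, params)
    return bonded_energy(structure.coords(), top)


def _pair_matrices(top: Topology):
    include = ~top.exclusion
    iu = np.triu_indices(top.n_atoms, 1)
    mask = include[iu]
    return iu, mask


def vdw_energy(
    structure: ProteinStructure,
    params: ParameterSet | None = None,
    top: Topology | None = None,
    xyz: np.ndarray | None = None,
) -> float:
    """12-6 Lennard-Jones over nonbonded pairs (1-2/1-3 excluded, 1-4 full)."""
    params = params or default_parameters()
    top = top or build_topology(structure, params)
    xyz = structure.coords() if xyz is None else xyz
    iu, mask = _pair_matrices(top)
    i, j = iu[0][mask], iu[1][mask]
    if len(i) == 0:
        return 0.0
    r = np.linalg.norm(xyz[i] - xyz[j], axis=1)
    rmin = top.rmin_half[i] + top.rmin_half[j]
    epsij = np.sqrt(top.eps[i] * top.eps[j])
    s6 = (rmin / r) ** 6
    return float(np.sum(epsij * (s6 * s6 - 2.0 * s6)))


def hydrophobicity_delta(wt_aa: str, mt_aa: str, scale: Dict[str, float] | None = None) -> float:
    """Hydropathy-scale difference scale(MT) - scale(WT)."""
    scale = scale or load_hydropathy()
    return scale[as_three_letter(mt_aa)] - scale[as_three_letter(wt_aa)]
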