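"""Mutant construction: side-chain substitution, unfolded-state segments and
steepest-descent clash relief.

The substitution operator strips the mutated residue to its backbone, rebuilds
the new side chain from internal-coordinate templates at each bundled rotamer,
and keeps the rotamer with the lowest steric-overlap score against the rest of
the structure (ties resolved to the lowest rotamer index).  The wild type is
rebuilt through the same operator (a self-substitution), so wild-type and
mutant pass through identical geometric machinery and systematic template
error cancels in energy differences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np

from . import forcefield as ff
from .residues import BACKBONE_ATOMS, as_three_letter, build_sidechain, load_rotamers
from .structure import Atom, ProteinStructure, ResidueID

logger = logging.getLogger(__name__)

COULOMB_K = 332.0636  # kcal A / (mol e^2)
RELAX_DIELECTRIC = 80.0
CLASH_FRACTION = 0.8  # overlap counts below this fraction of the radius sum


@dataclass(frozen=True)
class MutationSpec:
    """One substitution: chain / author position / WT -> MT amino acid."""

    chain: str
    seq: int
    wt_aa: str
    mt_aa: str
    icode: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "wt_aa", as_three_letter(self.wt_aa))
        object.__setattr__(self, "mt_aa", as_three_letter(self.mt_aa))

    @property
    def is_self(self) -> bool:
        return self.wt_aa == self.mt_aa


@dataclass
class StructureQuartet:
    """The four structures the energy model evaluates: folded WT and MT plus
    their 3-residue unfolded-state segments."""

    wt: ProteinStructure
    mt: ProteinStructure
    wt_segment: ProteinStructure
    mt_segment: ProteinStructure


def _site_residue(structure: ProteinStructure, mutation: MutationSpec):
    try:
        return structure.residue(mutation.chain, mutation.seq, mutation.icode)
    except KeyError:
        raise KeyError(
            f"mutation site {mutation.chain}:{mutation.seq}{mutation.icode} "
            "not found in structure"
        ) from None


def clash_score(
    coords_a: np.ndarray,
    radii_a: np.ndarray,
    coords_b: np.ndarray,
    radii_b: np.ndarray,
) -> float:
    """Quadratic steric-overlap penalty between two atom sets."""
    if len(coords_a) == 0 or len(coords_b) == 0:
        return 0.0
    d = np.linalg.norm(coords_a[:, None, :] - coords_b[None, :, :], axis=2)
    limit = CLASH_FRACTION * (radii_a[:, None] + radii_b[None, :])
    overlap = np.clip(limit - d, 0.0, None)
    return float(np.sum(overlap**2))


def score_rotamers(
    structure: ProteinStructure,
    mutation: MutationSpec,
    params: ff.ParameterSet | None = None,
) -> List[float]:
    """Steric-overlap score of every bundled rotamer of the target residue
    against the rest of the structure (the brute-force enumeration that
    build_mutant minimizes over)."""
    params = params or ff.default_parameters()
    rid, atoms = _site_residue(structure, mutation)
    backbone = {n: atoms[n].xyz for n in BACKBONE_ATOMS if n in atoms}
    other = [
        a
        for a in structure.atoms
        if a.res.key() != rid.key() or a.name in BACKBONE_ATOMS
    ]
    other_xyz = np.array([a.xyz for a in other]).reshape(-1, 3)
    other_rad = np.array([params.get(a.res.aa, a.name).rmin_half for a in other])
    scores = []
    for chis in load_rotamers()[mutation.mt_aa]:
        placed = build_sidechain(mutation.mt_aa, backbone, chis)
        sc_names = list(placed)
        sc_xyz = np.array([placed[n] for n in sc_names]).reshape(-1, 3)
        sc_rad = np.array(
            [params.get(mutation.mt_aa, n).rmin_half for n in sc_names]
        )
        scores.append(clash_score(sc_xyz, sc_rad, other_xyz, other_rad))
    return scores


def build_mutant(
    structure: ProteinStructure,
    mutation: MutationSpec,
    params: ff.ParameterSet | None = None,
) -> ProteinStructure:
    """Substitute the side chain at the mutation site.

    The backbone and every other residue are untouched; the new side chain is
    the lowest-clash bundled rotamer.  Gly targets simply lose the side chain;
    mutations from Gly construct CB from the N/CA/C frame.
    """
    params = params or ff.default_parameters()
    rid, atoms = _site_residue(structure, mutation)
    if rid.aa != mutation.wt_aa:
        raise ValueError(
            f"wild-type mismatch at {mutation.chain}:{mutation.seq}: "
            f"structure has {rid.aa}, mutation says {mutation.wt_aa}"
        )
    missing = [n for n in ("N", "CA", "C") if n not in atoms]
    if missing:
        raise ValueError(f"site {rid} is missing backbone atoms {missing}")

    scores = score_rotamers(structure, mutation, params)
    best = int(np.argmin(scores))  # ties -> lowest index
    chis = load_rotamers()[mutation.mt_aa][best]

    backbone = {n: atoms[n].xyz for n in BACKBONE_ATOMS if n in atoms}
    placed = build_sidechain(mutation.mt_aa, backbone, chis)

    new_rid = ResidueID(rid.chain, rid.seq, rid.icode, mutation.mt_aa)
    new_atoms: List[Atom] = []
    inserted = False
    for a in structure.atoms:
        if a.res.key() != rid.key():
            new_atoms.append(a.copy())
            continue
        if a.name in BACKBONE_ATOMS:
            new_atoms.append(Atom(a.name, a.element, new_rid, a.xyz.copy()))
            if a.name == "O" and not inserted:
                for n, xyz in placed.items():
                    new_atoms.append(Atom(n, n[0], new_rid, np.asarray(xyz)))
                inserted = True
        # old side-chain atoms dropped
    if not inserted:  # residue had no O; append side chain at the end
        idx = max(
            i for i, a in enumerate(new_atoms) if a.res.key() == rid.key()
        )
        for n, xyz in placed.items():
            idx += 1
            new_atoms.insert(idx, Atom(n, n[0], new_rid, np.asarray(xyz)))
    out = ProteinStructure(new_atoms, source=structure.source)
    return out


def rebuild_wildtype(
    structure: ProteinStructure,
    mutation: MutationSpec,
    params: ff.ParameterSet | None = None,
) -> ProteinStructure:
    """Pass the wild type through the same substitution operator (X -> X)."""
    self_mut = MutationSpec(
        mutation.chain, mutation.seq, mutation.wt_aa, mutation.wt_aa, mutation.icode
    )
    return build_mutant(structure, self_mut, params)


def extract_segment(structure: ProteinStructure, chain: str, seq: int, icode: str = "") -> ProteinStructure:
    """The 3 consecutive residues centred on the site, coordinates verbatim.

    At a chain terminus the segment degrades to 2 residues with a warning.
    The fragment ends are left uncapped; bonded terms across the cut bonds are
    simply absent, identically for WT and MT.
    """
    residues = structure.residues()
    chain_res = [(i, rid) for i, (rid, _) in enumerate(residues) if rid.chain == chain]
    pos = None
    for k, (_, rid) in enumerate(chain_res):
        if rid.key() == (chain, seq, icode):
            pos = k
            break
    if pos is None:
        raise KeyError(f"residue {chain}:{seq}{icode} not found")
    lo, hi = max(0, pos - 1), min(len(chain_res) - 1, pos + 1)
    if hi - lo < 2:
        logger.warning(
            "site %s:%s is at a chain terminus; using a %d-residue segment",
            chain, seq, hi - lo + 1,
        )
    keep = {chain_res[k][1].key() for k in range(lo, hi + 1)}
    atoms = [a.copy() for a in structure.atoms if a.res.key() in keep]
    return ProteinStructure(atoms, source=structure.source)


def build_quartet(
    structure: ProteinStructure,
    mutation: MutationSpec,
    params: ff.ParameterSet | None = None,
    relax_steps: int = 0,
) -> StructureQuartet:
    """WT (rebuilt), MT, and their 3-residue segments."""
    wt = rebuild_wildtype(structure, mutation, params)
    mt = build_mutant(structure, mutation, params)
    if relax_steps > 0:
        wt = relax_clashes(wt, relax_steps, params)
        mt = relax_clashes(mt, relax_steps, params)
    wt_seg = extract_segment(wt, mutation.chain, mutation.seq, mutation.icode)
    mt_seg = extract_segment(mt, mutation.chain, mutation.seq, mutation.icode)
    return StructureQuartet(wt, mt, wt_seg, mt_seg)


# ---------------------------------------------------------------------------
# steepest-descent clash relief

def _relax_energy_grad(
    xyz: np.ndarray, top: ff.Topology
) -> Tuple[float, np.ndarray]:
    """Energy and gradient of the relaxation objective: bonded terms + LJ +
    solvent-screened Coulomb (uniform dielectric 80)."""
    n = len(xyz)
    grad = np.zeros_like(xyz)
    energy = 0.0

    if len(top.bonds):
        i, j = top.bonds.T
        dv = xyz[i] - xyz[j]
        d = np.linalg.norm(dv, axis=1)
        diff = d - top.bond_r0
        energy += float(np.sum(top.bond_k * diff**2))
        f = (2.0 * top.bond_k * diff / d)[:, None] * dv
        np.add.at(grad, i, f)
        np.add.at(grad, j, -f)

    if len(top.angles):
        i, j, k = top.angles.T
        u = xyz[i] - xyz[j]
        v = xyz[k] - xyz[j]
        lu = np.linalg.norm(u, axis=1)
        lv = np.linalg.norm(v, axis=1)
        uh = u / lu[:, None]
        vh = v / lv[:, None]
        cosang = np.clip(np.sum(uh * vh, axis=1), -1.0, 1.0)
        theta = np.arccos(cosang)
        t0 = np.radians(top.angle_t0)
        energy += float(np.sum(top.angle_k * (theta - t0) ** 2))
        dedt = 2.0 * top.angle_k * (theta - t0)
        sin = np.sqrt(np.clip(1.0 - cosang**2, 1e-12, None))
        dti = (uh * cosang[:, None] - vh) / (lu * sin)[:, None]
        dtk = (vh * cosang[:, None] - uh) / (lv * sin)[:, None]
        np.add.at(grad, i, dedt[:, None] * dti)
        np.add.at(grad, k, dedt[:, None] * dtk)
        np.add.at(grad, j, -dedt[:, None] * (dti + dtk))

    # dihedrals and impropers: few terms, per-term numeric gradients
    def _numeric(quad, term_energy):
        nonlocal energy
        h = 1e-5
        energy += term_energy(xyz)
        for a in quad:
            for c in range(3):
                xyz[a, c] += h
                ep = term_energy(xyz)
                xyz[a, c] -= 2 * h
                em = term_energy(xyz)
                xyz[a, c] += h
                grad[a, c] += (ep - em) / (2 * h)

    from .geometry import dihedral as _dih

    for row in range(len(top.dihedrals)):
        q = top.dihedrals[row]

        def e_d(x, q=q, row=row):
            phi = _dih(x[q[0]], x[q[1]], x[q[2]], x[q[3]])
            return float(
                top.dihedral_k[row]
                * (1.0 + np.cos(np.radians(top.dihedral_n[row] * phi - top.dihedral_d[row])))
            )

        _numeric(q, e_d)

    for row in range(len(top.impropers)):
        q = top.impropers[row]

        def e_i(x, q=q, row=row):
            psi = _dih(x[q[0]], x[q[1]], x[q[2]], x[q[3]])
            diff = (psi - top.improper_psi0[row] + 180.0) % 360.0 - 180.0
            return float(top.improper_k[row] * np.radians(diff) ** 2)

        _numeric(q, e_i)

    # nonbonded (LJ + screened Coulomb)
    include = ~top.exclusion
    iu = np.triu_indices(n, 1)
    mask = include[iu]
    i, j = iu[0][mask], iu[1][mask]
    if len(i):
        dv = xyz[i] - xyz[j]
        r = np.linalg.norm(dv, axis=1)
        rmin = top.rmin_half[i] + top.rmin_half[j]
        epsij = np.sqrt(top.eps[i] * top.eps[j])
        s6 = (rmin / r) ** 6
        energy += float(np.sum(epsij * (s6 * s6 - 2.0 * s6)))
        dedr = -12.0 * epsij / r * (s6 * s6 - s6)
        qq = COULOMB_K * top.charges[i] * top.charges[j] / (RELAX_DIELECTRIC * r)
        energy += float(np.sum(qq))
        dedr += -qq / r
        f = (dedr / r)[:, None] * dv
        np.add.at(grad, i, f)
        np.add.at(grad, j, -f)
    return energy, grad


def relax_clashes(
    structure: ProteinStructure,
    max_steps: int = 200,
    params: ff.ParameterSet | None = None,
    grad_tol: float = 0.1,
) -> ProteinStructure:
    """Steepest descent with backtracking on the MM energy; the energy is
    non-increasing across accepted steps.  max_steps=0 returns a copy."""
    params = params or ff.default_parameters()
    out = structure.copy()
    if max_steps <= 0:
        return out
    top = ff.build_topology(out, params)
    xyz = out.coords()
    e, g = _relax_energy_grad(xyz, top)
    step = 0.02
    for _ in range(max_steps):
        gnorm = float(np.linalg.norm(g))
        if gnorm < grad_tol:
            break
        direction = -g / max(np.max(np.abs(g)), 1e-12)
        accepted = False
        for _try in range(20):
            trial = xyz + step * direction
            et, gt = _relax_energy_grad(trial, top)
            if et < e:
                xyz, e, g = trial, et, gt
                step = min(step * 1.5, 0.5)
                accepted = True
                break
            step *= 0.5
        if not accepted:
            break
    out.set_coords(xyz)
    return out
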