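"""Canonical amino-acid definitions and internal-coordinate residue templates.

The bundled template file encodes, for every heavy side-chain atom of the 20
canonical residues, a NeRF construction rule (reference atoms, bond length,
bond angle, torsion).  Torsions that rotate with a side-chain dihedral are
stored symbolically ("chi1", "chi2-179.9", ...) so the same template places any
rotamer.  Ring-closing bonds that the construction tree does not imply are
listed separately and are part of the covalent topology.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .geometry import place_atom

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}
CANONICAL_AA = frozenset(AA3_TO_1)

BACKBONE_ATOMS = ("N", "CA", "C", "O")

#: residue dielectric classes used by the electrostatic model
CHARGED_AA = frozenset("RKHDE")
POLAR_AA = frozenset("STNQY")


def as_three_letter(aa: str) -> str:
    aa = aa.strip().upper()
    if len(aa) == 1:
        if aa not in AA1_TO_3:
            raise ValueError(f"unknown amino-acid code {aa!r}")
        return AA1_TO_3[aa]
    if aa not in CANONICAL_AA:
        raise ValueError(f"unknown amino-acid code {aa!r}")
    return aa


def _data_text(name: str) -> str:
    return (resources.files("mutddg") / "data" / name).read_text()


@dataclass(frozen=True)
class TemplateAtom:
    name: str
    a1: str
    a2: str
    a3: str
    bond: float
    angle: float
    chi: int | None     # chi index this torsion rotates with, or None
    offset: float       # literal torsion when chi is None, else offset to chi


_TORSION_RE = re.compile(r"^chi(\d)([+-]\d+(?:\.\d+)?)?$")


@lru_cache(maxsize=1)
def load_templates() -> Dict[str, List[TemplateAtom]]:
    out: Dict[str, List[TemplateAtom]] = {aa: [] for aa in CANONICAL_AA}
    lines = _data_text("templates.tsv").splitlines()[1:]
    for line in lines:
        res, atom, a1, a2, a3, bond, angle, torsion = line.split("\t")
        m = _TORSION_RE.match(torsion)
        if m:
            chi = int(m.group(1))
            off = float(m.group(2) or 0.0)
        else:
            chi = None
            off = float(torsion)
        out[res].append(
            TemplateAtom(atom, a1, a2, a3, float(bond), float(angle), chi, off)
        )
    return out


@lru_cache(maxsize=1)
def load_closure_bonds() -> Dict[str, List[Tuple[str, str]]]:
    out: Dict[str, List[Tuple[str, str]]] = {}
    for line in _data_text("closure_bonds.tsv").splitlines()[1:]:
        res, a, b = line.split("\t")
        out.setdefault(res, []).append((a, b))
    return out


@lru_cache(maxsize=1)
def load_rotamers() -> Dict[str, List[Tuple[float, ...]]]:
    """Bundled coarse rotamer set: aa -> ordered list of chi tuples."""
    out: Dict[str, List[Tuple[float, ...]]] = {}
    for line in _data_text("rotamers.tsv").splitlines()[1:]:
        parts = line.split("\t")
        res = parts[0]
        chis = tuple(float(x) for x in parts[2:] if x != "")
        out.setdefault(res, []).append(chis)
    for aa in ("ALA", "GLY"):
        out[aa] = [()]
    return out


@lru_cache(maxsize=1)
def load_rotamer_counts() -> Dict[str, int]:
    return {
        line.split("\t")[0]: int(line.split("\t")[1])
        for line in _data_text("rotamer_counts.tsv").splitlines()[1:]
    }


@lru_cache(maxsize=1)
def load_hydropathy() -> Dict[str, float]:
    return {
        line.split("\t")[0]: float(line.split("\t")[1])
        for line in _data_text("hydropathy.tsv").splitlines()[1:]
    }


def heavy_atom_names(aa: str) -> List[str]:
    """Backbone + side-chain heavy atom names of a canonical residue."""
    aa = as_three_letter(aa)
    return list(BACKBONE_ATOMS) + [t.name for t in load_templates()[aa]]


def sidechain_bonds(aa: str) -> List[Tuple[str, str]]:
    """Covalent bonds within the residue beyond the N-CA-C(=O) backbone."""
    aa = as_three_letter(aa)
    bonds = [(t.a1, t.name) for t in load_templates()[aa]]
    bonds += load_closure_bonds().get(aa, [])
    return bonds


def build_sidechain(
    aa: str,
    backbone: Dict[str, np.ndarray],
    chis: Sequence[float] = (),
) -> Dict[str, np.ndarray]:
    """Place the side-chain heavy atoms of `aa` onto an existing backbone.

    `backbone` must contain N, CA and C coordinates.  Returns a dict of the
    newly placed atoms (CB onward) in template order.
    """
    aa = as_three_letter(aa)
    pos: Dict[str, np.ndarray] = dict(backbone)
    placed: Dict[str, np.ndarray] = {}
    for t in load_templates()[aa]:
        if t.chi is None:
            torsion = t.offset
        else:
            if t.chi > len(chis):
                raise ValueError(
                    f"{aa} template needs chi{t.chi}, got {len(chis)} values"
                )
            torsion = chis[t.chi - 1] + t.offset
        xyz = place_atom(pos[t.a3], pos[t.a2], pos[t.a1], t.bond, t.angle, torsion)
        pos[t.name] = xyz
        placed[t.name] = xyz
    return placed


def default_chis(aa: str) -> Tuple[float, ...]:
    """First bundled rotamer (the deterministic reference conformation)."""
    return load_rotamers()[as_three_letter(aa)][0]
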