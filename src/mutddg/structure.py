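"""Protein structures and PDB fixed-column input/output.

The in-memory model is deliberately small: an ordered list of heavy atoms,
each carrying its parent residue identity (author chain / number / insertion
code / canonical type).  Only the first MODEL of a file is read, the highest
occupancy alternate location is kept (ties resolved to 'A'), and hydrogens,
HETATM records and waters are dropped: the energy model downstream is a
heavy-atom model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, List, Tuple

import numpy as np

from .residues import BACKBONE_ATOMS, CANONICAL_AA

logger = logging.getLogger(__name__)


class PDBParseError(ValueError):
    """Raised when a PDB file cannot be interpreted."""


@dataclass(frozen=True)
class ResidueID:
    """Author-numbering address of one residue."""

    chain: str
    seq: int
    icode: str = ""
    aa: str = "GLY"

    def key(self) -> Tuple[str, int, str]:
        """Identity without the amino-acid type (used for matching sites)."""
        return (self.chain, self.seq, self.icode)

    def __str__(self) -> str:  # e.g. A:42A/LEU
        return f"{self.chain}:{self.seq}{self.icode}/{self.aa}"


@dataclass
class Atom:
    name: str
    element: str
    res: ResidueID
    xyz: np.ndarray

    def copy(self) -> "Atom":
        return Atom(self.name, self.element, self.res, self.xyz.copy())


@dataclass
class ProteinStructure:
    atoms: List[Atom] = field(default_factory=list)
    source: str = ""

    def __len__(self) -> int:
        return len(self.atoms)

    def copy(self) -> "ProteinStructure":
        return ProteinStructure([a.copy() for a in self.atoms], self.source)

    def coords(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms], float).reshape(-1, 3)

    def set_coords(self, xyz: np.ndarray) -> None:
        for a, p in zip(self.atoms, np.asarray(xyz, float)):
            a.xyz = p.copy()

    @property
    def chains(self) -> List[str]:
        seen: List[str] = []
        for a in self.atoms:
            if a.res.chain not in seen:
                seen.append(a.res.chain)
        return seen

    def residues(self) -> "List[Tuple[ResidueID, Dict[str, Atom]]]":
        """Residues in file order as (id, {atom name: atom})."""
        order: List[ResidueID] = []
        groups: Dict[Tuple[str, int, str], Dict[str, Atom]] = {}
        for a in self.atoms:
            k = a.res.key()
            if k not in groups:
                groups[k] = {}
                order.append(a.res)
            groups[k][a.name] = a
        return [(rid, groups[rid.key()]) for rid in order]

    def residue(self, chain: str, seq: int, icode: str = "") -> Tuple[ResidueID, Dict[str, Atom]]:
        for rid, atoms in self.residues():
            if rid.key() == (chain, seq, icode):
                return rid, atoms
        raise KeyError(f"residue {chain}:{seq}{icode} not found")


def _parse_float(text: str, what: str, lineno: int) -> float:
    try:
        return float(text)
    except ValueError as exc:
        raise PDBParseError(
            f"line {lineno}: unparseable {what} field {text.strip()!r}"
        ) from exc


def read_pdb(path: str | Path) -> ProteinStructure:
    """Read the first model's ATOM records into a ProteinStructure.

    HETATM records, waters and hydrogens are dropped; of alternate locations
    only the highest-occupancy one is kept (tie -> altloc 'A').  Residues with
    an incomplete N/CA/C backbone are dropped with a warning; non-canonical
    residue names are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    # (residue key, atom name) -> (occupancy, altloc, Atom)
    best: Dict[Tuple[Tuple[str, int, str], str], Tuple[float, str, Atom]] = {}
    order: List[Tuple[Tuple[str, int, str], str]] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        rec = line[:6]
        if rec == "ENDMDL":
            break
        if rec != "ATOM  ":
            continue
        name = line[12:16].strip()
        altloc = line[16]
        resname = line[17:20].strip()
        chain = line[21].strip()
        try:
            seq = int(line[22:26])
        except ValueError as exc:
            raise PDBParseError(f"line {lineno}: bad residue number") from exc
        icode = line[26].strip()
        x = _parse_float(line[30:38], "x", lineno)
        y = _parse_float(line[38:46], "y", lineno)
        z = _parse_float(line[46:54], "z", lineno)
        occ = line[54:60].strip()
        occupancy = float(occ) if occ else 1.0
        element = (line[76:78].strip() or name[0]).upper()
        if element == "H" or element == "D":
            continue
        if resname == "HOH":
            continue
        if resname not in CANONICAL_AA:
            raise PDBParseError(
                f"line {lineno}: non-canonical residue {resname!r} is not supported"
            )
        rid = ResidueID(chain, seq, icode, resname)
        atom = Atom(name, element, rid, np.array([x, y, z]))
        key = (rid.key(), name)
        if key not in best:
            best[key] = (occupancy, altloc, atom)
            order.append(key)
        else:
            occ0, alt0, _ = best[key]
            if occupancy > occ0 or (occupancy == occ0 and altloc == "A" and alt0 != "A"):
                best[key] = (occupancy, altloc, atom)

    if not best:
        raise PDBParseError(f"{path}: empty structure (no ATOM records)")

    structure = ProteinStructure([best[k][2] for k in order], source=str(path))

    complete: List[Atom] = []
    bad: set = set()
    for rid, atoms in structure.residues():
        if any(b not in atoms for b in ("N", "CA", "C")):
            bad.add(rid.key())
            logger.warning("residue %s is missing backbone atoms; dropped", rid)
    if bad:
        complete = [a for a in structure.atoms if a.res.key() not in bad]
        structure = ProteinStructure(complete, source=structure.source)
    return structure


def select_chain(structure: ProteinStructure, chain: str) -> ProteinStructure:
    """Keep only the atoms of one chain, preserving order."""
    available = structure.chains
    if chain not in available:
        raise KeyError(
            f"chain {chain!r} not present; available chains: {', '.join(available)}"
        )
    return ProteinStructure(
        [a.copy() for a in structure.atoms if a.res.chain == chain],
        source=structure.source,
    )


def write_pdb(structure: ProteinStructure, path: str | Path) -> None:
    """Write fixed-column ATOM records with a TER per chain and END."""
    if len(structure) == 0:
        raise ValueError("refusing to write an empty structure")
    lines: List[str] = []
    serial = 0
    prev_chain: str | None = None
    last_rid: ResidueID | None = None
    for a in structure.atoms:
        if prev_chain is not None and a.res.chain != prev_chain:
            serial += 1
            lines.append(_ter_line(serial, last_rid))
        serial += 1
        name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
        lines.append(
            f"ATOM  {serial:5d} {name}{'':1s}{a.res.aa:>3s} {a.res.chain:1s}"
            f"{a.res.seq:4d}{a.res.icode or ' ':1s}   "
            f"{a.xyz[0]:8.3f}{a.xyz[1]:8.3f}{a.xyz[2]:8.3f}"
            f"{1.0:6.2f}{0.0:6.2f}          {a.element:>2s}"
        )
        prev_chain = a.res.chain
        last_rid = a.res
    serial += 1
    lines.append(_ter_line(serial, last_rid))
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def _ter_line(serial: int, rid: ResidueID | None) -> str:
    assert rid is not None
    return (
        f"TER   {serial:5d}      {rid.aa:>3s} {rid.chain:1s}"
        f"{rid.seq:4d}{rid.icode or ' ':1s}"
    )


def renumber_order(residues: Iterable[ResidueID]) -> Dict[Tuple[str, int, str], int]:
    """Sequential index per residue key, in structure order."""
    return {rid.key(): i for i, rid in enumerate(residues)}
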