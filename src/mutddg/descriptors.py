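"""Residue descriptors: solvent accessibility, burial class, secondary
structure, and the paired category codes consumed by the knowledge layer.

SASA is numeric Shrake-Rupley with a deterministic golden-spiral sphere point
set (no RNG), so results are bit-reproducible.  Secondary structure comes from
an internal backbone H-bond + phi/psi assigner producing the 5-class
vocabulary H (helix), S (strand), B (bridge), T (turn), C (coil).
"""

from __future__ import annotations

import logging
from functools import lru_cache
from importlib import resources
from typing import Dict, List, Tuple

import numpy as np

from .forcefield import ParameterSet, default_parameters
from .structure import ProteinStructure, ResidueID

logger = logging.getLogger(__name__)

PROBE_RADIUS = 1.4        # water probe, A
N_SPHERE_POINTS = 960
EPS_BURIED = 0.001        # rSASA at or below this counts as buried

LOC_CLASSES = ("B", "PE", "E")
SSE_CLASSES = ("H", "C", "T", "S", "B")

HBOND_NO_MAX = 3.5        # N...O distance, A
HBOND_ANGLE_MIN = 90.0    # C=O...N angle at the carbonyl O, degrees
MIN_HELIX_RUN = 4         # consecutive i,i+4 H-bonds required for H


@lru_cache(maxsize=1)
def _sphere_points(n: int = N_SPHERE_POINTS) -> np.ndarray:
    """Deterministic golden-section spiral points on the unit sphere."""
    k = np.arange(n)
    z = 1.0 - 2.0 * (k + 0.5) / n
    r = np.sqrt(1.0 - z * z)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    theta = golden * k
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def compute_sasa(
    structure: ProteinStructure,
    params: ParameterSet | None = None,
    probe_radius: float = PROBE_RADIUS,
    n_sphere_points: int = N_SPHERE_POINTS,
) -> Tuple[np.ndarray, float]:
    """Shrake-Rupley SASA: per-atom areas (A^2) and their total."""
    params = params or default_parameters()
    xyz = structure.coords()
    radii = np.array(
        [params.get(a.res.aa, a.name).pb_radius for a in structure.atoms]
    )
    r_ext = radii + probe_radius
    pts = _sphere_points(n_sphere_points)
    n = len(xyz)
    areas = np.zeros(n)
    for i in range(n):
        ri = r_ext[i]
        # neighbors whose extended spheres can occlude atom i
        d = np.linalg.norm(xyz - xyz[i], axis=1)
        nb = np.where((d < ri + r_ext) & (np.arange(n) != i))[0]
        surface = xyz[i] + ri * pts
        if len(nb):
            dist2 = np.sum(
                (surface[:, None, :] - xyz[nb][None, :, :]) ** 2, axis=2
            )
            buried = np.any(dist2 < (r_ext[nb] ** 2)[None, :], axis=1)
            frac = 1.0 - np.mean(buried)
        else:
            frac = 1.0
        areas[i] = 4.0 * np.pi * ri * ri * frac
    return areas, float(np.sum(areas))


@lru_cache(maxsize=1)
def load_reference_sasa() -> Dict[str, float]:
    """Maximal per-residue SASA from extended Gly-X-Gly tripeptides computed
    with this module's own algorithm (see scripts/regenerate_ref_sasa.py)."""
    text = (resources.files("mutddg") / "data" / "ref_sasa.tsv").read_text()
    return {
        line.split("\t")[0]: float(line.split("\t")[1])
        for line in text.splitlines()[1:]
    }


def residue_sasa(
    structure: ProteinStructure,
    params: ParameterSet | None = None,
    probe_radius: float = PROBE_RADIUS,
    n_sphere_points: int = N_SPHERE_POINTS,
) -> Dict[Tuple[str, int, str], float]:
    """Summed heavy-atom SASA per residue key."""
    areas, _ = compute_sasa(structure, params, probe_radius, n_sphere_points)
    out: Dict[Tuple[str, int, str], float] = {}
    for a, area in zip(structure.atoms, areas):
        out[a.res.key()] = out.get(a.res.key(), 0.0) + float(area)
    return out


def residue_rsasa(
    structure: ProteinStructure,
    chain: str,
    seq: int,
    icode: str = "",
    params: ParameterSet | None = None,
) -> float:
    """Residue SASA relative to its extended Gly-X-Gly reference maximum."""
    rid, _ = structure.residue(chain, seq, icode)
    per_res = residue_sasa(structure, params)
    ref = load_reference_sasa()[rid.aa]
    return per_res[rid.key()] / ref


def burial_class(rsasa: float, eps_buried: float = EPS_BURIED) -> str:
    """B / PE / E from relative accessibility (thresholds 0 and 0.25)."""
    if rsasa < 0:
        raise ValueError("rSASA must be non-negative")
    if rsasa <= eps_buried:
        return "B"
    if rsasa <= 0.25:
        return "PE"
    return "E"


# ---------------------------------------------------------------------------
# secondary structure

def _backbone_arrays(structure: ProteinStructure):
    residues = structure.residues()
    keep = [
        (rid, atoms)
        for rid, atoms in residues
        if all(n in atoms for n in ("N", "CA", "C", "O"))
    ]
    rids = [rid for rid, _ in keep]
    N = np.array([a["N"].xyz for _, a in keep]).reshape(-1, 3)
    O = np.array([a["O"].xyz for _, a in keep]).reshape(-1, 3)
    C = np.array([a["C"].xyz for _, a in keep]).reshape(-1, 3)
    return rids, N, O, C


def _hbond_matrix(rids: List[ResidueID], N, O, C) -> np.ndarray:
    """hb[i, j] True when N(i) donates to O(j)."""
    n = len(rids)
    hb = np.zeros((n, n), bool)
    if n == 0:
        return hb
    d = np.linalg.norm(N[:, None, :] - O[None, :, :], axis=2)
    # C=O...N angle at O
    co = N[:, None, :] - O[None, :, :]          # O -> N
    cv = C - O                                   # O -> C
    cos = np.sum(co * cv[None, :, :], axis=2) / (
        np.clip(d, 1e-9, None) * np.linalg.norm(cv, axis=1)[None, :]
    )
    ang = np.degrees(np.arccos(np.clip(cos, -1.0, 1.0)))  # C=O...N angle at O
    for i in range(n):
        for j in range(n):
            if rids[i].chain == rids[j].chain and abs(i - j) < 2:
                continue
            if d[i, j] < HBOND_NO_MAX and ang[i, j] >= HBOND_ANGLE_MIN:
                hb[i, j] = True
    return hb


def assign_sse(structure: ProteinStructure) -> Dict[Tuple[str, int, str], str]:
    """Five-class secondary structure from backbone H-bonds.

    Helix: runs of >= 4 consecutive i,i+4 H-bonds.  Strand/bridge: pairs of
    mutual inter-strand H-bonds; a rung with a neighbor within 2 residues on
    both strands makes a ladder (S), an isolated rung a bridge (B).  Turn:
    i,i+3 H-bond.  Everything else is coil.  Precedence H > S > B > T > C.
    """
    rids, N, O, C = _backbone_arrays(structure)
    n = len(rids)
    labels = {rid.key(): "C" for rid, _ in structure.residues()}
    if n < 3:
        if n:
            logger.warning("chain too short for secondary structure; all coil")
        return labels
    hb = _hbond_matrix(rids, N, O, C)
    rank = {"C": 0, "T": 1, "B": 2, "S": 3, "H": 4}

    def put(i: int, lab: str) -> None:
        k = rids[i].key()
        if rank[lab] > rank[labels[k]]:
            labels[k] = lab

    same_chain = [
        [rids[i].chain == rids[j].chain for j in range(n)] for i in range(n)
    ]

    # helices: donor index i means O(i) <- N(i+4)
    donors = [
        i
        for i in range(n - 4)
        if same_chain[i][i + 4] and hb[i + 4, i]
    ]
    runs: List[List[int]] = []
    for i in donors:
        if runs and runs[-1][-1] == i - 1:
            runs[-1].append(i)
        else:
            runs.append([i])
    for run in runs:
        if len(run) >= MIN_HELIX_RUN:
            for r in range(run[0] + 1, run[-1] + 4 + 1):
                put(r, "H")

    # turns: O(i) <- N(i+3)
    for i in range(n - 3):
        if same_chain[i][i + 3] and hb[i + 3, i]:
            put(i + 1, "T")
            put(i + 2, "T")

    # bridges: mutual N/O H-bonds between sequence-distant residues
    bridges = []
    for i in range(n):
        for j in range(i + 1, n):
            if same_chain[i][j] and j - i < 3:
                continue
            if hb[i, j] and hb[j, i]:
                bridges.append((i, j))
    laddered = set()
    for a in range(len(bridges)):
        for b in range(len(bridges)):
            if a == b:
                continue
            i1, j1 = bridges[a]
            i2, j2 = bridges[b]
            if 1 <= abs(i2 - i1) <= 2 and 1 <= abs(j2 - j1) <= 2:
                laddered.add(a)
                laddered.add(b)
                for r in range(min(i1, i2), max(i1, i2) + 1):
                    put(r, "S")
                for r in range(min(j1, j2), max(j1, j2) + 1):
                    put(r, "S")
    for a, (i, j) in enumerate(bridges):
        if a not in laddered:
            put(i, "B")
            put(j, "B")
    return labels


def pair_code(a: str, b: str, kind: str | None = None) -> str:
    """Canonical category pair: burial pairs are dash-joined ("B-PE"), SSE
    pairs plain-joined ("HH"), labels sorted lexicographically.

    `kind` ("loc" or "sse") disambiguates the (B, B) pair, which exists in
    both vocabularies.
    """
    if kind is None:
        if a in ("PE", "E") or b in ("PE", "E"):
            kind = "loc"
        elif (a in SSE_CLASSES and a != "B") or (b in SSE_CLASSES and b != "B"):
            kind = "sse"
        else:
            raise ValueError("pair (B, B) is ambiguous; pass kind='loc' or 'sse'")
    if kind == "loc":
        for x in (a, b):
            if x not in LOC_CLASSES:
                raise ValueError(f"invalid burial class {x!r}")
        return "-".join(sorted((a, b)))
    if kind == "sse":
        for x in (a, b):
            if x not in SSE_CLASSES:
                raise ValueError(f"invalid SSE class {x!r}")
        return "".join(sorted((a, b)))
    raise ValueError(f"unknown pair kind {kind!r}")
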