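"""Deterministic generators: ideal peptides, labeled mutation datasets and
linear regression datasets.

Every generator is a pure function of its arguments (plus an explicit seed for
the stochastic ones); there is no hidden global RNG state.  The labeled-dataset
generator emulates the statistical shape of a curated stability database:
per-category probabilities of a mutation causing a "large" (|ddG| >= 1
kcal/mol) change, a configurable overall large/small imbalance, and two
log-normal magnitude distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .forcefield import (
    ANG_CA_C_N,
    ANG_CA_C_O,
    ANG_C_N_CA,
    ANG_N_CA_C,
    BB_CA_C,
    BB_C_N,
    BB_C_O,
    BB_N_CA,
)
from .geometry import place_atom
from .residues import AA1_TO_3, BACKBONE_ATOMS, build_sidechain, default_chis
from .structure import Atom, ProteinStructure, ResidueID

PHI_PSI = {
    "helix": (-57.0, -47.0),
    "extended": (-120.0, 120.0),
    "sheet": (-139.0, 135.0),
}


def _build_backbone(
    n_res: int, phi: float, psi: float, omega: float = 180.0
) -> List[Dict[str, np.ndarray]]:
    """NeRF backbone trace at fixed (phi, psi); returns per-residue coords."""
    out: List[Dict[str, np.ndarray]] = []
    # first residue in a canonical local frame
    n = np.zeros(3)
    ca = np.array([BB_N_CA, 0.0, 0.0])
    c = place_atom(np.array([0.0, 1.0, 0.0]), n, ca, BB_CA_C, ANG_N_CA_C, 0.0)
    out.append({"N": n, "CA": ca, "C": c})
    for _ in range(1, n_res):
        prev = out[-1]
        n = place_atom(prev["N"], prev["CA"], prev["C"], BB_C_N, ANG_CA_C_N, psi)
        ca = place_atom(prev["CA"], prev["C"], n, BB_N_CA, ANG_C_N_CA, omega)
        c = place_atom(prev["C"], n, ca, BB_CA_C, ANG_N_CA_C, phi)
        out.append({"N": n, "CA": ca, "C": c})
    # carbonyl oxygens: O opposite the next N (torsion psi + 180)
    for i, res in enumerate(out):
        if i + 1 < len(out):
            psi_i = psi
        else:
            psi_i = psi  # last residue keeps the conformational psi
        res["O"] = place_atom(res["N"], res["CA"], res["C"], BB_C_O, ANG_CA_C_O, psi_i + 180.0)
    return out


def _to_structure(
    sequence: str,
    backbones: List[Dict[str, np.ndarray]],
    chain: str,
    start_seq: int,
) -> List[Atom]:
    atoms: List[Atom] = []
    for i, (aa1, bb) in enumerate(zip(sequence, backbones)):
        aa3 = AA1_TO_3[aa1]
        rid = ResidueID(chain, start_seq + i, "", aa3)
        pos = dict(bb)
        pos.update(build_sidechain(aa3, bb, default_chis(aa3)))
        for name in list(BACKBONE_ATOMS) + [
            k for k in pos if k not in BACKBONE_ATOMS
        ]:
            atoms.append(Atom(name, name[0], rid, np.asarray(pos[name], float)))
    return atoms


def make_peptide(
    sequence: str,
    conformation: str = "extended",
    chain: str = "A",
    start_seq: int = 1,
) -> ProteinStructure:
    """Ideal-geometry peptide at canonical phi/psi.

    Conformations: "helix" (-57/-47), "extended" (-120/+120) and "sheet_pair"
    (two H-bonded antiparallel strands at -139/+135, chains A and B).
    """
    sequence = sequence.upper()
    if len(sequence) < 3:
        raise ValueError("sequence must have length >= 3")
    for aa in sequence:
        if aa not in AA1_TO_3:
            raise ValueError(f"invalid residue letter {aa!r}")

    if conformation == "sheet_pair":
        return _make_sheet_pair(sequence, start_seq)
    if conformation not in PHI_PSI:
        raise ValueError(f"unknown conformation {conformation!r}")
    phi, psi = PHI_PSI[conformation]
    bbs = _build_backbone(len(sequence), phi, psi)
    return ProteinStructure(
        _to_structure(sequence, bbs, chain, start_seq), source=f"synthetic:{conformation}"
    )


def _strand_axis(bbs: List[Dict[str, np.ndarray]]) -> Tuple[np.ndarray, np.ndarray]:
    ca = np.array([b["CA"] for b in bbs])
    center = ca.mean(axis=0)
    axis = ca[-1] - ca[0]
    return center, axis / np.linalg.norm(axis)


def _count_hbonds(a1: List[Dict[str, np.ndarray]], a2: List[Dict[str, np.ndarray]]) -> int:
    cnt = 0
    for r1 in a1:
        for r2 in a2:
            if np.linalg.norm(r1["N"] - r2["O"]) < 3.4:
                cnt += 1
            if np.linalg.norm(r2["N"] - r1["O"]) < 3.4:
                cnt += 1
    return cnt


def _make_sheet_pair(sequence: str, start_seq: int) -> ProteinStructure:
    """Two antiparallel strands; the partner placement is a deterministic grid
    search maximizing the number of inter-strand N...O contacts."""
    phi, psi = PHI_PSI["sheet"]
    bbs = _build_backbone(len(sequence), phi, psi)
    center, axis = _strand_axis(bbs)

    # orthonormal frame around the strand axis
    ref = np.array([0.0, 0.0, 1.0])
    perp1 = ref - np.dot(ref, axis) * axis
    perp1 /= np.linalg.norm(perp1)
    perp2 = np.cross(axis, perp1)

    def flipped(offset: np.ndarray, roll: float) -> List[Dict[str, np.ndarray]]:
        # 180-degree rotation about perp1 reverses the strand direction
        cosr, sinr = np.cos(np.radians(roll)), np.sin(np.radians(roll))
        out = []
        for bb in bbs:
            res = {}
            for k, p in bb.items():
                v = p - center
                # rotate pi about perp1
                v = 2.0 * np.dot(v, perp1) * perp1 - v
                # roll about the (now reversed) strand axis
                a = np.dot(v, axis)
                b1 = np.dot(v, perp1)
                b2 = np.dot(v, perp2)
                b1r = b1 * cosr - b2 * sinr
                b2r = b1 * sinr + b2 * cosr
                res[k] = center + a * axis + b1r * perp1 + b2r * perp2 + offset
            out.append(res)
        return out[::-1]

    best = None
    for du in np.arange(-3.5, 3.51, 0.25):
        for dv in np.arange(4.0, 6.01, 0.25):
            for roll in np.arange(0.0, 360.0, 15.0):
                cand = flipped(du * axis + dv * perp2, roll)
                score = _count_hbonds(bbs, cand)
                key = (score, -abs(du))
                if best is None or key > best[0]:
                    best = (key, cand)
    partner = best[1]

    atoms = _to_structure(sequence, bbs, "A", start_seq)
    atoms += _to_structure(sequence, partner, "B", start_seq)
    return ProteinStructure(atoms, source="synthetic:sheet_pair")


# ---------------------------------------------------------------------------
# labeled mutation datasets

LOC_CODES = ("B-B", "B-PE", "E-E", "E-PE", "PE-PE")
SSE_CODES = ("BB", "CC", "CH", "CS", "CT", "HH", "HS", "HT", "SS", "ST", "TT")
AA_LETTERS = tuple("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class SyntheticDatasetSpec:
    """Generative description of a labeled stability dataset.

    Rates are P(large effect | category).  Defaults are balanced (0.5 in every
    category, no class imbalance), the fixed point of the flag machinery.
    """

    n: int = 1000
    wt_rates: Dict[str, float] = field(
        default_factory=lambda: {a: 0.5 for a in AA_LETTERS}
    )
    mt_rates: Dict[str, float] = field(
        default_factory=lambda: {a: 0.5 for a in AA_LETTERS}
    )
    loc_rates: Dict[str, float] = field(
        default_factory=lambda: {c: 0.5 for c in LOC_CODES}
    )
    sse_rates: Dict[str, float] = field(
        default_factory=lambda: {c: 0.5 for c in SSE_CODES}
    )
    p_large: float = 0.5          # marginal large-effect fraction
    small_logmu: float = -0.9     # log-normal for |ddG| < 1
    small_logsd: float = 0.6
    large_logmu: float = 0.0      # 1 + log-normal for |ddG| >= 1
    large_logsd: float = 0.8


def _sample_category(
    rng: np.random.Generator, rates: Dict[str, float], large: bool
) -> str:
    cats = list(rates)
    w = np.array([rates[c] if large else 1.0 - rates[c] for c in cats], float)
    if w.sum() <= 0:
        w = np.ones(len(cats))
    return cats[rng.choice(len(cats), p=w / w.sum())]


def make_labeled_dataset(spec: SyntheticDatasetSpec, seed: int) -> pd.DataFrame:
    """Sample a labeled dataset whose per-category large-effect rates converge
    to the specified rates (flags conditionally independent given the
    large/small class)."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(spec.n):
        large = rng.random() < spec.p_large
        wt = _sample_category(rng, spec.wt_rates, large)
        mt = _sample_category(rng, spec.mt_rates, large)
        while mt == wt:
            mt = _sample_category(rng, spec.mt_rates, large)
        loc = _sample_category(rng, spec.loc_rates, large)
        sse = _sample_category(rng, spec.sse_rates, large)
        if large:
            mag = 1.0 + rng.lognormal(spec.large_logmu, spec.large_logsd)
        else:
            mag = min(0.999, rng.lognormal(spec.small_logmu, spec.small_logsd))
        sign = 1.0 if rng.random() < 0.5 else -1.0
        rows.append(
            {
                "protein": "SYN",
                "chain": "A",
                "position": i + 1,
                "wt": wt,
                "mt": mt,
                "ddg": sign * mag,
                "ph": 7.0,
                "loc_code": loc,
                "sse_code": sse,
                "source": "synthetic",
            }
        )
    return pd.DataFrame(rows)


def make_linear_dataset(
    weights: Dict[str, float],
    intercept: float,
    noise_sd: float,
    n: int,
    seed: int,
) -> Tuple[pd.DataFrame, np.ndarray]:
    """Standard-normal features with y = X w + w0 + noise."""
    rng = np.random.default_rng(seed)
    names = list(weights)
    X = rng.normal(size=(n, len(names)))
    y = X @ np.array([weights[k] for k in names]) + intercept
    if noise_sd > 0:
        y = y + rng.normal(scale=noise_sd, size=n)
    return pd.DataFrame(X, columns=names), y


def make_two_regime_dataset(
    n: int,
    seed: int,
    noise_sd: float = 0.5,
) -> Tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Features + y generated from two different linear models selected by a
    binary regime label (the generative analogue of the small/large split).

    Returns (features, y, regime) where regime is a boolean array
    (True = large).
    """
    rng = np.random.default_rng(seed)
    names = ["d_ie", "dd_ve", "dd_ee", "dd_sp", "d_ssum"]
    X = rng.normal(size=(n, len(names)))
    regime = rng.random(n) < 0.5
    w_small = np.array([0.09, 0.08, 0.59, 0.45, -0.13])
    w_large = np.array([-0.30, 0.90, -0.40, 1.50, 0.80])
    y = np.where(regime, X @ w_large - 2.27, X @ w_small - 0.744)
    y = y + rng.normal(scale=noise_sd, size=n)
    return pd.DataFrame(X, columns=names), y, regime
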