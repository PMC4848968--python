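"""Regenerate the bundled data tables under src/mutddg/data/.

Internal-coordinate side-chain templates are measured from biotite's CCD ideal
residue geometries, expressed relative to the standard chi torsions so that
rotamers can be placed at arbitrary chi values.  The remaining tables (charges,
LJ parameters, rotamer sets, hydropathy scale, rotamer counts, probability
tables, weight sets) are authored here.

Run from the repository root:  python scripts/regenerate_data.py
"""

from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import biotite.structure.info as info

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))
from mutddg.geometry import bond_angle, dihedral, distance  # noqa: E402

DATA = Path(__file__).resolve().parents[1] / "src" / "mutddg" / "data"
DATA.mkdir(parents=True, exist_ok=True)

AA3 = [
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
]

# Standard chi-angle definitions (atom quadruples).
CHI_ATOMS = {
    "ARG": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "NE"), ("CG", "CD", "NE", "CZ")],
    "ASN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "ASP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "CYS": [("N", "CA", "CB", "SG")],
    "GLN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "GLU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "HIS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "ILE": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "LEU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "LYS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "CE"), ("CG", "CD", "CE", "NZ")],
    "MET": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"),
            ("CB", "CG", "SD", "CE")],
    "PHE": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "PRO": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD")],
    "SER": [("N", "CA", "CB", "OG")],
    "THR": [("N", "CA", "CB", "OG1")],
    "TRP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TYR": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "VAL": [("N", "CA", "CB", "CG1")],
}

# NeRF construction tree for side-chain atoms: (atom, a1, a2, a3, tie)
# tie = ("chi", k) -> torsion stored as chiK+offset; tie = "abs" -> literal.
TREE = {
    "ALA": [],
    "SER": [("OG", "CB", "CA", "N", ("chi", 1))],
    "CYS": [("SG", "CB", "CA", "N", ("chi", 1))],
    "THR": [("OG1", "CB", "CA", "N", ("chi", 1)),
            ("CG2", "CB", "CA", "N", ("chi", 1))],
    "VAL": [("CG1", "CB", "CA", "N", ("chi", 1)),
            ("CG2", "CB", "CA", "N", ("chi", 1))],
    "LEU": [("CG", "CB", "CA", "N", ("chi", 1)),
            ("CD1", "CG", "CB", "CA", ("chi", 2)),
            ("CD2", "CG", "CB", "CA", ("chi", 2))],
    "ILE": [("CG1", "CB", "CA", "N", ("chi", 1)),
            ("CG2", "CB", "CA", "N", ("chi", 1)),
            ("CD1", "CG1", "CB", "CA", ("chi", 2))],
    "MET": [("CG", "CB", "CA", "N", ("chi", 1)),
            ("SD", "CG", "CB", "CA", ("chi", 2)),
            ("CE", "SD", "CG", "CB", ("chi", 3))],
    "PRO": [("CG", "CB", "CA", "N", ("chi", 1)),
            ("CD", "CG", "CB", "CA", ("chi", 2))],
    "ASP": [("CG", "CB", "CA", "N", ("chi", 1)),
            ("OD1", "CG", "CB", "CA", ("chi", 2)),
            ("OD2", "CG", "CB", "CA", ("chi", 2))],
    "ASN": [("CG", "CB", "CA", "N", ("chi", 1)),
            ("OD1", "CG", "CB", "CA", ("chi", 2)),
            ("ND2", "CG", "CB", "CA", ("chi", 2))],
    "GLU": [("CG", "CB", "CA", "N", ("chi", 1)),
            ("CD", "CG", "CB", "CA", ("chi", 2)),
            ("OE1", "CD", "CG", "CB", ("chi", 3)),
            ("OE2", "CD", "CG", "CB", ("chi", 3))],
    "GLN": [("CG", "CB", "CA", "N", ("chi", 1)),
            ("CD", "CG", "CB", "CA", ("chi", 2)),
            ("OE1", "CD", "CG", "CB", ("chi", 3)),
            ("NE2", "CD", "CG", "CB", ("chi", 3))],
    "LYS": [("CG", "CB", "CA", "N", ("chi", 1)),
            ("CD", "CG", "CB", "CA", ("chi", 2)),
            ("CE", "CD", "CG", "CB", ("chi", 3)),
            ("NZ", "CE", "CD", "CG", ("chi", 4))],
    "ARG": [("CG", "CB", "CA", "N", ("chi", 1)),
            ("CD", "CG", "CB", "CA", ("chi", 2)),
            ("NE", "CD", "CG", "CB", ("chi", 3)),
            ("CZ", "NE", "CD", "CG", ("chi", 4)),
            ("NH1", "CZ", "NE", "CD", "abs"),
            ("NH2", "CZ", "NE", "CD", "abs")],
    "HIS": [("CG", "CB", "CA", "N", ("chi", 1)),
            ("ND1", "CG", "CB", "CA", ("chi", 2)),
            ("CD2", "CG", "CB", "CA", ("chi", 2)),
            ("CE1", "ND1", "CG", "CB", "abs"),
            ("NE2", "CE1", "ND1", "CG", "abs")],
    "PHE": [("CG", "CB", "CA", "N", ("chi", 1)),
            ("CD1", "CG", "CB", "CA", ("chi", 2)),
            ("CD2", "CG", "CB", "CA", ("chi", 2)),
            ("CE1", "CD1", "CG", "CB", "abs"),
            ("CE2", "CD2", "CG", "CB", "abs"),
            ("CZ", "CE1", "CD1", "CG", "abs")],
    "TYR": [("CG", "CB", "CA", "N", ("chi", 1)),
            ("CD1", "CG", "CB", "CA", ("chi", 2)),
            ("CD2", "CG", "CB", "CA", ("chi", 2)),
            ("CE1", "CD1", "CG", "CB", "abs"),
            ("CE2", "CD2", "CG", "CB", "abs"),
            ("CZ", "CE1", "CD1", "CG", "abs"),
            ("OH", "CZ", "CE1", "CD1", "abs")],
    "TRP": [("CG", "CB", "CA", "N", ("chi", 1)),
            ("CD1", "CG", "CB", "CA", ("chi", 2)),
            ("CD2", "CG", "CB", "CA", ("chi", 2)),
            ("NE1", "CD1", "CG", "CB", "abs"),
            ("CE2", "NE1", "CD1", "CG", "abs"),
            ("CE3", "CD2", "CG", "CD1", "abs"),
            ("CZ2", "CE2", "NE1", "CD1", "abs"),
            ("CZ3", "CE3", "CD2", "CG", "abs"),
            ("CH2", "CZ2", "CE2", "NE1", "abs")],
    "GLY": [],
}

# Ring/cycle bonds not implied by the construction tree.
CLOSURES = {
    "PRO": [("CD", "N")],
    "HIS": [("NE2", "CD2")],
    "PHE": [("CZ", "CE2")],
    "TYR": [("CZ", "CE2")],
    "TRP": [("CE2", "CD2"), ("CH2", "CZ3")],
}


def write_templates() -> None:
    rows = ["res\tatom\ta1\ta2\ta3\tbond\tangle\ttorsion"]
    for res in AA3:
        atoms = info.residue(res)
        coords = {n: c for n, c in zip(atoms.atom_name, atoms.coord)}
        chis = {
            k + 1: dihedral(*(coords[a] for a in quad))
            for k, quad in enumerate(CHI_ATOMS.get(res, []))
        }
        entries = []
        if res != "GLY":
            entries.append(("CB", "CA", "N", "C", "abs"))
        entries += TREE[res]
        for atom, a1, a2, a3, tie in entries:
            b = distance(coords[atom], coords[a1])
            ang = bond_angle(coords[atom], coords[a1], coords[a2])
            tor = dihedral(coords[atom], coords[a1], coords[a2], coords[a3])
            if tie == "abs":
                tspec = f"{tor:.2f}"
            else:
                k = tie[1]
                off = (tor - chis[k] + 180.0) % 360.0 - 180.0
                tspec = f"chi{k}" if abs(off) < 0.005 else f"chi{k}{off:+.2f}"
            rows.append(
                f"{res}\t{atom}\t{a1}\t{a2}\t{a3}\t{b:.3f}\t{ang:.2f}\t{tspec}"
            )
    (DATA / "templates.tsv").write_text("\n".join(rows) + "\n")

    rows = ["res\tatom1\tatom2"]
    for res, pairs in CLOSURES.items():
        for a, b in pairs:
            rows.append(f"{res}\t{a}\t{b}")
    (DATA / "closure_bonds.tsv").write_text("\n".join(rows) + "\n")


# Coarse rotamer set: candidate values per chi position.  sp3-sp3 chis take the
# three staggered values; terminal sp2 chis take a few canonical placements.
SP3 = (-60.0, 180.0, 60.0)
CHI_CHOICES = {
    "SER": [SP3], "CYS": [SP3], "THR": [SP3], "VAL": [SP3],
    "LEU": [SP3, SP3], "ILE": [SP3, SP3],
    "MET": [SP3, SP3, SP3],
    "LYS": [SP3, SP3, (180.0,), (180.0,)],
    "ARG": [SP3, SP3, (180.0,), (180.0,)],
    "ASP": [SP3, (-30.0, 30.0, 90.0)],
    "ASN": [SP3, (-90.0, 0.0, 90.0)],
    "GLU": [SP3, SP3, (-30.0, 30.0, 90.0)],
    "GLN": [SP3, SP3, (-90.0, 0.0, 90.0)],
    "HIS": [SP3, (-90.0, 90.0)],
    "PHE": [SP3, (90.0, 60.0, -60.0)],
    "TYR": [SP3, (90.0, 60.0, -60.0)],
    "TRP": [SP3, (-90.0, 90.0, 120.0)],
}


def write_rotamers() -> None:
    import itertools

    rows = ["res\tindex\tchi1\tchi2\tchi3\tchi4"]
    for res in AA3:
        if res in ("ALA", "GLY"):
            continue
        if res == "PRO":  # ring: single template conformation
            atoms = info.residue(res)
            coords = {n: c for n, c in zip(atoms.atom_name, atoms.coord)}
            chis = [dihedral(*(coords[a] for a in q)) for q in CHI_ATOMS["PRO"]]
            vals = [f"{c:.2f}" for c in chis] + ["", ""]
            rows.append(f"{res}\t0\t" + "\t".join(vals[:4]))
            continue
        choices = CHI_CHOICES[res]
        for i, combo in enumerate(itertools.product(*choices)):
            vals = [f"{c:.2f}" for c in combo] + [""] * (4 - len(combo))
            rows.append(f"{res}\t{i}\t" + "\t".join(vals))
    (DATA / "rotamers.tsv").write_text("\n".join(rows) + "\n")


# ---------------------------------------------------------------------------
# Nonbonded parameters: heavy-atom model with hydrogen charges folded onto the
# parent heavy atom.  LJ well depths / rmin and radii are element-class values.
LJ = {  # element -> (eps kcal/mol, rmin/2 A)
    "C": (0.080, 2.00),
    "N": (0.170, 1.85),
    "O": (0.120, 1.70),
    "S": (0.450, 2.00),
}

BACKBONE_Q = {"N": -0.16, "CA": 0.16, "C": 0.51, "O": -0.51}

# Side-chain base charges (H folded in); residues are corrected to exact formal
# charge at load time (remainder onto CB).
SIDE_Q = {
    "SER": {"OG": -0.23, "CB": 0.23},
    "THR": {"OG1": -0.23, "CB": 0.23, "CG2": 0.0},
    "CYS": {"SG": -0.07, "CB": 0.07},
    "TYR": {"OH": -0.23, "CZ": 0.11, "CE1": 0.06, "CE2": 0.06},
    "ASP": {"CG": 0.62, "OD1": -0.76, "OD2": -0.76, "CB": -0.10},
    "GLU": {"CD": 0.62, "OE1": -0.76, "OE2": -0.76, "CG": -0.10},
    "ASN": {"CG": 0.55, "OD1": -0.55, "ND2": 0.02, "CB": -0.02},
    "GLN": {"CD": 0.55, "OE1": -0.55, "NE2": 0.02, "CG": -0.02},
    "LYS": {"NZ": 0.69, "CE": 0.31},
    "ARG": {"NE": -0.10, "CZ": 0.64, "NH1": 0.23, "NH2": 0.23},
    "HIS": {"ND1": -0.20, "NE2": -0.20, "CE1": 0.25, "CG": 0.05, "CD2": 0.10},
    "TRP": {"NE1": -0.23, "CD1": 0.11, "CE2": 0.12},
    "MET": {"SD": -0.09, "CG": 0.05, "CE": 0.04},
}

FORMAL = {"ASP": -1, "GLU": -1, "LYS": 1, "ARG": 1}


def write_params() -> None:
    rows = ["res\tatom\tcharge\teps\trmin_half\tpb_radius"]
    for res in AA3:
        atoms = info.residue(res)
        heavy = [
            n for n, e in zip(atoms.atom_name, atoms.element)
            if e != "H" and n != "OXT"
        ]
        side = SIDE_Q.get(res, {})
        for name in heavy:
            q = BACKBONE_Q.get(name, side.get(name, 0.0))
            elem = name[0]
            eps, rmh = LJ[elem]
            rows.append(f"{res}\t{name}\t{q:.4f}\t{eps:.3f}\t{rmh:.2f}\t{rmh:.2f}")
    (DATA / "params.tsv").write_text("\n".join(rows) + "\n")


def write_scales() -> None:
    # Kyte-Doolittle hydropathy
    kd = {
        "ALA": 1.8, "ARG": -4.5, "ASN": -3.5, "ASP": -3.5, "CYS": 2.5,
        "GLN": -3.5, "GLU": -3.5, "GLY": -0.4, "HIS": -3.2, "ILE": 4.5,
        "LEU": 3.8, "LYS": -3.9, "MET": 1.9, "PHE": 2.8, "PRO": -1.6,
        "SER": -0.8, "THR": -0.7, "TRP": -0.9, "TYR": -1.3, "VAL": 4.2,
    }
    rows = ["res\tvalue"] + [f"{r}\t{v}" for r, v in sorted(kd.items())]
    (DATA / "hydropathy.tsv").write_text("\n".join(rows) + "\n")

    # Maximal side-chain rotamer counts (3 states per sp3 chi, fewer for
    # terminal sp2/ring chis); provisional values, config-replaceable.
    rot = {
        "ALA": 1, "GLY": 1, "PRO": 2, "SER": 3, "CYS": 3, "THR": 3, "VAL": 3,
        "ASP": 6, "ASN": 6, "HIS": 6, "PHE": 6, "TYR": 6, "TRP": 6,
        "ILE": 9, "LEU": 9, "GLU": 18, "GLN": 18, "MET": 27,
        "LYS": 81, "ARG": 81,
    }
    rows = ["res\tn_rotamers"] + [f"{r}\t{v}" for r, v in sorted(rot.items())]
    (DATA / "rotamer_counts.tsv").write_text("\n".join(rows) + "\n")


def write_knowledge_tables() -> None:
    # Per-residue probabilities of causing a large (|ddG| >= 1 kcal/mol) effect,
    # as wild-type (X->any) and mutant-type (any->Y), raw P and altered P'.
    wt_mt = """aa	wt_cases	p_wt	pprime_wt	mt_cases	p_mt	pprime_mt
A	91	0.60	0.56	374	0.54	0.53
C	7	0.69	0.55	36	0.44	0.51
D	52	0.48	0.50	34	0.58	0.63
E	93	0.44	0.48	43	0.62	0.64
F	52	0.72	0.69	85	0.45	0.41
G	79	0.52	0.57	167	0.68	0.69
H	41	0.36	0.37	10	0.78	0.79
I	103	0.66	0.63	65	0.40	0.32
K	114	0.22	0.20	32	0.47	0.45
L	92	0.83	0.80	69	0.33	0.25
M	23	0.58	0.59	15	0.43	0.45
N	40	0.62	0.60	19	0.65	0.67
P	42	0.35	0.36	16	0.40	0.36
Q	25	0.25	0.30	41	0.26	0.30
R	37	0.51	0.49	20	0.62	0.53
S	40	0.30	0.21	55	0.60	0.53
T	86	0.50	0.46	39	0.74	0.70
V	141	0.61	0.59	107	0.58	0.52
W	23	0.81	0.86	17	0.44	0.45
Y	81	0.67	0.66	18	0.58	0.65
"""
    (DATA / "prob_wt_mt.tsv").write_text(wt_mt)

    loc_sse = """kind	code	cases	p	pprime
loc	B-B	102	0.74	0.70
loc	B-PE	132	0.78	0.76
loc	E-E	457	0.31	0.29
loc	E-PE	130	0.56	0.55
loc	PE-PE	441	0.65	0.65
sse	BB	14	0.26	0.27
sse	CC	182	0.47	0.45
sse	CH	6	0.81	0.65
sse	CS	8	0.59	0.61
sse	CT	6	0.15	0.16
sse	HH	378	0.55	0.53
sse	HS	1	0.50	0.50
sse	HT	2	0.50	0.50
sse	SS	455	0.63	0.61
sse	ST	2	0.50	0.50
sse	TT	208	0.39	0.38
"""
    (DATA / "prob_loc_sse.tsv").write_text(loc_sse)


def write_weights() -> None:
    # Published weight sets of the two-regime and pooled ("all") linear models.
    # NA = term not part of that regime's published fit.
    w = """term	small	small_p	large	large_p	all	all_p
intercept	-7.44e-1	0.0	-2.27e0	0.0	-1.58e0	0.0
d_ie	9.28e-2	1.36e-2	NA	NA	NA	NA
dd_ee	5.93e-1	3.37e-7	8.54e-1	0.0	8.93e-1	0.0
dd_ve	7.51e-2	2.03e-4	1.63e-1	0.0	1.69e-1	0.0
dd_sp	4.53e-1	5.14e-8	6.32e-1	0.0	6.68e-1	0.0
d_s	NA	NA	4.07e-1	4.18e-2	4.85e-1	1.03e-3
d_hydr	NA	NA	NA	NA	-1.57e0	9.63e-3
d_ssum	-1.26e-1	1.99e-5	-6.55e-1	4.05e-4	-6.67e-1	2.24e-6
sas_mt	NA	NA	9.36e-5	1.10e-4	-5.46e1	2.88e-3
snsas_mt	NA	NA	-7.71e-1	6.84e-3	-2.78e1	4.77e-2
"""
    (DATA / "weights.tsv").write_text(w)


if __name__ == "__main__":
    write_templates()
    write_rotamers()
    write_params()
    write_scales()
    write_knowledge_tables()
    write_weights()
    print("wrote data tables to", DATA)
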