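"""Regenerate the reference maximal-SASA table (data/ref_sasa.tsv).

The reference for residue type X is the central-residue SASA of an extended
Gly-X-Gly tripeptide, computed with the package's own Shrake-Rupley algorithm
so that rSASA normalization is self-consistent with it.
"""

from __future__ import annotations

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from mutddg.descriptors import residue_sasa  # noqa: E402
from mutddg.residues import AA3_TO_1 # noqa: E402
from mutddg.synth import make_peptide  # noqa: E402

DATA = Path(__file__).resolve().parents[1] / "src" / "mutddg" / "data"

rows = ["res\tmax_sasa"]
for aa3, aa1 in sorted(AA3_TO_1.items()):
    pep = make_peptide(f"G{aa1}G", "extended")
    per_res = residue_sasa(pep)
    rows.append(f"{aa3}\t{per_res[('A', 2, '')]:.3f}")
(DATA / "ref_sasa.tsv").write_text("\n".join(rows) + "\n")
print("wrote", DATA / "ref_sasa.tsv")
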