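"""Mutant building: side-chain substitution, segments, clash relaxation."""

import logging

import numpy as np
import pytest

from mutddg.forcefield import build_topology, default_parameters
from mutddg.geometry import bond_angle, distance
from mutddg.mutate import (
    MutationSpec,
    _relax_energy_grad,
    build_mutant,
    build_quartet,
    extract_segment,
    rebuild_wildtype,
    relax_clashes,
    score_rotamers,
)
from mutddg.structure import Atom, ProteinStructure, ResidueID
from mutddg.synth import make_peptide


def names_at(structure, seq):
    return [a.name for a in structure.atoms if a.res.seq == seq]


def test_ala_to_gly_deletes_side_chain():
    pep = make_peptide("GAAAG", "helix")
    mt = build_mutant(pep, MutationSpec("A", 3, "A", "G"))
    assert names_at(mt, 3) == ["N", "CA", "C", "O"]


def test_gly_to_ala_builds_tetrahedral_cb():
    pep = make_peptide("AAGAA", "helix")
    mt = build_mutant(pep, MutationSpec("A", 3, "G", "A"))
    atoms = {a.name: a.xyz for a in mt.atoms if a.res.seq == 3}
    assert "CB" in atoms
    assert distance(atoms["CB"], atoms["CA"]) == pytest.approx(1.52, abs=0.02)
    # tetrahedral geometry around CA
    assert bond_angle(atoms["N"], atoms["CA"], atoms["CB"]) == pytest.approx(109.5, abs=3.0)
    assert bond_angle(atoms["C"], atoms["CA"], atoms["CB"]) == pytest.approx(110.5, abs=3.0)


def test_rotamer_choice_matches_exhaustive_enumeration():
    """Brute-force oracle: the placed rotamer is the argmin of the full
    clash-score enumeration (ties -> lowest index)."""
    pep = make_peptide("AVLVAVLVA", "helix")
    mut = MutationSpec("A", 5, "A", "W")
    scores = score_rotamers(pep, mut)
    best = int(np.argmin(scores))
    mt = build_mutant(pep, mut)
    # rebuild at the oracle's rotamer and compare coordinates
    from mutddg.residues import build_sidechain, load_rotamers

    site = {a.name: a.xyz for a in pep.atoms if a.res.seq == 5}
    expect = build_sidechain("TRP", site, load_rotamers()["TRP"][best])
    got = {a.name: a.xyz for a in mt.atoms if a.res.seq == 5}
    for name, xyz in expect.items():
        assert np.allclose(got[name], xyz)


def test_wt_mismatch_reports_actual_residue():
    pep = make_peptide("AAGAA", "helix")
    with pytest.raises(ValueError, match="GLY"):
        build_mutant(pep, MutationSpec("A", 3, "A", "V"))


def test_site_not_found():
    pep = make_peptide("AAA", "helix")
    with pytest.raises(KeyError):
        build_mutant(pep, MutationSpec("A", 99, "A", "G"))


def test_rebuild_wildtype_idempotent_and_backbone_preserved():
    pep = make_peptide("AAVAA", "helix")
    mut = MutationSpec("A", 3, "V", "L")
    wt1 = rebuild_wildtype(pep, mut)
    wt2 = rebuild_wildtype(wt1, mut)
    assert np.allclose(wt1.coords(), wt2.coords())
    for name in ("N", "CA", "C", "O"):
        a0 = [a for a in pep.atoms if a.res.seq == 3 and a.name == name][0]
        a1 = [a for a in wt1.atoms if a.res.seq == 3 and a.name == name][0]
        assert np.allclose(a0.xyz, a1.xyz)


def test_mutation_touches_only_site():
    pep = make_peptide("AAVAA", "helix")
    mut = MutationSpec("A", 3, "V", "F")
    wt = rebuild_wildtype(pep, mut)
    mt = build_mutant(pep, mut)
    wt_other = [(a.name, tuple(a.xyz)) for a in wt.atoms if a.res.seq != 3]
    mt_other = [(a.name, tuple(a.xyz)) for a in mt.atoms if a.res.seq != 3]
    assert wt_other == mt_other


def test_reverse_mutation_restores_atom_names():
    pep = make_peptide("AAVAA", "helix")
    fwd = build_mutant(pep, MutationSpec("A", 3, "V", "W"))
    back = build_mutant(fwd, MutationSpec("A", 3, "W", "V"))
    assert names_at(back, 3) == names_at(pep, 3)


def test_extract_segment_center_and_copy_semantics():
    pep = make_peptide("AAVAA", "helix")
    seg = extract_segment(pep, "A", 3)
    assert [r.seq for r, _ in seg.residues()] == [2, 3, 4]
    parent = {(a.res.seq, a.name): a.xyz for a in pep.atoms}
    for a in seg.atoms:
        assert np.array_equal(a.xyz, parent[(a.res.seq, a.name)])


def test_extract_segment_terminus_degrades(caplog):
    pep = make_peptide("AAVAA", "helix")
    with caplog.at_level(logging.WARNING):
        seg = extract_segment(pep, "A", 1)
    assert [r.seq for r, _ in seg.residues()] == [1, 2]
    assert any("terminus" in r.message for r in caplog.records)


def test_segment_energy_is_local():
    """Bonded energy of an extracted segment does not depend on the rest of
    the protein (unfolded-state locality assumption)."""
    from mutddg.forcefield import internal_energy

    pep = make_peptide("AAVAAAG", "helix")
    seg = extract_segment(pep, "A", 3)
    lone = ProteinStructure([a.copy() for a in seg.atoms])
    assert internal_energy(seg).internal == pytest.approx(
        internal_energy(lone).internal, abs=1e-12
    )


def test_relax_separates_clashing_atoms():
    rid1 = ResidueID("A", 1, "", "GLY")
    rid2 = ResidueID("A", 5, "", "GLY")
    s = ProteinStructure(
        [
            Atom("CA", "C", rid1, np.array([0.0, 0.0, 0.0])),
            Atom("CA", "C", rid2, np.array([1.0, 0.0, 0.0])),
        ]
    )
    params = default_parameters()
    top = build_topology(s, params)
    e0, _ = _relax_energy_grad(s.coords(), top)
    relaxed = relax_clashes(s, 500)
    e1, _ = _relax_energy_grad(relaxed.coords(), top)
    d = distance(relaxed.atoms[0].xyz, relaxed.atoms[1].xyz)
    assert d > 2.0
    assert e1 < e0


def test_relax_near_fixed_point():
    """A structure already at its energy minimum barely moves in 100 more
    steps."""
    pep = make_peptide("AAAAA", "helix")
    params = default_parameters()
    top = build_topology(pep, params)
    minimal = relax_clashes(pep, 500)
    e0, _ = _relax_energy_grad(minimal.coords(), top)
    again = relax_clashes(minimal, 100)
    e1, _ = _relax_energy_grad(again.coords(), top)
    assert 0.0 <= e0 - e1 < 0.5


def test_relax_zero_steps_is_identity(helix12):
    out = relax_clashes(helix12, 0)
    assert np.array_equal(out.coords(), helix12.coords())


def test_quartet_invariants():
    pep = make_peptide("AAVAA", "helix")
    q = build_quartet(pep, MutationSpec("A", 3, "V", "L"))
    assert [r.seq for r, _ in q.wt_segment.residues()] == [2, 3, 4]
    # segment backbone equals parent coordinates exactly
    parent = {(a.res.seq, a.name): a.xyz for a in q.mt.atoms}
    for a in q.mt_segment.atoms:
        assert np.array_equal(a.xyz, parent[(a.res.seq, a.name)])
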