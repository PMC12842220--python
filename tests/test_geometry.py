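"""Dihedrals, symmetry-corrected RMSD, pockets and contacts."""

from itertools import product

import numpy as np
import pytest
from Bio.PDB.vectors import Vector, calc_dihedral
from scipy.spatial.transform import Rotation

from peprank.geometry import (
    backbone_rmsd,
    compute_phi_psi,
    count_contacts,
    dihedral,
    extract_pocket,
    heavy_atom_rmsd,
)
from peprank.structio import Atom, MolecularStructure, Pose
from peprank.synthetic import build_peptide, perturb_pose, sample_dihedrals


def _atom(name, element, resname, resseq, chain, xyz, serial):
    return Atom(serial, name, element, resname, resseq, chain,
                np.asarray(xyz, float))


class TestDihedrals:
    def test_four_point_formula_matches_biopython(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            pts = rng.normal(size=(4, 3)) * 3
            ours = dihedral(*pts)
            ref = np.degrees(calc_dihedral(*[Vector(*p) for p in pts]))
            assert ours == pytest.approx(ref, abs=1e-9)

    def test_builder_angles_recovered(self):
        pep = build_peptide("AAAAA", [(-60, -45)] * 5)
        angles = compute_phi_psi(pep)
        for i, phi, psi in angles.residues[1:-1]:
            assert phi == pytest.approx(-60, abs=1e-6)
            assert psi == pytest.approx(-45, abs=1e-6)

    def test_termini_are_undefined(self):
        pep = build_peptide("AGA", [(-60, -45)] * 3)
        angles = compute_phi_psi(pep)
        assert angles.residues[0][1] is None
        assert angles.residues[-1][2] is None
        assert len(angles.defined()) == 1

    def test_random_conformation_matches_oracle(self):
        rng = np.random.default_rng(8)
        dh = sample_dihedrals(6, rng)
        pep = build_peptide("AGAGAG", dh)
        named = {}
        for key, _, atoms in pep.residues():
            named[key[1]] = {a.name: a.coords for a in atoms}
        angles = compute_phi_psi(pep)
        for i, phi, psi in angles.residues:
            seq = i + 1
            if phi is not None:
                expected = np.degrees(calc_dihedral(
                    Vector(*named[seq - 1]["C"]), Vector(*named[seq]["N"]),
                    Vector(*named[seq]["CA"]), Vector(*named[seq]["C"])))
                assert phi == pytest.approx(expected, abs=1e-9)
            if psi is not None:
                expected = np.degrees(calc_dihedral(
                    Vector(*named[seq]["N"]), Vector(*named[seq]["CA"]),
                    Vector(*named[seq]["C"]), Vector(*named[seq + 1]["N"])))
                assert psi == pytest.approx(expected, abs=1e-9)

    def test_missing_backbone_atom_names_residue(self):
        pep = build_peptide("AGA", [(-60, -45)] * 3)
        pruned = MolecularStructure(
            [a for a in pep.atoms if not (a.residue_seq == 2 and a.name == "CA")]
        )
        with pytest.raises(ValueError, match="2"):
            compute_phi_psi(pruned)

    def test_invariant_under_rigid_motion(self):
        rng = np.random.default_rng(5)
        pep = build_peptide("AGAGA", sample_dihedrals(5, rng))
        rot = Rotation.random(random_state=2).as_matrix()
        moved = pep.transformed(rot, np.array([1.0, -7.0, 3.0]))
        a = compute_phi_psi(pep)
        b = compute_phi_psi(moved)
        for (_, p1, s1), (_, p2, s2) in zip(a.residues, b.residues):
            if p1 is not None:
                assert p1 == pytest.approx(p2, abs=1e-8)
            if s1 is not None:
                assert s1 == pytest.approx(s2, abs=1e-8)


def _glu_structure(shift=0.0, swap=False):
    """Minimal Ala-Glu-Ala-like chain with a symmetric carboxylate."""
    rng = np.random.default_rng(1)
    base = build_peptide("AAA", [(-60, -45)] * 3)
    atoms = list(base.atoms)
    serial = max(a.serial for a in atoms)
    # graft OE1/OE2 onto residue 2 (rename it GLU with CG/CD too)
    ca2 = next(a.coords for a in atoms if a.residue_seq == 2 and a.name == "CA")
    extra_names = ["CG", "CD", "OE1", "OE2"]
    offsets = [np.array([1.0, 1.0, 0.0]), np.array([2.0, 1.5, 0.0]),
               np.array([3.0, 1.0, 0.3]), np.array([2.2, 2.6, -0.2])]
    if swap:
        offsets[2], offsets[3] = offsets[3], offsets[2]
    new_atoms = []
    for a in atoms:
        name, resname = a.name, a.residue_name
        if a.residue_seq == 2:
            resname = "GLU"
        new_atoms.append(Atom(a.serial, name, a.element, resname, a.residue_seq,
                              a.chain_id, a.coords + shift))
    for name, off in zip(extra_names, offsets):
        serial += 1
        element = "O" if name.startswith("O") else "C"
        new_atoms.insert(
            [i for i, a in enumerate(new_atoms) if a.residue_seq == 2][-1] + 1,
            Atom(serial, name, element, "GLU", 2, "P", ca2 + off + shift),
        )
    return MolecularStructure(new_atoms)


class TestHeavyAtomRmsd:
    def test_identity_and_translation(self):
        pep = build_peptide("AGAGA", [(-60, -45)] * 5)
        assert heavy_atom_rmsd(pep, pep) == 0.0
        moved = pep.transformed(np.eye(3), np.array([3.0, 0.0, 4.0]))
        assert heavy_atom_rmsd(pep, moved) == pytest.approx(5.0, abs=1e-9)

    def test_carboxylate_swap_matches_brute_force(self):
        ref = _glu_structure()
        cand = _glu_structure(shift=0.3, swap=True)
        got = heavy_atom_rmsd(ref, cand)
        # brute force: enumerate OE1/OE2 swap and O/OXT swap explicitly
        ref_map = {(a.residue_seq, a.name): a.coords for a in ref.atoms}
        cand_map = {(a.residue_seq, a.name): a.coords for a in cand.atoms}
        keys = list(ref_map)
        swap_groups = [((2, "OE1"), (2, "OE2")), ((3, "O"), (3, "OXT"))]
        best = np.inf
        for bits in product([False, True], repeat=len(swap_groups)):
            mapping = {k: k for k in keys}
            for on, (ka, kb) in zip(bits, swap_groups):
                if on:
                    mapping[ka], mapping[kb] = kb, ka
            sq = [np.sum((ref_map[k] - cand_map[mapping[k]]) ** 2) for k in keys]
            best = min(best, np.sqrt(np.mean(sq)))
        assert got == pytest.approx(best, abs=1e-12)
        # the swapped candidate must beat the identity mapping
        identity = np.sqrt(np.mean(
            [np.sum((ref_map[k] - cand_map[k]) ** 2) for k in keys]
        ))
        assert got <= identity + 1e-12

    def test_cterm_oxt_swap_is_free(self):
        ref = build_peptide("AGA", [(-60, -45)] * 3)
        atoms = []
        last = max(a.residue_seq for a in ref.atoms)
        coords = {(a.residue_seq, a.name): a.coords for a in ref.atoms}
        for a in ref.atoms:
            xyz = a.coords
            if a.residue_seq == last and a.name == "O":
                xyz = coords[(last, "OXT")]
            elif a.residue_seq == last and a.name == "OXT":
                xyz = coords[(last, "O")]
            atoms.append(Atom(a.serial, a.name, a.element, a.residue_name,
                              a.residue_seq, a.chain_id, xyz))
        cand = MolecularStructure(atoms)
        assert heavy_atom_rmsd(ref, cand) == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_in_arguments(self):
        pep = build_peptide("AGAGA", [(-60, -45)] * 5)
        decoy = perturb_pose(Pose(pep, "n"), 3.0, mode="mixed", seed=4).structure
        assert heavy_atom_rmsd(pep, decoy) == pytest.approx(
            heavy_atom_rmsd(decoy, pep), abs=1e-9
        )

    def test_superposed_never_exceeds_fixed_frame(self):
        rng = np.random.default_rng(9)
        pep = build_peptide("AGAGAG", sample_dihedrals(6, rng))
        for target in (1.0, 4.0, 9.0):
            decoy = perturb_pose(Pose(pep, "n"), target, mode="mixed",
                                 seed=int(target)).structure
            fixed = heavy_atom_rmsd(pep, decoy, superpose=False)
            aligned = heavy_atom_rmsd(pep, decoy, superpose=True)
            assert aligned <= fixed + 1e-9

    def test_rmsd_scales_linearly_on_interpolation(self):
        pep = build_peptide("AGAGA", [(-60, -45)] * 5)
        decoy = perturb_pose(Pose(pep, "n"), 6.0, mode="rigid", seed=2).structure
        ref_xyz = pep.coords()
        dec_xyz = decoy.coords()
        full = heavy_atom_rmsd(pep, decoy)
        for t in (0.25, 0.5, 0.75):
            interp = MolecularStructure([
                Atom(a.serial, a.name, a.element, a.residue_name, a.residue_seq,
                     a.chain_id, (1 - t) * x + t * y)
                for a, x, y in zip(pep.atoms, ref_xyz, dec_xyz)
            ])
            assert heavy_atom_rmsd(pep, interp) == pytest.approx(t * full, rel=1e-9)

    def test_mismatched_molecules_raise(self):
        a = build_peptide("AGA", [(-60, -45)] * 3)
        b = build_peptide("AGAG", [(-60, -45)] * 4)
        from peprank.geometry import MatchingError

        with pytest.raises(MatchingError):
            heavy_atom_rmsd(a, b)


class TestBackboneRmsd:
    def test_identity_and_sidechain_restriction(self):
        pep = build_peptide("AAAAA", [(-60, -45)] * 5)
        assert backbone_rmsd(pep, pep) == 0.0
        # perturb CB atoms only: backbone unchanged, heavy-atom RMSD > 0
        atoms = [
            Atom(a.serial, a.name, a.element, a.residue_name, a.residue_seq,
                 a.chain_id, a.coords + (0.8 if a.name == "CB" else 0.0))
            for a in pep.atoms
        ]
        cand = MolecularStructure(atoms)
        assert backbone_rmsd(pep, cand) == 0.0
        assert heavy_atom_rmsd(pep, cand) > 0.1

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(12)
        pep = build_peptide("AGAGA", sample_dihedrals(5, rng))
        decoy = perturb_pose(Pose(pep, "n"), 4.0, mode="mixed", seed=6).structure
        got = backbone_rmsd(pep, decoy)
        ref_map = {(a.residue_seq, a.name): a.coords for a in pep.atoms
                   if a.name in ("N", "CA", "C", "O")}
        cand_map = {(a.residue_seq, a.name): a.coords for a in decoy.atoms
                    if a.name in ("N", "CA", "C", "O")}
        sq = [np.sum((ref_map[k] - cand_map[k]) ** 2) for k in ref_map]
        assert got == pytest.approx(np.sqrt(np.mean(sq)), abs=1e-12)

    def test_equals_heavy_atom_rmsd_for_glycine_backbone(self):
        pep = build_peptide("GGGG", [(-70, 150)] * 4)
        stripped = MolecularStructure([a for a in pep.atoms if a.name != "OXT"])
        decoy = stripped.transformed(
            Rotation.random(random_state=3).as_matrix(), np.array([1.0, 2.0, 0.5])
        )
        assert backbone_rmsd(stripped, decoy) == pytest.approx(
            heavy_atom_rmsd(stripped, decoy), abs=1e-9
        )


class TestPocketAndContacts:
    def _fixture(self, seed=0, n_rec=60):
        rng = np.random.default_rng(seed)
        pep = build_peptide("AGAGA", sample_dihedrals(5, rng))
        rec_atoms = []
        names = ("N", "CA", "C")
        for j, xyz in enumerate(rng.uniform(-10, 18, (n_rec, 3))):
            name = names[j % 3]
            rec_atoms.append(_atom(name, name[0], "GLY", j // 3 + 1, "A", xyz,
                                   serial=j + 1))
        return MolecularStructure(rec_atoms), pep

    def test_whole_residue_inclusion(self):
        pep = build_peptide("AGA", [(-60, -45)] * 3)
        anchor = pep.atoms[0].coords
        rec = MolecularStructure([
            _atom("N", "N", "GLY", 1, "A", anchor + [9.9, 0, 0], 1),
            _atom("CA", "C", "GLY", 1, "A", anchor + [30.0, 0, 0], 2),
            _atom("N", "N", "GLY", 2, "A", anchor + [40.0, 0, 0], 3),
        ])
        pocket = extract_pocket(rec, pep, radius=10.0)
        assert {a.name for a in pocket.atoms} == {"N", "CA"}
        assert all(a.residue_seq == 1 for a in pocket.atoms)

    def test_empty_pocket(self):
        pep = build_peptide("AGA", [(-60, -45)] * 3)
        far = MolecularStructure(
            [_atom("CA", "C", "GLY", 1, "A", pep.atoms[0].coords + 100.0, 1)]
        )
        assert len(extract_pocket(far, pep)) == 0

    def test_pocket_matches_brute_force(self):
        rec, pep = self._fixture(seed=4)
        pocket = extract_pocket(rec, pep, radius=10.0)
        pep_xyz = pep.coords()
        keep = set()
        for a in rec.atoms:
            if np.min(np.linalg.norm(pep_xyz - a.coords, axis=1)) <= 10.0:
                keep.add(a.residue_key)
        expected = {a.residue_key for a in rec.atoms if a.residue_key in keep}
        assert {a.residue_key for a in pocket.atoms} == expected

    def test_contact_count_trivial_and_brute_force(self):
        pep = build_peptide("AGA", [(-60, -45)] * 3)
        far = MolecularStructure(
            [_atom("CA", "C", "GLY", 1, "A", pep.atoms[0].coords + 100.0, 1)]
        )
        assert count_contacts(far, pep) == 0
        near = MolecularStructure([
            _atom("CA", "C", "GLY", 1, "A", pep.atoms[0].coords + [4.4, 0, 0], 1),
            _atom("CB", "C", "GLY", 1, "A", pep.atoms[0].coords + [50.0, 0, 0], 2),
        ])
        # 4.4 A from atom 0; check no other peptide atom is within 4.5
        d = np.linalg.norm(pep.coords() - near.atoms[0].coords, axis=1)
        assert count_contacts(near, pep) == int(np.sum(d < 4.5))

        rec, pep2 = self._fixture(seed=6)
        got = count_contacts(rec, pep2, cutoff=4.5)
        rec_xyz = rec.coords(heavy_only=True)
        pep_xyz = pep2.coords(heavy_only=True)
        expected = sum(
            1 for r in rec_xyz for p in pep_xyz if np.linalg.norm(r - p) < 4.5
        )
        assert got == expected
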