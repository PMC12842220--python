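"""Dihedral angles, symmetry-corrected RMSD, pockets and contacts.

RMSD between a pose and the native conformation is, by default, computed
in the shared receptor frame (no superposition): docking poses live in
the receptor's coordinate system and aligning them first would reward
wrongly placed poses.  A ``superpose`` flag exposes the aligned variant.

The heavy-atom RMSD is minimized over chemically equivalent atom
permutations: carboxylate oxygens of Asp/Glu and the C-terminus,
Phe/Tyr ring flips, and the Arg guanidinium nitrogens.  These groups are
independent across residues, so the exact minimum is a per-residue
choice when no superposition is involved.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .structio import MolecularStructure, Pose

__all__ = [
    "DihedralSet",
    "MatchingError",
    "compute_phi_psi",
    "dihedral",
    "heavy_atom_rmsd",
    "backbone_rmsd",
    "extract_pocket",
    "count_contacts",
]

BACKBONE_ATOMS = ("N", "CA", "C", "O")

#: per-residue-type equivalent-atom swaps; each entry is one permutation
#: option (applied as a whole, e.g. a full aromatic ring flip)
SYMMETRY_SWAPS: dict[str, tuple[tuple[str, str], ...]] = {
    "ASP": (("OD1", "OD2"),),
    "GLU": (("OE1", "OE2"),),
    "PHE": (("CD1", "CD2"), ("CE1", "CE2")),
    "TYR": (("CD1", "CD2"), ("CE1", "CE2")),
    "ARG": (("NH1", "NH2"),),
}
CTERM_SWAP: tuple[tuple[str, str], ...] = (("O", "OXT"),)


class MatchingError(ValueError):
    """Raised when two poses cannot be mapped atom-by-atom."""


@dataclass
class DihedralSet:
    """Backbone phi/psi angles in degrees; ``None`` marks undefined termini."""

    residues: list[tuple[int, float | None, float | None]]

    def defined(self) -> list[tuple[float, float]]:
        """(phi, psi) pairs for residues where both angles exist."""
        return [(phi, psi) for _, phi, psi in self.residues
                if phi is not None and psi is not None]


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral angle in degrees, IUPAC sign convention."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def compute_phi_psi(peptide: MolecularStructure) -> DihedralSet:
    """Backbone phi/psi per residue; first phi and last psi are undefined."""
    backbone: list[dict[str, np.ndarray]] = []
    for key, resname, atoms in peptide.residues():
        named = {a.name: a.coords for a in atoms}
        for req in ("N", "CA", "C"):
            if req not in named:
                raise ValueError(
                    f"residue {resname} {key[0]}{key[1]}: missing backbone atom {req}"
                )
        backbone.append(named)

    out: list[tuple[int, float | None, float | None]] = []
    n = len(backbone)
    for i, named in enumerate(backbone):
        phi = psi = None
        if i > 0:
            phi = dihedral(backbone[i - 1]["C"], named["N"], named["CA"], named["C"])
        if i < n - 1:
            psi = dihedral(named["N"], named["CA"], named["C"], backbone[i + 1]["N"])
        out.append((i, phi, psi))
    return DihedralSet(out)


def _as_structure(obj: Pose | MolecularStructure) -> MolecularStructure:
    return obj.structure if isinstance(obj, Pose) else obj


def _match_atoms(
    ref: MolecularStructure, cand: MolecularStructure, names: tuple[str, ...] | None
) -> tuple[list[tuple[int, int]], dict[tuple, dict[str, int]], dict[tuple, dict[str, int]]]:
    """Identity mapping over (residue, atom-name), heavy atoms only."""
    def index(st: MolecularStructure):
        idx: dict[tuple, dict[str, int]] = {}
        resnames: dict[tuple, str] = {}
        for i, a in enumerate(st.atoms):
            if not a.is_heavy:
                continue
            if names is not None and a.name not in names:
                continue
            idx.setdefault(a.residue_key, {})[a.name] = i
            resnames[a.residue_key] = a.residue_name
        return idx, resnames

    ref_idx, ref_names = index(ref)
    cand_idx, cand_names = index(cand)
    ref_keys = list(ref_idx)
    cand_keys = list(cand_idx)
    if len(ref_keys) != len(cand_keys):
        raise MatchingError(
            f"residue counts differ: {len(ref_keys)} vs {len(cand_keys)}"
        )
    pairs: list[tuple[int, int]] = []
    for rk, ck in zip(ref_keys, cand_keys):
        if ref_names[rk] != cand_names[ck]:
            raise MatchingError(
                f"residue mismatch at {rk}: {ref_names[rk]} vs {cand_names[ck]}"
            )
        ra, ca = ref_idx[rk], cand_idx[ck]
        if set(ra) != set(ca):
            raise MatchingError(
                f"atom sets differ in residue {rk}: "
                f"{sorted(set(ra) ^ set(ca))}"
            )
        for name in ra:
            pairs.append((ra[name], ca[name]))
    return pairs, ref_idx, cand_idx


def _rmsd_from_coords(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def _superposed_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    rot, _ = Rotation.align_vectors(ac, bc)
    return _rmsd_from_coords(ac, rot.apply(bc))


def heavy_atom_rmsd(
    reference: Pose | MolecularStructure,
    candidate: Pose | MolecularStructure,
    superpose: bool = False,
) -> float:
    """Heavy-atom RMSD minimized over equivalent-atom permutations.

    ``superpose=False`` (default) evaluates in the fixed receptor frame;
    ``superpose=True`` applies an optimal rigid alignment first.
    """
    ref = _as_structure(reference)
    cand = _as_structure(candidate)
    pairs, ref_idx, cand_idx = _match_atoms(ref, cand, names=None)

    ref_xyz = ref.coords()
    cand_xyz = cand.coords()
    base = np.array([[ri, ci] for ri, ci in pairs])

    # per-residue swap options in the candidate
    residues = ref.residues()
    cand_keys = list(cand_idx)
    last_ck = cand_keys[-1] if cand_keys else None
    residue_swaps: list[tuple[tuple, list[tuple[str, str]]]] = []
    for (key, resname, _), ck in zip(residues, cand_keys):
        swaps = [
            (a, b)
            for a, b in SYMMETRY_SWAPS.get(resname, ())
            if a in cand_idx[ck] and b in cand_idx[ck]
        ]
        if ck == last_ck:
            swaps += [
                (a, b) for a, b in CTERM_SWAP
                if a in cand_idx[ck] and b in cand_idx[ck]
            ]
        if swaps:
            residue_swaps.append((ck, swaps))

    def apply_swaps(mapping: dict[int, int], choices: dict[tuple, bool]) -> dict[int, int]:
        m = dict(mapping)
        for ck, on in choices.items():
            if not on:
                continue
            swaps = dict(residue_swaps)[ck]
            for a, b in swaps:
                ia, ib = cand_idx[ck][a], cand_idx[ck][b]
                ref_a = [ri for ri, ci in m.items() if ci == ia]
                ref_b = [ri for ri, ci in m.items() if ci == ib]
                if ref_a and ref_b:
                    m[ref_a[0]], m[ref_b[0]] = ib, ia
        return m

    mapping = {ri: ci for ri, ci in pairs}

    if not residue_swaps:
        a = ref_xyz[base[:, 0]]
        b = cand_xyz[base[:, 1]]
        return _superposed_rmsd(a, b) if superpose else _rmsd_from_coords(a, b)

    if not superpose:
        # exact: each residue's choice is independent of the others
        best = dict(mapping)
        for ck, swaps in residue_swaps:
            m0 = apply_swaps(best, {ck: False})
            m1 = apply_swaps(best, {ck: True})

            def ssd(m: dict[int, int]) -> float:
                idx = [(ri, ci) for ri, ci in m.items() if ci in cand_idx[ck].values()]
                a = ref_xyz[[ri for ri, _ in idx]]
                b = cand_xyz[[ci for _, ci in idx]]
                return float(np.sum((a - b) ** 2))

            best = m1 if ssd(m1) < ssd(m0) else m0
        ri = np.array(list(best))
        ci = np.array([best[r] for r in best])
        return _rmsd_from_coords(ref_xyz[ri], cand_xyz[ci])

    # superposed: enumerate the full product (peptides are short)
    best_val = np.inf
    n_opts = len(residue_swaps)
    if 2 ** n_opts > 4096:
        raise MatchingError("too many symmetry combinations to enumerate")
    for bits in product((False, True), repeat=n_opts):
        choices = {ck: on for (ck, _), on in zip(residue_swaps, bits)}
        m = apply_swaps(mapping, choices)
        ri = np.array(list(m))
        ci = np.array([m[r] for r in m])
        val = _superposed_rmsd(ref_xyz[ri], cand_xyz[ci])
        best_val = min(best_val, val)
    return best_val


def backbone_rmsd(
    reference: Pose | MolecularStructure,
    candidate: Pose | MolecularStructure,
    superpose: bool = False,
) -> float:
    """RMSD over the backbone atoms N, CA, C, O (no permutations needed)."""
    ref = _as_structure(reference)
    cand = _as_structure(candidate)
    pairs, _, _ = _match_atoms(ref, cand, names=BACKBONE_ATOMS)
    if not pairs:
        raise MatchingError("no backbone atoms in common")
    a = ref.coords()[[ri for ri, _ in pairs]]
    b = cand.coords()[[ci for _, ci in pairs]]
    return _superposed_rmsd(a, b) if superpose else _rmsd_from_coords(a, b)


def extract_pocket(
    receptor: MolecularStructure,
    peptide: MolecularStructure | Pose,
    radius: float = 10.0,
) -> MolecularStructure:
    """Receptor residues with any atom within ``radius`` of any peptide atom.

    Whole residues are returned, never partial ones; an empty selection
    yields an empty structure.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    pep = _as_structure(peptide)
    if len(pep) == 0 or len(receptor) == 0:
        return MolecularStructure([], source_id=receptor.source_id)
    tree = cKDTree(pep.coords())
    keep: set[tuple] = set()
    for atom in receptor.atoms:
        dist, _ = tree.query(atom.coords)
        if dist <= radius:
            keep.add(atom.residue_key)
    atoms = [a for a in receptor.atoms if a.residue_key in keep]
    return MolecularStructure(atoms, source_id=receptor.source_id)


def count_contacts(
    receptor: MolecularStructure,
    pose: Pose | MolecularStructure,
    cutoff: float = 4.5,
) -> int:
    """Number of receptor/peptide heavy-atom pairs at distance < ``cutoff``."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    pep = _as_structure(pose)
    rec_xyz = receptor.coords(heavy_only=True)
    pep_xyz = pep.coords(heavy_only=True)
    if len(rec_xyz) == 0 or len(pep_xyz) == 0:
        return 0
    d = np.linalg.norm(rec_xyz[None, :, :] - pep_xyz[:, None, :], axis=2)
    return int(np.sum(d < cutoff))
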