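"""Structure containers, PDB I/O and complex curation.

Receptors and peptide poses travel through the pipeline as
:class:`MolecularStructure` objects: flat, ordered atom lists with
chain/residue identity, coordinates in Angstrom and optional partial
charges.  Reading goes through gemmi (first model only, highest-occupancy
altloc); writing uses a fixed-column serializer so that write/read round
trips are byte-stable.

Curation applies the dataset-quality filters used to assemble the
training corpus: no small molecule or metal within 7 A of the peptide,
no missing peptide residues or heavy atoms, and a receptor of at least
500 atoms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np
from scipy.spatial import cKDTree

from .residues import (
    HEAVY_ATOM_TEMPLATE,
    METAL_ELEMENTS,
    STANDARD_RESIDUES,
    WATER_NAMES,
)

__all__ = [
    "Atom",
    "MolecularStructure",
    "Pose",
    "ComplexRecord",
    "CurationConfig",
    "CurationVerdict",
    "PdbParseError",
    "read_structure",
    "write_structure",
    "find_interacting_chains",
    "curate_complex",
]


class PdbParseError(ValueError):
    """Raised when a PDB file cannot be parsed into a structure."""


@dataclass(frozen=True)
class Atom:
    """One atom record.

    ``residue_seq`` carries the author residue number; ``icode`` the
    insertion code ('' when absent).  ``partial_charge`` is in units of
    the elementary charge and optional.
    """

    serial: int
    name: str
    element: str
    residue_name: str
    residue_seq: int
    chain_id: str
    coords: np.ndarray
    icode: str = ""
    partial_charge: float | None = None
    is_hetero: bool = False

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.shape != (3,) or not np.all(np.isfinite(coords)):
            raise ValueError(f"atom {self.name}: coords must be a finite 3-vector")
        object.__setattr__(self, "coords", coords)
        if not self.element:
            raise ValueError(f"atom {self.name}: empty element symbol")

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() not in ("H", "D")

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_seq, self.icode)


class MolecularStructure:
    """Ordered atom collection with chain/residue indexing."""

    def __init__(self, atoms: list[Atom], source_id: str = "") -> None:
        self.atoms = list(atoms)
        self.source_id = source_id
        seen: set[tuple] = set()
        for atom in self.atoms:
            key = (*atom.residue_key, atom.name)
            if key in seen:
                raise ValueError(f"duplicate atom {key} in structure {source_id!r}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def chain_ids(self) -> list[str]:
        out: list[str] = []
        for atom in self.atoms:
            if atom.chain_id not in out:
                out.append(atom.chain_id)
        return out

    def chain(self, chain_id: str) -> "MolecularStructure":
        atoms = [a for a in self.atoms if a.chain_id == chain_id]
        if not atoms:
            raise KeyError(f"chain {chain_id!r} not present")
        return MolecularStructure(atoms, source_id=self.source_id)

    def residues(self) -> list[tuple[tuple[str, int, str], str, list[Atom]]]:
        """Residues in file order as ``(key, residue_name, atoms)`` triples."""
        order: list[tuple[str, int, str]] = []
        groups: dict[tuple[str, int, str], list[Atom]] = {}
        for atom in self.atoms:
            key = atom.residue_key
            if key not in groups:
                groups[key] = []
                order.append(key)
            groups[key].append(atom)
        return [(key, groups[key][0].residue_name, groups[key]) for key in order]

    def coords(self, heavy_only: bool = False) -> np.ndarray:
        atoms = self.heavy_atoms() if heavy_only else self.atoms
        if not atoms:
            return np.empty((0, 3))
        return np.vstack([a.coords for a in atoms])

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.is_heavy]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "MolecularStructure":
        """Return a copy moved rigidly: ``x -> R x + t``."""
        rotation = np.asarray(rotation, float)
        translation = np.asarray(translation, float)
        atoms = [
            replace(a, coords=rotation @ a.coords + translation) for a in self.atoms
        ]
        return MolecularStructure(atoms, source_id=self.source_id)

    def with_charges(self, charges: dict[tuple[str, int, str, str], float]) -> "MolecularStructure":
        """Attach partial charges keyed by ``(chain, resseq, icode, atom name)``."""
        atoms = []
        for a in self.atoms:
            key = (*a.residue_key, a.name)
            q = charges.get(key, a.partial_charge)
            atoms.append(replace(a, partial_charge=q))
        return MolecularStructure(atoms, source_id=self.source_id)


@dataclass
class Pose:
    """One candidate peptide conformation for a complex."""

    structure: MolecularStructure
    pose_id: str
    source: str = ""
    rmsd: float | None = None


@dataclass
class ComplexRecord:
    """A receptor with its single-chain, 3-10 residue peptide ligand."""

    receptor: MolecularStructure
    peptide: MolecularStructure
    complex_id: str

    def __post_init__(self) -> None:
        chains = self.peptide.chain_ids
        if len(chains) != 1:
            raise ValueError(
                f"{self.complex_id}: peptide must be a single chain, got {chains}"
            )
        residues = self.peptide.residues()
        if not 3 <= len(residues) <= 10:
            raise ValueError(
                f"{self.complex_id}: peptide length {len(residues)} outside 3-10"
            )
        for key, resname, _ in residues:
            if resname not in STANDARD_RESIDUES:
                raise ValueError(
                    f"{self.complex_id}: non-standard peptide residue {resname} at {key}"
                )

    @property
    def peptide_length(self) -> int:
        return len(self.peptide.residues())

    @property
    def peptide_sequence(self) -> str:
        from .residues import THREE_TO_ONE

        return "".join(THREE_TO_ONE[name] for _, name, _ in self.peptide.residues())


@dataclass
class CurationConfig:
    """Cutoffs for the dataset-curation filters (Angstrom)."""

    hetero_cutoff: float = 7.0
    interaction_cutoff: float = 5.0
    min_receptor_atoms: int = 500


@dataclass
class CurationVerdict:
    passed: bool
    failed_rules: list[tuple[str, str]] = field(default_factory=list)

    def rule_ids(self) -> set[str]:
        return {rule for rule, _ in self.failed_rules}


# ---------------------------------------------------------------------------
# PDB I/O


def read_structure(path, fmt: str = "pdb", charges_from_bfactor: bool = False) -> MolecularStructure:
    """Parse a PDB file into a :class:`MolecularStructure`.

    Only the first MODEL is read.  Alternate locations are resolved to the
    highest-occupancy conformer (ties go to the first encountered).  Waters
    are retained and flagged hetero.  With ``charges_from_bfactor`` the
    B-factor column is interpreted as a partial charge, the convention the
    synthetic fixtures use to keep charges inside the PDB file.
    """
    path = str(path)
    if fmt != "pdb":
        raise ValueError(f"unsupported format {fmt!r}")
    # validate coordinate fields up front: the parser is lenient about them
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM  ", "HETATM")):
                for lo, hi in ((30, 38), (38, 46), (46, 54)):
                    try:
                        float(line[lo:hi])
                    except ValueError:
                        raise PdbParseError(
                            f"{path}: malformed coordinate field on line {lineno}"
                        ) from None
    try:
        st = gemmi.read_pdb(path)
    except (RuntimeError, ValueError) as exc:
        raise PdbParseError(f"{path}: {exc}") from exc
    if len(st) == 0:
        raise PdbParseError(f"{path}: no ATOM records found")
    model = st[0]

    atoms: list[Atom] = []
    serial = 0
    for chain in model:
        for res in chain:
            # altloc resolution: highest occupancy, tie -> first encountered
            name_order: list[str] = []
            best: dict[str, gemmi.Atom] = {}
            for ga in res:
                prev = best.get(ga.name)
                if prev is None:
                    name_order.append(ga.name)
                    best[ga.name] = ga
                elif ga.occ > prev.occ:
                    best[ga.name] = ga
            is_het = res.het_flag == "H" or res.name in WATER_NAMES
            for name in name_order:
                ga = best[name]
                serial += 1
                atoms.append(
                    Atom(
                        serial=serial,
                        name=ga.name,
                        element=ga.element.name or ga.name[0],
                        residue_name=res.name,
                        residue_seq=res.seqid.num,
                        icode=(res.seqid.icode or "").strip(),
                        chain_id=chain.name,
                        coords=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                        partial_charge=float(ga.b_iso) if charges_from_bfactor else None,
                        is_hetero=is_het,
                    )
                )
    if not atoms:
        raise PdbParseError(f"{path}: no ATOM records found")
    return MolecularStructure(atoms, source_id=st.name or path)


def _format_atom_name(name: str, element: str) -> str:
    # PDB columns 13-16: one/two-letter elements start in column 14/13.
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1 and len(name) <= 3:
        return f" {name:<3s}"
    return f"{name:<4s}"


def write_structure(structure: MolecularStructure, path, charges_in_bfactor: bool = False) -> None:
    """Serialize to fixed-column PDB, coordinates at 3 decimals.

    Serial numbers above 99999 wrap modulo 100000, the usual PDB
    convention for oversized files.
    """
    if len(structure) == 0:
        raise ValueError("refusing to write an empty structure")
    lines: list[str] = []
    prev_chain = None
    for i, atom in enumerate(structure.atoms, start=1):
        if prev_chain is not None and atom.chain_id != prev_chain:
            lines.append("TER")
        prev_chain = atom.chain_id
        record = "HETATM" if atom.is_hetero else "ATOM  "
        bfac = 0.0
        if charges_in_bfactor and atom.partial_charge is not None:
            bfac = atom.partial_charge
        x, y, z = atom.coords
        lines.append(
            f"{record}{i % 100000:5d} {_format_atom_name(atom.name, atom.element)}"
            f"{'':1s}{atom.residue_name:>3s} {atom.chain_id[:1]:1s}"
            f"{atom.residue_seq:4d}{atom.icode[:1] or ' ':1s}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{bfac:6.2f}"
            f"          {atom.element.upper():>2s}"
        )
    lines.append("TER")
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Interaction detection and curation


def find_interacting_chains(
    structure: MolecularStructure, peptide_chain: str, cutoff: float = 5.0
) -> set[str]:
    """Chains with a heavy atom strictly closer than ``cutoff`` to the peptide.

    Implements the receptor-chain selection rule: a chain interacts when at
    least one of its heavy atoms lies at distance < ``cutoff`` (default
    5.0 A) from at least one peptide heavy atom.  Water and other hetero
    records never qualify as interacting chains.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if peptide_chain not in structure.chain_ids:
        raise KeyError(f"unknown chain {peptide_chain!r}")
    pep = [a for a in structure.atoms if a.chain_id == peptide_chain and a.is_heavy]
    if not pep:
        return set()
    tree = cKDTree(np.vstack([a.coords for a in pep]))
    out: set[str] = set()
    for atom in structure.atoms:
        if atom.chain_id == peptide_chain or not atom.is_heavy or atom.is_hetero:
            continue
        if atom.chain_id in out:
            continue
        dist, _ = tree.query(atom.coords)
        if dist < cutoff:
            out.add(atom.chain_id)
    return out


def _residue_gaps(peptide: MolecularStructure) -> list[str]:
    gaps = []
    residues = peptide.residues()
    for (key_a, _, _), (key_b, _, _) in zip(residues, residues[1:]):
        if key_b[1] - key_a[1] > 1:
            gaps.append(f"gap between residues {key_a[1]} and {key_b[1]}")
    return gaps


def curate_complex(
    record: ComplexRecord,
    context: MolecularStructure | None = None,
    rules: CurationConfig | None = None,
) -> CurationVerdict:
    """Apply the five dataset-curation filters, each reported independently.

    Rules: (i) non-water small molecule within ``hetero_cutoff`` of any
    peptide atom; (ii) metal ion within the same cutoff; (iii) peptide
    residue-numbering gap; (iv) peptide residue missing heavy atoms versus
    its standard template; (v) receptor smaller than
    ``min_receptor_atoms``.  Distances for (i)/(ii) are measured to *all*
    peptide atoms, hydrogens included.
    """
    rules = rules or CurationConfig()
    failed: list[tuple[str, str]] = []

    pep_coords = record.peptide.coords()
    tree = cKDTree(pep_coords)

    if context is not None:
        hetero_atoms = [a for a in context.atoms if a.is_hetero]
        flagged_small: set[tuple] = set()
        for atom in hetero_atoms:
            if atom.residue_name in WATER_NAMES:
                continue
            dist, _ = tree.query(atom.coords)
            if dist >= rules.hetero_cutoff:
                continue
            if atom.element.upper() in METAL_ELEMENTS:
                failed.append(
                    ("metal-proximity",
                     f"{atom.element} at {dist:.2f} A (residue {atom.residue_name} "
                     f"{atom.chain_id}{atom.residue_seq})")
                )
            else:
                key = atom.residue_key
                if key not in flagged_small:
                    flagged_small.add(key)
                    failed.append(
                        ("small-molecule-proximity",
                         f"{atom.residue_name} {atom.chain_id}{atom.residue_seq} "
                         f"at {dist:.2f} A")
                    )

    for gap in _residue_gaps(record.peptide):
        failed.append(("missing-residue", gap))

    # OXT is never required: templates cover the canonical heavy atoms only
    for key, resname, atoms in record.peptide.residues():
        present = {a.name for a in atoms}
        missing = sorted(set(HEAVY_ATOM_TEMPLATE[resname]) - present)
        if missing:
            failed.append(
                ("missing-atoms", f"residue {resname} {key[0]}{key[1]}: {missing}")
            )

    if len(record.receptor) < rules.min_receptor_atoms:
        failed.append(
            ("receptor-too-small",
             f"{len(record.receptor)} atoms < {rules.min_receptor_atoms}")
        )

    return CurationVerdict(passed=not failed, failed_rules=failed)
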