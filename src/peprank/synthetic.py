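"""Synthetic fixtures: peptides, decoy poses, receptors, feature tables.

Everything the pipeline consumes can be generated here, standing in for
crystallographic complexes and docking engines:

* an internal-coordinate (NeRF) peptide builder with exact control over
  backbone dihedrals (backbone + CB + terminal OXT, idealized geometry);
* decoy poses perturbed to a targeted heavy-atom RMSD (0-20 A) by
  translation, dihedral noise, or both, with the docking convention of
  at least two sub-2 A poses per complex;
* charged dummy receptor shells placed in a radial band around the
  peptide so that interaction detection, contact counting,
  electrostatics and fingerprints all have something to bite on;
* feature tables with planted signal (deterministic transforms of the
  RMSD target plus Gaussian noise) for recovery tests of the cleaning
  and selection cascade;
* block-structured TM-score matrices with known ground-truth clusters.

Every generator is a pure function of its seed and parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasplit import ClusterAssignment, SimilarityMatrix
from .descriptors import FeatureTable, one_hot_length
from .geometry import compute_phi_psi, dihedral, heavy_atom_rmsd
from .residues import ONE_TO_THREE
from .structio import Atom, ComplexRecord, MolecularStructure, Pose

__all__ = [
    "SyntheticSpec",
    "PerturbationError",
    "build_peptide",
    "perturb_pose",
    "make_receptor_shell",
    "make_complex",
    "make_pose_set",
    "simulate_feature_dataset",
    "make_similarity_matrix",
    "assign_dummy_charges",
]

# idealized backbone geometry (Angstrom / degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_C_OXT = 1.249
BOND_CA_CB = 1.521
ANGLE_N_CA_C = 111.0
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.5
ANGLE_CA_C_OXT = 117.0
ANGLE_N_CA_CB = 110.4
OMEGA = 180.0
CB_IMPROPER = 122.55  # torsion C-N-CA-CB, L-configuration

_ELEMENT = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C", "OXT": "O"}


class PerturbationError(RuntimeError):
    """Raised when a decoy cannot reach the requested RMSD."""


def _place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """NeRF atom placement: distance to c, angle at c, torsion about b-c."""
    ang = np.radians(angle_deg)
    tor = np.radians(torsion_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = np.array(
        [-bond * np.cos(ang), bond * np.sin(ang) * np.cos(tor),
         bond * np.sin(ang) * np.sin(tor)]
    )
    return c + np.column_stack([bc, m, n]) @ d2


def build_peptide(
    sequence: str,
    dihedrals: list[tuple[float, float]],
    chain_id: str = "P",
    source_id: str = "synthetic",
) -> MolecularStructure:
    """Build an all-backbone (+CB, +OXT) peptide at the given dihedrals.

    ``dihedrals[i] = (phi_i, psi_i)`` in degrees; the first phi is
    geometrically unused and the last psi orients the terminal
    carboxylate.  Recovering the angles with
    :func:`~peprank.geometry.compute_phi_psi` reproduces the interior
    requests to well under 1e-6 degrees.
    """
    sequence = sequence.upper()
    n = len(sequence)
    if not 3 <= n <= 10:
        raise ValueError(f"peptide length {n} outside 3-10")
    if len(dihedrals) != n:
        raise ValueError("need one (phi, psi) pair per residue")
    for phi, psi in dihedrals:
        if not (-180 <= phi <= 180 and -180 <= psi <= 180):
            raise ValueError(f"angles out of range: ({phi}, {psi})")
    resnames = []
    for letter in sequence:
        if letter not in ONE_TO_THREE:
            raise ValueError(f"unknown residue letter {letter!r}")
        resnames.append(ONE_TO_THREE[letter])

    coords: list[dict[str, np.ndarray]] = []
    # residue 1: N at origin, CA on x, C in the xy-plane
    first = {
        "N": np.zeros(3),
        "CA": np.array([BOND_N_CA, 0.0, 0.0]),
    }
    first["C"] = _place_atom(
        np.array([0.0, -1.0, 0.0]), first["N"], first["CA"],
        BOND_CA_C, ANGLE_N_CA_C, 0.0,
    )
    coords.append(first)

    for i in range(1, n):
        prev = coords[i - 1]
        psi_prev = dihedrals[i - 1][1]
        cur: dict[str, np.ndarray] = {}
        cur["N"] = _place_atom(prev["N"], prev["CA"], prev["C"],
                               BOND_C_N, ANGLE_CA_C_N, psi_prev)
        cur["CA"] = _place_atom(prev["CA"], prev["C"], cur["N"],
                                BOND_N_CA, ANGLE_C_N_CA, OMEGA)
        cur["C"] = _place_atom(prev["C"], cur["N"], cur["CA"],
                               BOND_CA_C, ANGLE_N_CA_C, dihedrals[i][0])
        # carbonyl O of the previous residue, anti to the new amide N
        prev["O"] = _place_atom(prev["N"], prev["CA"], prev["C"],
                                BOND_C_O, ANGLE_CA_C_O, psi_prev - 180.0)
        coords.append(cur)

    last = coords[-1]
    psi_last = dihedrals[-1][1]
    last["O"] = _place_atom(last["N"], last["CA"], last["C"],
                            BOND_C_O, ANGLE_CA_C_O, psi_last - 180.0)
    last["OXT"] = _place_atom(last["N"], last["CA"], last["C"],
                              BOND_C_OXT, ANGLE_CA_C_OXT, psi_last)

    for i, cur in enumerate(coords):
        if resnames[i] != "GLY":
            cur["CB"] = _place_atom(cur["C"], cur["N"], cur["CA"],
                                    BOND_CA_CB, ANGLE_N_CA_CB, CB_IMPROPER)

    atoms: list[Atom] = []
    serial = 0
    for i, cur in enumerate(coords):
        order = ["N", "CA", "C", "O"]
        if "CB" in cur:
            order.append("CB")
        if "OXT" in cur:
            order.append("OXT")
        for name in order:
            serial += 1
            atoms.append(
                Atom(
                    serial=serial,
                    name=name,
                    element=_ELEMENT[name],
                    residue_name=resnames[i],
                    residue_seq=i + 1,
                    chain_id=chain_id,
                    coords=cur[name],
                )
            )
    return MolecularStructure(atoms, source_id=source_id)


def assign_dummy_charges(
    structure: MolecularStructure, scale: float = 0.2, seed: int = 0
) -> MolecularStructure:
    """Attach N(0, scale) partial charges, rounded to 2 decimals.

    The rounding matches the precision of the PDB B-factor column used
    to carry charges through file round trips.
    """
    rng = np.random.default_rng(seed)
    charges = {}
    for a in structure.atoms:
        charges[(*a.residue_key, a.name)] = round(float(rng.normal(0, scale)), 2)
    return structure.with_charges(charges)


# ---------------------------------------------------------------------------
# Decoy generation


def _full_dihedrals(peptide: MolecularStructure) -> list[tuple[float, float]]:
    """Recover a complete per-residue (phi, psi) list, termini included.

    The undefined terminal angles are reconstructed from the carbonyl
    oxygen orientation (psi of the last residue) and set to 0 where
    truly absent (phi of the first residue, which is geometrically
    unused by the builder).
    """
    angles = compute_phi_psi(peptide)
    residues = peptide.residues()
    out = []
    for (idx, phi, psi), (_, _, atoms) in zip(angles.residues, residues):
        if psi is None:
            named = {a.name: a.coords for a in atoms}
            if "O" in named:
                psi = dihedral(named["N"], named["CA"], named["C"], named["O"]) + 180.0
                psi = ((psi + 180.0) % 360.0) - 180.0
            else:
                psi = 0.0
        if phi is None:
            phi = 0.0
        out.append((phi, psi))
    return out


def _kabsch_align(mobile: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Rigidly align mobile onto target (both (n, 3)); returns moved coords."""
    from scipy.spatial.transform import Rotation

    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    rot, _ = Rotation.align_vectors(target - tc, mobile - mc)
    return rot.apply(mobile - mc) + tc


def perturb_pose(
    native: Pose | MolecularStructure,
    target_rmsd: float,
    mode: str = "mixed",
    seed: int = 0,
    tolerance: float = 0.05,
) -> Pose:
    """A decoy whose heavy-atom RMSD to the native pose hits the target.

    ``rigid`` translates the pose along a random direction (RMSD equals
    the translation length, exact); ``dihedral`` adds scaled Gaussian
    noise to the backbone dihedrals, rebuilds, and rigidly re-anchors
    onto the native frame; ``mixed`` combines dihedral noise with a
    rigid rotation and translation.  Non-rigid modes reach the target by
    bisection on the perturbation amplitude to within ``tolerance``
    (default 5%) and require builder-style poses (backbone + CB).
    """
    st = native.structure if isinstance(native, Pose) else native
    pose_id = native.pose_id if isinstance(native, Pose) else "native"
    if target_rmsd < 0:
        raise ValueError("target RMSD must be non-negative")
    if mode not in ("rigid", "dihedral", "mixed"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)

    if target_rmsd == 0:
        return Pose(st, pose_id=pose_id, source=mode, rmsd=0.0)

    if mode == "rigid":
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        moved = st.transformed(np.eye(3), direction * target_rmsd)
        return Pose(moved, pose_id=pose_id, source=mode, rmsd=float(target_rmsd))

    # dihedral / mixed: deterministic perturbation direction, amplitude t
    from .residues import THREE_TO_ONE

    sequence = "".join(THREE_TO_ONE[name] for _, name, _ in st.residues())
    base_angles = _full_dihedrals(st)
    n = len(base_angles)
    deltas = rng.normal(size=(n, 2))
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    shift = rng.normal(size=3)
    shift /= np.linalg.norm(shift)
    native_xyz = st.coords()

    def build_at(t: float) -> MolecularStructure:
        angles = [
            (
                float(np.clip(phi + t * 30.0 * dphi, -180, 180)),
                float(np.clip(psi + t * 30.0 * dpsi, -180, 180)),
            )
            for (phi, psi), (dphi, dpsi) in zip(base_angles, deltas)
        ]
        rebuilt = build_peptide(sequence, angles, chain_id=st.atoms[0].chain_id,
                                source_id=st.source_id)
        aligned = _kabsch_align(rebuilt.coords(), native_xyz)
        moved = MolecularStructure(
            [
                Atom(a.serial, a.name, a.element, a.residue_name, a.residue_seq,
                     a.chain_id, xyz, a.icode, a.partial_charge, a.is_hetero)
                for a, xyz in zip(rebuilt.atoms, aligned)
            ],
            source_id=st.source_id,
        )
        if mode == "mixed":
            from scipy.spatial.transform import Rotation

            rot = Rotation.from_rotvec(axis * np.radians(t * 20.0)).as_matrix()
            center = moved.coords().mean(axis=0)
            moved = moved.transformed(rot, center - rot @ center + shift * t)
        return moved

    def rmsd_at(t: float) -> tuple[float, MolecularStructure]:
        cand = build_at(t)
        return heavy_atom_rmsd(st, cand, superpose=False), cand

    lo, hi = 0.0, 0.25
    val_hi, cand_hi = rmsd_at(hi)
    tries = 0
    while val_hi < target_rmsd and tries < 40:
        hi *= 2.0
        val_hi, cand_hi = rmsd_at(hi)
        tries += 1
    if val_hi < target_rmsd:
        raise PerturbationError(
            f"mode {mode!r} saturates at {val_hi:.2f} A below target {target_rmsd} A"
        )
    best_val, best_cand = val_hi, cand_hi
    for _ in range(60):
        mid = (lo + hi) / 2.0
        val, cand = rmsd_at(mid)
        if abs(val - target_rmsd) < abs(best_val - target_rmsd):
            best_val, best_cand = val, cand
        if abs(val - target_rmsd) <= tolerance * target_rmsd:
            break
        if val < target_rmsd:
            lo = mid
        else:
            hi = mid
    if abs(best_val - target_rmsd) > tolerance * target_rmsd:
        raise PerturbationError(
            f"could not reach {target_rmsd} A within {tolerance:.0%} "
            f"(best {best_val:.3f} A)"
        )
    return Pose(best_cand, pose_id=pose_id, source=mode, rmsd=float(best_val))


# ---------------------------------------------------------------------------
# Receptor shells and whole complexes


def make_receptor_shell(
    pose: Pose | MolecularStructure,
    n_atoms: int = 600,
    radius_band: tuple[float, float] = (3.0, 8.0),
    charge_scale: float = 0.2,
    seed: int = 0,
    chain_id: str = "R",
) -> MolecularStructure:
    """Charged dummy atoms in a radial band around the peptide.

    Each atom sits at a minimum distance to the peptide inside
    ``radius_band``; when the band starts below 5 A the first atom is
    constrained under 5 A so the interaction rule is guaranteed to fire.
    One single-atom residue per dummy atom.
    """
    st = pose.structure if isinstance(pose, Pose) else pose
    lo, hi = radius_band
    if not 0 < lo < hi:
        raise ValueError("invalid radius band")
    rng = np.random.default_rng(seed)
    pep = st.coords()
    elements = ("C", "N", "O")
    atoms: list[Atom] = []
    placed = 0
    attempts = 0
    while placed < n_atoms:
        attempts += 1
        if attempts > 200 * n_atoms:
            raise RuntimeError("shell placement did not converge")
        anchor = pep[rng.integers(len(pep))]
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        r = rng.uniform(lo, hi)
        x = anchor + direction * r
        dmin = float(np.min(np.linalg.norm(pep - x, axis=1)))
        upper = min(hi, 5.0 - 1e-6) if (placed == 0 and lo < 5.0) else hi
        if not lo <= dmin <= upper:
            continue
        placed += 1
        element = elements[placed % 3]
        atoms.append(
            Atom(
                serial=placed,
                name=element,
                element=element,
                residue_name="DUM",
                residue_seq=placed,
                chain_id=chain_id,
                coords=x,
                partial_charge=round(float(rng.normal(0, charge_scale)), 2),
            )
        )
    return MolecularStructure(atoms, source_id=st.source_id)


_HELIX = (-60.0, -45.0)
_SHEET = (-120.0, 130.0)


def sample_dihedrals(n: int, rng: np.random.Generator,
                     helix_fraction: float = 0.7) -> list[tuple[float, float]]:
    """Backbone angles from a helix/sheet mixture with Gaussian scatter."""
    out = []
    for _ in range(n):
        if rng.random() < helix_fraction:
            mu, sd = _HELIX, 10.0
        else:
            mu, sd = _SHEET, 15.0
        phi = float(np.clip(rng.normal(mu[0], sd), -179.9, 179.9))
        psi = float(np.clip(rng.normal(mu[1], sd), -179.9, 179.9))
        out.append((phi, psi))
    return out


def make_complex(
    complex_id: str,
    length: int = 5,
    seed: int = 0,
    n_receptor_atoms: int = 600,
    charge_scale: float = 0.2,
    alphabet: str = "AG",
) -> tuple[ComplexRecord, Pose]:
    """A random synthetic complex: built peptide + charged receptor shell.

    The default Ala/Gly alphabet keeps the built peptides complete with
    respect to the heavy-atom templates (the builder places backbone and
    CB only), so freshly generated complexes pass curation.
    """
    rng = np.random.default_rng(seed)
    sequence = "".join(alphabet[rng.integers(len(alphabet))] for _ in range(length))
    peptide = build_peptide(sequence, sample_dihedrals(length, rng),
                            source_id=complex_id)
    peptide = assign_dummy_charges(peptide, scale=charge_scale,
                                   seed=int(rng.integers(2**31)))
    native = Pose(peptide, pose_id="native", source="xray", rmsd=0.0)
    receptor = make_receptor_shell(
        native, n_atoms=n_receptor_atoms, charge_scale=charge_scale,
        seed=int(rng.integers(2**31)),
    )
    return ComplexRecord(receptor=receptor, peptide=peptide,
                         complex_id=complex_id), native


def make_pose_set(
    record: ComplexRecord,
    native: Pose,
    n_poses: int = 23,
    rmsd_range: tuple[float, float] = (0.0, 20.0),
    n_good: int = 2,
    seed: int = 0,
) -> list[Pose]:
    """A docking-like pose ensemble with at least ``n_good`` sub-2 A poses.

    The native pose is kept (RMSD 0), ``n_good`` decoys are targeted
    below 2 A, and the remainder spread over ``rmsd_range``.
    """
    if n_poses < 3:
        raise ValueError("need at least 3 poses per complex")
    rng = np.random.default_rng(seed)
    targets = [0.0]
    targets += list(rng.uniform(0.6, 1.8, size=n_good))
    lo, hi = max(rmsd_range[0], 2.0), rmsd_range[1]
    targets += list(rng.uniform(lo, hi, size=n_poses - 1 - n_good))
    poses = []
    for i, target in enumerate(targets):
        mode = "mixed" if target < 12 else "rigid"
        pose = perturb_pose(native, float(target), mode=mode,
                            seed=int(rng.integers(2**31)))
        pose.pose_id = f"p{i:02d}"
        charges = {(*a.residue_key, a.name): a.partial_charge
                   for a in record.peptide.atoms}
        pose.structure = pose.structure.with_charges(charges)
        poses.append(pose)
    return poses


# ---------------------------------------------------------------------------
# Planted-signal feature tables


@dataclass
class SyntheticSpec:
    """Study conditions for the simulated training corpus.

    Defaults mirror the real data shape: 23 poses per complex spanning
    0-20 A RMSD with at least two sub-2 A poses, peptide lengths 3-10,
    and a cluster structure dominated by singletons.
    """

    n_complexes: int = 50
    poses_per_complex: int = 23
    peptide_lengths: tuple[int, ...] = tuple(range(3, 11))
    rmsd_range: tuple[float, float] = (0.0, 20.0)
    n_good: int = 2
    n_informative: int = 5
    n_noise_continuous: int = 15
    n_noise_binary: int = 15
    noise: float = 0.1
    new_cluster_prob: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if any(not 3 <= n <= 10 for n in self.peptide_lengths):
            raise ValueError("peptide lengths must lie in 3-10")
        if self.poses_per_complex < 3:
            raise ValueError("poses_per_complex must be at least 3")


_TRANSFORMS = (
    lambda r: r,
    lambda r: np.sqrt(r),
    lambda r: np.log1p(r),
    lambda r: (r / 10.0) ** 2,
    lambda r: 20.0 - r,
    lambda r: np.cos(r / 4.0),
    lambda r: np.sqrt(np.maximum(20.0 - r, 0.0)),
)


def simulate_feature_dataset(
    spec: SyntheticSpec,
) -> tuple[FeatureTable, ClusterAssignment]:
    """A feature table with planted signal plus a cluster assignment.

    Informative columns (family RESCORE) are standardized deterministic
    transforms of the RMSD target plus N(0, noise) perturbation;
    continuous noise columns carry family 3D and binary noise columns
    family PLEC; one-hot length columns carry family LEN.
    """
    rng = np.random.default_rng(spec.seed)
    rows_cid, rows_pid, rmsds, lengths = [], [], [], []
    cluster_map: dict[str, str] = {}
    cluster_labels: list[str] = []
    for i in range(spec.n_complexes):
        cid = f"C{i:03d}"
        length = int(rng.choice(spec.peptide_lengths))
        if not cluster_labels or rng.random() < spec.new_cluster_prob:
            cluster_labels.append(cid)
            cluster_map[cid] = cid
        else:
            cluster_map[cid] = cluster_labels[rng.integers(len(cluster_labels))]
        good = rng.uniform(0.2, 1.9, size=spec.n_good)
        rest = rng.uniform(max(spec.rmsd_range[0], 2.0), spec.rmsd_range[1],
                           size=spec.poses_per_complex - spec.n_good)
        pose_rmsds = np.concatenate([good, rest])
        rng.shuffle(pose_rmsds)
        for j, value in enumerate(pose_rmsds):
            rows_cid.append(cid)
            rows_pid.append(f"p{j:02d}")
            rmsds.append(float(value))
            lengths.append(length)

    idx = pd.MultiIndex.from_arrays([rows_cid, rows_pid],
                                    names=["complex_id", "pose_id"])
    rmsd_arr = np.array(rmsds)
    data = {}
    families = {}
    for k in range(spec.n_informative):
        raw = _TRANSFORMS[k % len(_TRANSFORMS)](rmsd_arr)
        std = np.std(raw)
        signal = (raw - raw.mean()) / (std if std > 0 else 1.0)
        data[f"sim_signal_{k:02d}"] = signal + rng.normal(0, spec.noise,
                                                          size=len(rmsd_arr))
        families[f"sim_signal_{k:02d}"] = "RESCORE"
    for k in range(spec.n_noise_continuous):
        data[f"sim_noise_{k:02d}"] = rng.normal(size=len(rmsd_arr))
        families[f"sim_noise_{k:02d}"] = "3D"
    for k in range(spec.n_noise_binary):
        p = rng.uniform(0.05, 0.5)
        data[f"sim_bit_{k:02d}"] = rng.binomial(1, p, size=len(rmsd_arr)).astype(float)
        families[f"sim_bit_{k:02d}"] = "PLEC"
    onehot = np.vstack([one_hot_length(n) for n in lengths]).astype(float)
    for b in range(8):
        data[f"len_{b + 3}"] = onehot[:, b]
        families[f"len_{b + 3}"] = "LEN"

    table = FeatureTable(
        pd.DataFrame(data, index=idx),
        families,
        target=pd.Series(rmsd_arr, index=idx, name="RMSD"),
        groups=pd.Series([cluster_map[c] for c in rows_cid], index=idx,
                         name="cluster"),
    )
    return table, ClusterAssignment(cluster_map)


def make_similarity_matrix(
    cluster_sizes: list[int],
    within: tuple[float, float] = (0.41, 0.9),
    between: tuple[float, float] = (0.0, 0.39),
    seed: int = 0,
) -> SimilarityMatrix:
    """Block-structured TM-score matrix with planted clusters."""
    rng = np.random.default_rng(seed)
    n = int(np.sum(cluster_sizes))
    ids = [f"C{i:03d}" for i in range(n)]
    block = np.repeat(np.arange(len(cluster_sizes)), cluster_sizes)
    values = np.empty((n, n))
    for i in range(n):
        values[i, i] = 1.0
        for j in range(i + 1, n):
            lo, hi = within if block[i] == block[j] else between
            values[i, j] = values[j, i] = rng.uniform(lo, hi)
    return SimilarityMatrix(ids, values)
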