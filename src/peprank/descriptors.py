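"""Per-pose feature computation and assembly.

Five feature families describe every pose:

``RAM``
    the eight Ramachandran-index terms (peptide conformation only);
``3D``
    geometric shape descriptors of the peptide heavy-atom cloud, each
    also normalized by heavy-atom count and rotatable-bond count;
``RESCORE``
    interaction-energy style terms: a distance-dependent-dielectric
    Coulomb energy (ElectDD), the intermolecular contact count, and the
    contact-normalized energy; external engine scores (force-field,
    empirical docking scores, surface-area terms) merge into this family
    from a delimited text file;
``PLEC``
    a hashed count fingerprint over paired ligand/protein circular atom
    environments for every intermolecular heavy-atom contact;
``LEN``
    one-hot peptide length, 3-10 residues.

The table itself is a pandas DataFrame indexed by (complex_id, pose_id)
with a column-to-family map, an optional RMSD target and an optional
structural-cluster group label.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import compute_phi_psi
from .ramachandran import AngleDensityModel, ramachandran_index
from .residues import CHI_COUNT, INTRA_RESIDUE_BONDS
from .structio import ComplexRecord, MolecularStructure, Pose

__all__ = [
    "FeatureTable",
    "FingerprintConfig",
    "COULOMB_CONSTANT",
    "geometric_descriptors",
    "electdd",
    "normalized_score",
    "interaction_fingerprint",
    "one_hot_length",
    "assemble_feature_table",
]

#: Coulomb constant in kcal*A/(mol*e^2)
COULOMB_CONSTANT = 332.0636

FAMILIES = ("RAM", "3D", "RESCORE", "PLEC", "LEN")


@dataclass
class FingerprintConfig:
    size: int = 16384
    ligand_depth: int = 2
    protein_depth: int = 4
    contact_cutoff: float = 4.5

    def __post_init__(self) -> None:
        if self.size <= 0 or self.ligand_depth < 0 or self.protein_depth < 0:
            raise ValueError("invalid fingerprint configuration")


@dataclass
class FeatureTable:
    """Named per-pose features with family tags, target and group labels."""

    data: pd.DataFrame
    families: dict[str, str]
    target: pd.Series | None = None
    groups: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            raise ValueError("duplicate (complex_id, pose_id) row ids")
        unknown = set(self.families.values()) - set(FAMILIES)
        if unknown:
            raise ValueError(f"unknown feature families: {sorted(unknown)}")
        missing = set(self.data.columns) - set(self.families)
        if missing:
            raise ValueError(f"columns without family tag: {sorted(missing)}")
        if self.target is not None and (self.target.dropna() < 0).any():
            raise ValueError("RMSD target must be non-negative")

    @property
    def n_rows(self) -> int:
        return len(self.data)

    def columns_of(self, family: str) -> list[str]:
        return [c for c in self.data.columns if self.families[c] == family]

    def with_columns(self, columns: list[str]) -> "FeatureTable":
        fams = {c: self.families[c] for c in columns}
        return FeatureTable(self.data[columns].copy(), fams, self.target, self.groups)

    def drop_family(self, family: str) -> "FeatureTable":
        keep = [c for c in self.data.columns if self.families[c] != family]
        return self.with_columns(keep)

    def complex_ids(self) -> list[str]:
        return list(dict.fromkeys(self.data.index.get_level_values(0)))

    def to_tsv(self, path) -> None:
        df = self.data.copy()
        fam_line = "#family\t-\t-\t" + "\t".join(
            self.families[c] for c in df.columns
        )
        if self.target is not None:
            df["RMSD"] = self.target
            fam_line += "\tTARGET"
        if self.groups is not None:
            df["cluster"] = self.groups
            fam_line += "\tGROUP"
        with open(path, "w") as fh:
            fh.write(fam_line + "\n")
            df.to_csv(fh, sep="\t", index=True)

    @classmethod
    def from_tsv(cls, path) -> "FeatureTable":
        with open(path) as fh:
            fam_line = fh.readline().rstrip("\n")
            df = pd.read_csv(fh, sep="\t", index_col=[0, 1])
        if not fam_line.startswith("#family"):
            raise ValueError(f"{path}: missing #family header line")
        tags = fam_line.split("\t")[3:]
        target = groups = None
        cols = list(df.columns)
        families = {}
        for col, tag in zip(cols, tags):
            if tag == "TARGET":
                target = df[col]
            elif tag == "GROUP":
                groups = df[col]
            else:
                families[col] = tag
        data = df[[c for c in cols if c in families]]
        return cls(data, families, target, groups)


# ---------------------------------------------------------------------------
# 3D geometric descriptors


def _rotatable_bond_count(peptide: MolecularStructure) -> int:
    """Template-counted rotatable torsions: phi/psi plus side-chain chis."""
    residues = peptide.residues()
    n = len(residues)
    backbone = 2 * (n - 1)
    chis = sum(CHI_COUNT.get(resname, 0) for _, resname, _ in residues)
    return backbone + chis


def geometric_descriptors(pose: Pose | MolecularStructure) -> dict[str, float]:
    """Shape descriptors of the peptide heavy-atom cloud.

    Diameter3D is the maximum pairwise distance; Radius3D the minimum
    over atoms of the maximum distance to any other atom (geometric
    eccentricity radius); the shape and Petitjean indices are both
    (D - R) / R, reported under both conventional names; the three
    principal moments of inertia use unit masses; PBF is the RMS
    distance of atoms to their least-squares plane.  Each descriptor is
    also emitted divided by the heavy-atom count and by the
    template-counted rotatable-bond number.
    """
    st = pose.structure if isinstance(pose, Pose) else pose
    xyz = st.coords(heavy_only=True)
    if len(xyz) < 4:
        raise ValueError("need at least 4 heavy atoms")

    d = np.linalg.norm(xyz[:, None, :] - xyz[None, :, :], axis=2)
    ecc = d.max(axis=1)
    diameter = float(ecc.max())
    radius = float(ecc.min())
    shape_index = (diameter - radius) / radius

    centered = xyz - xyz.mean(axis=0)
    # inertia tensor with unit masses
    r2 = np.sum(centered**2, axis=1)
    inertia = np.eye(3) * r2.sum() - centered.T @ centered
    moments = np.sort(np.linalg.eigvalsh(inertia))

    # least-squares plane: normal = smallest principal axis of the gyration
    gyration = centered.T @ centered
    evals, evecs = np.linalg.eigh(gyration)
    if evals[1] < 1e-10:
        raise ValueError("degenerate (collinear) geometry: plane undefined")
    normal = evecs[:, 0]
    pbf = float(np.sqrt(np.mean((centered @ normal) ** 2)))

    base = {
        "Diameter3D": diameter,
        "Radius3D": radius,
        "GeometricalShapeIndex": shape_index,
        "PetitjeanIndex3D": shape_index,
        "MOI1": float(moments[0]),
        "MOI2": float(moments[1]),
        "MOI3": float(moments[2]),
        "PBF": pbf,
    }
    n_heavy = len(xyz)
    n_rot = max(_rotatable_bond_count(st), 1)
    out = dict(base)
    for name, value in base.items():
        out[f"{name}_per_heavy"] = value / n_heavy
        out[f"{name}_per_rotbond"] = value / n_rot
    return out


# ---------------------------------------------------------------------------
# Interaction-energy terms


def electdd(
    pose: Pose | MolecularStructure,
    receptor: MolecularStructure,
    dielectric_k: float = 1.0,
    coulomb_constant: float = COULOMB_CONSTANT,
    cutoff: float | None = None,
) -> float:
    """Coulomb energy with a distance-dependent dielectric, kcal/mol.

    eps(r) = k * r, so each intermolecular pair contributes
    C * q_i * q_j / (k * r^2).  All atoms carrying a charge participate;
    heavy atoms without a charge are an error.
    """
    pep = pose.structure if isinstance(pose, Pose) else pose
    missing = [
        f"{a.chain_id}{a.residue_seq}:{a.name}"
        for st in (pep, receptor)
        for a in st.atoms
        if a.is_heavy and a.partial_charge is None
    ]
    if missing:
        raise ValueError(f"atoms without partial charges: {missing[:10]}")

    def charged(st: MolecularStructure):
        atoms = [a for a in st.atoms if a.partial_charge is not None]
        q = np.array([a.partial_charge for a in atoms])
        xyz = np.vstack([a.coords for a in atoms]) if atoms else np.empty((0, 3))
        return q, xyz

    q1, x1 = charged(pep)
    q2, x2 = charged(receptor)
    if len(q1) == 0 or len(q2) == 0:
        return 0.0
    r = np.linalg.norm(x1[:, None, :] - x2[None, :, :], axis=2)
    with np.errstate(divide="ignore"):
        e = coulomb_constant * np.outer(q1, q2) / (dielectric_k * r**2)
    if cutoff is not None:
        e = np.where(r <= cutoff, e, 0.0)
    return float(e.sum())


def normalized_score(score: float, contacts: int) -> float:
    """Score divided by the receptor-ligand contact count; 0 if no contacts."""
    if contacts < 0:
        raise ValueError("contacts must be non-negative")
    if contacts == 0:
        warnings.warn("no receptor-ligand contacts; normalized score set to 0.0")
        return 0.0
    return score / contacts


# ---------------------------------------------------------------------------
# PLEC-style interaction fingerprint

_HASH_SEED = b"peprank-plec-v1:"


def _stable_hash(*parts) -> int:
    data = _HASH_SEED + "|".join(str(p) for p in parts).encode()
    return zlib.crc32(data) & 0xFFFFFFFF


def _bond_graph(st: MolecularStructure) -> dict[int, list[int]]:
    """Heavy-atom connectivity from residue templates plus peptide bonds.

    Residues without a template (e.g. dummy receptor-shell atoms) fall
    back to a 1.9 A distance rule within the residue; isolated atoms stay
    isolated.
    """
    adj: dict[int, list[int]] = {}
    index: dict[tuple, dict[str, int]] = {}
    heavy = [(i, a) for i, a in enumerate(st.atoms) if a.is_heavy]
    for i, a in heavy:
        adj[i] = []
        index.setdefault(a.residue_key, {})[a.name] = i

    def connect(i: int, j: int) -> None:
        adj[i].append(j)
        adj[j].append(i)

    residues = st.residues()
    for key, resname, atoms in residues:
        named = index.get(key, {})
        template = INTRA_RESIDUE_BONDS.get(resname)
        if template is not None:
            for a, b in template:
                if a in named and b in named:
                    connect(named[a], named[b])
        else:
            items = list(named.items())
            for ii in range(len(items)):
                for jj in range(ii + 1, len(items)):
                    pi, pj = items[ii][1], items[jj][1]
                    dist = np.linalg.norm(st.atoms[pi].coords - st.atoms[pj].coords)
                    if dist < 1.9:
                        connect(pi, pj)
    # inter-residue peptide bonds C(i) -> N(i+1) within a chain
    for (ka, ra, _), (kb, rb, _) in zip(residues, residues[1:]):
        if ka[0] != kb[0]:
            continue
        na, nb = index.get(ka, {}), index.get(kb, {})
        if "C" in na and "N" in nb:
            connect(na["C"], nb["N"])
    return adj


def _environment_ids(
    st: MolecularStructure, adj: dict[int, list[int]], max_depth: int
) -> dict[int, list[int]]:
    """Circular-environment identifiers per heavy atom for depths 0..max."""
    ids: dict[int, list[int]] = {}
    for i in adj:
        a = st.atoms[i]
        ids[i] = [_stable_hash("atom", a.element.upper(), len(adj[i]))]
    for depth in range(1, max_depth + 1):
        nxt = {}
        for i in adj:
            neigh = sorted(ids[j][depth - 1] for j in adj[i])
            nxt[i] = _stable_hash("env", depth, ids[i][depth - 1], *neigh)
        for i in adj:
            ids[i].append(nxt[i])
    return ids


def interaction_fingerprint(
    pose: Pose | MolecularStructure,
    receptor: MolecularStructure,
    cfg: FingerprintConfig | None = None,
) -> np.ndarray:
    """Hashed count vector over paired contact environments.

    For every intermolecular heavy-atom pair within ``contact_cutoff``,
    ligand and protein circular environments are grown in lockstep,
    clamped at their respective depths, and each (ligand id, protein id)
    pair is hashed into one of ``size`` buckets.  Deterministic across
    runs and platforms (CRC-32 with a fixed seed).
    """
    cfg = cfg or FingerprintConfig()
    pep = pose.structure if isinstance(pose, Pose) else pose
    counts = np.zeros(cfg.size, dtype=np.int64)

    pep_heavy = [(i, a) for i, a in enumerate(pep.atoms) if a.is_heavy]
    rec_heavy = [(i, a) for i, a in enumerate(receptor.atoms) if a.is_heavy]
    if not pep_heavy or not rec_heavy:
        return counts
    pep_xyz = np.vstack([a.coords for _, a in pep_heavy])
    rec_xyz = np.vstack([a.coords for _, a in rec_heavy])
    d = np.linalg.norm(pep_xyz[:, None, :] - rec_xyz[None, :, :], axis=2)
    pairs = np.argwhere(d < cfg.contact_cutoff)
    if len(pairs) == 0:
        return counts

    pep_env = _environment_ids(pep, _bond_graph(pep), cfg.ligand_depth)
    rec_env = _environment_ids(receptor, _bond_graph(receptor), cfg.protein_depth)
    max_depth = max(cfg.ligand_depth, cfg.protein_depth)
    for pi, ri in pairs:
        lig_idx = pep_heavy[pi][0]
        prot_idx = rec_heavy[ri][0]
        for depth in range(max_depth + 1):
            el = pep_env[lig_idx][min(depth, cfg.ligand_depth)]
            ep = rec_env[prot_idx][min(depth, cfg.protein_depth)]
            counts[_stable_hash("pair", el, ep) % cfg.size] += 1
    return counts


# ---------------------------------------------------------------------------
# Length encoding and table assembly


def one_hot_length(n: int) -> np.ndarray:
    """One-hot encoding of peptide length over the 3-10 residue range."""
    if not 3 <= n <= 10:
        raise ValueError(f"peptide length {n} outside 3-10")
    vec = np.zeros(8, dtype=int)
    vec[n - 3] = 1
    return vec


def assemble_feature_table(
    poses: list[tuple[ComplexRecord, Pose]],
    density: AngleDensityModel,
    external_scores: pd.DataFrame | str | None = None,
    fingerprint_config: FingerprintConfig | None = None,
    families: tuple[str, ...] = FAMILIES,
    contact_cutoff: float = 4.5,
) -> FeatureTable:
    """One feature row per pose; external columns merge as RESCORE.

    ``external_scores`` is a delimited table (or path) keyed by
    ``complex_id`` and ``pose_id``; it must cover every pose exactly.
    Poses whose native features cannot be computed are dropped with a
    warning.
    """
    cfg = fingerprint_config or FingerprintConfig()
    rows: list[dict[str, float]] = []
    index: list[tuple[str, str]] = []
    fam_map: dict[str, str] = {}
    targets: list[float | None] = []

    for record, pose in poses:
        try:
            row: dict[str, float] = {}
            if "RAM" in families:
                ram = ramachandran_index(compute_phi_psi(pose.structure), density)
                row.update(ram.as_dict())
                for name in ram.as_dict():
                    fam_map[name] = "RAM"
            if "3D" in families:
                geo = geometric_descriptors(pose)
                row.update(geo)
                for name in geo:
                    fam_map[name] = "3D"
            if "RESCORE" in families:
                from .geometry import count_contacts

                contacts = count_contacts(record.receptor, pose, cutoff=contact_cutoff)
                energy = electdd(pose, record.receptor)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    norm = normalized_score(energy, contacts)
                row.update(
                    {"ElectDD": energy, "n_contacts": float(contacts),
                     "ElectDD_norm_contact": norm}
                )
                for name in ("ElectDD", "n_contacts", "ElectDD_norm_contact"):
                    fam_map[name] = "RESCORE"
            if "PLEC" in families:
                fp = interaction_fingerprint(pose, record.receptor, cfg)
                width = len(str(cfg.size - 1))
                for b in range(cfg.size):
                    name = f"plec_{b:0{width}d}"
                    row[name] = float(fp[b])
                    fam_map[name] = "PLEC"
            if "LEN" in families:
                onehot = one_hot_length(record.peptide_length)
                for i, bit in enumerate(onehot):
                    name = f"len_{i + 3}"
                    row[name] = float(bit)
                    fam_map[name] = "LEN"
        except (ValueError, KeyError) as exc:
            warnings.warn(
                f"dropping pose {record.complex_id}/{pose.pose_id}: {exc}"
            )
            continue
        rows.append(row)
        index.append((record.complex_id, pose.pose_id))
        targets.append(pose.rmsd)

    idx = pd.MultiIndex.from_tuples(index, names=["complex_id", "pose_id"])
    data = pd.DataFrame(rows, index=idx)

    if external_scores is not None:
        ext = (
            pd.read_csv(external_scores, sep=None, engine="python")
            if isinstance(external_scores, str)
            else external_scores.copy()
        )
        ext = ext.set_index(["complex_id", "pose_id"])
        unknown = ext.index.difference(idx)
        if len(unknown):
            raise ValueError(f"external scores for unknown poses: {list(unknown)}")
        absent = idx.difference(ext.index)
        if len(absent):
            raise ValueError(f"external scores missing poses: {list(absent)}")
        ext = ext.loc[idx]
        for col in ext.columns:
            data[col] = ext[col].astype(float)
            fam_map[col] = "RESCORE"

    target = None
    if any(t is not None for t in targets):
        target = pd.Series(
            [np.nan if t is None else t for t in targets], index=idx, name="RMSD"
        )
    return FeatureTable(data, {c: fam_map[c] for c in data.columns}, target)
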