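"""Ramachandran-index descriptors.

An eight-term conformational descriptor for short peptides: the fraction
of residues falling in four empirically boxed regions of the (phi, psi)
plane, the arithmetic means of phi and psi, and the mean kernel-density
probability of phi and psi under densities fitted on a reference pool of
peptide backbone angles.

The region boxes were derived once from the 2-D angle density of a large
peptide pool and are fixed constants here.  The printed boxes overlap
(the region-1 helix/sheet boxes sit inside region 2's), so assignment
tests regions in priority order 1 -> 2 -> 3 and falls through to region
4; box boundaries are inclusive.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.stats import gaussian_kde

from .geometry import DihedralSet

__all__ = [
    "RamachandranIndex",
    "AngleDensityModel",
    "RamachandranError",
    "REGION_BOXES",
    "assign_region",
    "ramachandran_index",
    "fit_angle_density",
    "RAMACHANDRAN_FEATURES",
]

RAMACHANDRAN_FEATURES = (
    "region1", "region2", "region3", "region4",
    "phi_mean", "psi_mean", "phi_prob", "psi_prob",
)

#: region -> tuple of (phi_lo, phi_hi, psi_lo, psi_hi) boxes, inclusive.
#: Descending printed ranges are normalized to [lo, hi].
REGION_BOXES: dict[int, tuple[tuple[float, float, float, float], ...]] = {
    1: ((-130.0, -50.0, 120.0, 180.0), (-75.0, -60.0, -50.0, -25.0)),
    2: ((-150.0, -45.0, 100.0, 180.0), (-90.0, -45.0, -65.0, 0.0)),
    3: ((-180.0, -30.0, -180.0, 180.0), (-30.0, 105.0, -30.0, 90.0)),
}


class RamachandranError(ValueError):
    """Raised when the descriptor is undefined (no scorable residues)."""


def assign_region(phi: float, psi: float) -> int:
    """Region (1-4) of a (phi, psi) pair, first match in priority order."""
    if phi is None or psi is None:
        raise RamachandranError("phi/psi undefined; terminal residues must be filtered")
    if not (-180.0 <= phi <= 180.0 and -180.0 <= psi <= 180.0):
        raise ValueError(f"angles out of range: ({phi}, {psi})")
    for region in (1, 2, 3):
        for lo_phi, hi_phi, lo_psi, hi_psi in REGION_BOXES[region]:
            if lo_phi <= phi <= hi_phi and lo_psi <= psi <= hi_psi:
                return region
    return 4


@dataclass
class AngleDensityModel:
    """1-D Gaussian KDEs of the phi and psi angle pools (degrees)."""

    phi_pool: np.ndarray
    psi_pool: np.ndarray
    bandwidth_rule: str = "scott"

    def __post_init__(self) -> None:
        self.phi_pool = np.asarray(self.phi_pool, float).ravel()
        self.psi_pool = np.asarray(self.psi_pool, float).ravel()
        for name, pool in (("phi", self.phi_pool), ("psi", self.psi_pool)):
            if pool.size < 2:
                raise ValueError(f"{name} pool needs at least 2 angles")
            if np.ptp(pool) == 0:
                raise ValueError(f"{name} pool is degenerate (zero variance)")
        if self.bandwidth_rule != "scott":
            raise ValueError(f"unknown bandwidth rule {self.bandwidth_rule!r}")
        self._phi_kde = gaussian_kde(self.phi_pool, bw_method="scott")
        self._psi_kde = gaussian_kde(self.psi_pool, bw_method="scott")

    @property
    def pool_size(self) -> int:
        return int(self.phi_pool.size)

    def phi_density(self, angles) -> np.ndarray:
        return self._phi_kde(np.atleast_1d(np.asarray(angles, float)))

    def psi_density(self, angles) -> np.ndarray:
        return self._psi_kde(np.atleast_1d(np.asarray(angles, float)))

    def to_json(self, path) -> None:
        payload = {
            "format": "peprank-angle-density",
            "version": 1,
            "bandwidth_rule": self.bandwidth_rule,
            "phi_pool": self.phi_pool.tolist(),
            "psi_pool": self.psi_pool.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "AngleDensityModel":
        with open(path) as fh:
            payload = json.load(fh)
        if payload.get("format") != "peprank-angle-density":
            raise ValueError(f"{path}: not an angle-density artifact")
        return cls(
            np.array(payload["phi_pool"]),
            np.array(payload["psi_pool"]),
            payload.get("bandwidth_rule", "scott"),
        )


def fit_angle_density(
    angle_pool: list[tuple[float, float]] | np.ndarray,
    bandwidth_rule: str = "scott",
) -> AngleDensityModel:
    """Fit per-angle Gaussian KDEs on a pool of (phi, psi) pairs."""
    pool = np.asarray(angle_pool, float)
    if pool.ndim != 2 or pool.shape[1] != 2 or pool.shape[0] < 2:
        raise ValueError("angle pool must be an (n >= 2, 2) array of (phi, psi)")
    return AngleDensityModel(pool[:, 0], pool[:, 1], bandwidth_rule)


@dataclass(frozen=True)
class RamachandranIndex:
    """The eight-term descriptor vector."""

    region1: float
    region2: float
    region3: float
    region4: float
    phi_mean: float
    psi_mean: float
    phi_prob: float
    psi_prob: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in RAMACHANDRAN_FEATURES}

    def as_vector(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in RAMACHANDRAN_FEATURES])


def ramachandran_index(
    dihedrals: DihedralSet, density: AngleDensityModel
) -> RamachandranIndex:
    """Compute the eight-term descriptor from a peptide's dihedral set.

    Region fractions are n_i / N where N counts residues with *both*
    angles defined (terminal residues are excluded, which is why
    2-residue peptides are rejected: they have no scorable residue).
    Angle means are arithmetic means on [-180, 180], without circular
    wrap-around; the probability terms average the KDE density over the
    defined angles.
    """
    pairs = dihedrals.defined()
    n = len(pairs)
    if n == 0:
        raise RamachandranError(
            "no residue with both phi and psi defined; peptides of fewer than "
            "3 residues have no Ramachandran index"
        )
    counts = {1: 0, 2: 0, 3: 0, 4: 0}
    for phi, psi in pairs:
        counts[assign_region(phi, psi)] += 1
    phis = np.array([p for p, _ in pairs])
    psis = np.array([p for _, p in pairs])
    return RamachandranIndex(
        region1=counts[1] / n,
        region2=counts[2] / n,
        region3=counts[3] / n,
        region4=counts[4] / n,
        phi_mean=float(phis.mean()),
        psi_mean=float(psis.mean()),
        phi_prob=float(density.phi_density(phis).mean()),
        psi_prob=float(density.psi_density(psis).mean()),
    )
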