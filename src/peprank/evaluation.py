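"""Pose ranking, docking power and applicability-domain analysis.

Docking power is the fraction of complexes for which at least one of the
top-n ranked poses lies strictly below an RMSD success threshold
(2.0 A for heavy-atom RMSD, 2.5 A for backbone RMSD by convention),
reported as a curve over n = 1..10.

The applicability domain of the scorer is characterized by 1-nearest-
neighbor Euclidean distances in the 8-dimensional Ramachandran
descriptor space: poses far from the training data carry larger
prediction errors, and error binned by distance decile quantifies that
relationship after removing distance outliers beyond the 95th
percentile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import ks_2samp, pearsonr
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "DPCurve",
    "ADReport",
    "rank_poses",
    "docking_power",
    "nn_distance",
    "ad_analysis",
    "ks_two_sample",
]


@dataclass
class DPCurve:
    threshold: float
    rates: list[float]  # success rate for top-n, n = 1..len(rates)
    n_complexes: int

    def __post_init__(self) -> None:
        if any(not 0 <= r <= 1 for r in self.rates):
            raise ValueError("success rates must lie in [0, 1]")
        if any(b < a - 1e-12 for a, b in zip(self.rates, self.rates[1:])):
            raise ValueError("success rates must be non-decreasing in n")

    def top(self, n: int) -> float:
        return self.rates[n - 1]

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("top_n\tsuccess_rate\n")
            for n, rate in enumerate(self.rates, start=1):
                fh.write(f"{n}\t{rate:.6f}\n")


@dataclass
class ADReport:
    distances: np.ndarray
    p95_cutoff: float
    excluded_count: int
    bin_edges: np.ndarray
    bin_centers: np.ndarray
    bin_mean_distance: np.ndarray
    bin_mae: np.ndarray
    correlation_centers: float
    correlation_means: float

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("bin\tcenter\tmean_distance\tmae\n")
            for i, (c, m, e) in enumerate(
                zip(self.bin_centers, self.bin_mean_distance, self.bin_mae)
            ):
                fh.write(f"{i}\t{c:.6f}\t{m:.6f}\t{e:.6f}\n")


def rank_poses(scores: dict[str, float], direction: str = "asc") -> list[str]:
    """Pose ids ordered best-first; stable (ties keep input order).

    ``asc`` ranks small scores first (predicted RMSD), ``desc`` large
    first (affinity-like scores).
    """
    if direction not in ("asc", "desc"):
        raise ValueError("direction must be 'asc' or 'desc'")
    items = list(scores.items())
    sign = 1.0 if direction == "asc" else -1.0
    order = sorted(range(len(items)), key=lambda i: (sign * items[i][1], i))
    return [items[i][0] for i in order]


def docking_power(
    rankings: dict[str, list[str]],
    rmsd_labels: dict[tuple[str, str], float],
    threshold: float = 2.0,
    n_max: int = 10,
) -> DPCurve:
    """Success-rate curve over the top-n ranked poses, n = 1..n_max.

    A complex succeeds at n when the minimum RMSD label among its top-n
    poses is strictly below ``threshold``.
    """
    if not rankings:
        raise ValueError("no complexes to evaluate")
    rates = []
    for n in range(1, n_max + 1):
        hits = 0
        for cid, ordered in rankings.items():
            if not ordered:
                raise ValueError(f"complex {cid} has no poses")
            top = ordered[:n]
            labels = [rmsd_labels[(cid, pid)] for pid in top]
            if min(labels) < threshold:
                hits += 1
        rates.append(hits / len(rankings))
    return DPCurve(threshold=threshold, rates=rates, n_complexes=len(rankings))


def nn_distance(query_rows: np.ndarray, reference_rows: np.ndarray) -> np.ndarray:
    """Euclidean distance from each query to its nearest reference row."""
    query = np.atleast_2d(np.asarray(query_rows, float))
    ref = np.atleast_2d(np.asarray(reference_rows, float))
    nn = NearestNeighbors(n_neighbors=1, metric="euclidean").fit(ref)
    dist, _ = nn.kneighbors(query)
    return dist[:, 0]


def ad_analysis(
    distances: np.ndarray,
    abs_errors: np.ndarray,
    outlier_percentile: float = 95.0,
    n_bins: int = 10,
) -> ADReport:
    """Bin prediction error by 1-NN distance after outlier removal.

    Pairs with distance above the ``outlier_percentile`` (linear-
    interpolation convention) are excluded; the rest are binned by
    distance percentile edges at every 100/n_bins-th percentile
    (right-closed bins).  Reports per-bin MAE and the Pearson
    correlation of MAE with bin centers (midpoints) and with bin mean
    distances.
    """
    distances = np.asarray(distances, float)
    abs_errors = np.asarray(abs_errors, float)
    if distances.shape != abs_errors.shape:
        raise ValueError("distances and errors must align")
    cutoff = float(np.percentile(distances, outlier_percentile))
    keep = distances <= cutoff
    excluded = int(np.sum(~keep))
    d, e = distances[keep], abs_errors[keep]
    if d.size < n_bins:
        raise ValueError(f"only {d.size} retained pairs for {n_bins} bins")

    edges = np.percentile(d, np.linspace(0, 100, n_bins + 1))
    edges = np.unique(edges)
    if len(edges) < 2:
        raise ValueError("degenerate distance distribution")
    # right-closed bins; the lowest edge is inclusive on the left
    idx = np.searchsorted(edges, d, side="left") - 1
    idx = np.clip(idx, 0, len(edges) - 2)

    centers, mean_d, mae_bins = [], [], []
    for b in range(len(edges) - 1):
        mask = idx == b
        if not mask.any():
            continue
        centers.append((edges[b] + edges[b + 1]) / 2)
        mean_d.append(float(d[mask].mean()))
        mae_bins.append(float(e[mask].mean()))
    centers = np.array(centers)
    mean_d = np.array(mean_d)
    mae_bins = np.array(mae_bins)
    r_centers = float(pearsonr(centers, mae_bins).statistic) \
        if np.std(mae_bins) > 0 and len(centers) > 1 else 0.0
    r_means = float(pearsonr(mean_d, mae_bins).statistic) \
        if np.std(mae_bins) > 0 and len(mean_d) > 1 else 0.0
    return ADReport(
        distances=distances,
        p95_cutoff=cutoff,
        excluded_count=excluded,
        bin_edges=edges,
        bin_centers=centers,
        bin_mean_distance=mean_d,
        bin_mae=mae_bins,
        correlation_centers=r_centers,
        correlation_means=r_means,
    )


def ks_two_sample(sample_a, sample_b) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov statistic and two-sided p-value."""
    result = ks_2samp(np.asarray(sample_a, float), np.asarray(sample_b, float))
    return float(result.statistic), float(result.pvalue)
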