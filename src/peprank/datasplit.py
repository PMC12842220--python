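"""Structural clustering and grouped, stratified data splitting.

Binding-pocket similarity arrives as a square TM-score matrix (parsed
from an external structural aligner).  Complexes whose pockets score
above 0.4 are connected in a graph and its connected components become
structural clusters.  Splitting then treats clusters as atomic groups:
no cluster ever spans the train/evaluation boundary or two CV folds,
and the train/evaluation split additionally stratifies on peptide
length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from Bio import Align
from sklearn.model_selection import GroupKFold, StratifiedGroupKFold

__all__ = [
    "SimilarityMatrix",
    "ClusterAssignment",
    "SplitSpec",
    "read_similarity_matrix",
    "graph_cluster",
    "grouped_stratified_split",
    "grouped_kfold",
    "greedy_identity_cluster",
]


@dataclass
class SimilarityMatrix:
    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("similarity matrix must be square over the ids")
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise ValueError("TM-scores must lie in [0, 1]")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("similarity matrix must be symmetric")

    def score(self, a: str, b: str) -> float:
        i, j = self.ids.index(a), self.ids.index(b)
        return float(self.values[i, j])


@dataclass
class ClusterAssignment:
    mapping: dict[str, str]

    @property
    def n_clusters(self) -> int:
        return len(set(self.mapping.values()))

    def members(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for cid, cluster in self.mapping.items():
            out.setdefault(cluster, []).append(cid)
        return out


@dataclass
class SplitSpec:
    partition: dict[str, str]  # complex id -> "train" | "eval"

    def ids(self, which: str) -> list[str]:
        return [cid for cid, part in self.partition.items() if part == which]

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("complex_id\tpartition\n")
            for cid, part in self.partition.items():
                fh.write(f"{cid}\t{part}\n")

    @classmethod
    def from_tsv(cls, path) -> "SplitSpec":
        df = pd.read_csv(path, sep="\t")
        return cls(dict(zip(df["complex_id"].astype(str), df["partition"])))


def read_similarity_matrix(path) -> SimilarityMatrix:
    """Read a square TM-score table with matching row/column headers.

    The aligner reports two scores per pair (one per chain-length
    normalization); when the stored matrix is asymmetric, the larger of
    the (i, j) and (j, i) entries is kept on both sides, matching the
    longer-chain normalization convention.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    ids = [str(i) for i in df.index]
    if [str(c) for c in df.columns] != ids:
        raise ValueError(f"{path}: row and column ids differ")
    values = df.to_numpy(dtype=float)
    if np.any(values < 0) or np.any(values > 1):
        raise ValueError(f"{path}: TM-scores outside [0, 1]")
    if not np.allclose(values, values.T, atol=1e-9):
        warnings.warn("asymmetric similarity input; symmetrizing by max")
        values = np.maximum(values, values.T)
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(ids, values)


def graph_cluster(matrix: SimilarityMatrix, threshold: float = 0.4) -> ClusterAssignment:
    """Connected components of the graph with edges where score > threshold.

    Strict inequality; cluster labels are the smallest member id, making
    the assignment deterministic.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    g = nx.Graph()
    g.add_nodes_from(matrix.ids)
    n = len(matrix.ids)
    for i in range(n):
        for j in range(i + 1, n):
            if matrix.values[i, j] > threshold:
                g.add_edge(matrix.ids[i], matrix.ids[j])
    mapping: dict[str, str] = {}
    for component in nx.connected_components(g):
        label = min(component)
        for cid in component:
            mapping[cid] = label
    return ClusterAssignment({cid: mapping[cid] for cid in matrix.ids})


def _check_records(records, clusters: ClusterAssignment):
    ids = [cid for cid, _ in records]
    missing = [cid for cid in ids if cid not in clusters.mapping]
    if missing:
        raise ValueError(f"records without cluster assignment: {missing}")
    return ids


def grouped_stratified_split(
    records: list[tuple[str, int]],
    clusters: ClusterAssignment,
    n_splits: int = 4,
    seed: int = 0,
) -> SplitSpec:
    """Cluster-atomic train/evaluation split, stratified on peptide length.

    One of ``n_splits`` grouped, stratified folds becomes the evaluation
    partition (~1/n_splits of the complexes, 25% at the default 4);
    structural clusters are never split.  Deterministic given the seed.
    """
    ids = _check_records(records, clusters)
    lengths = np.array([length for _, length in records])
    groups = np.array([clusters.mapping[cid] for cid in ids])
    if len(set(groups)) < n_splits:
        raise ValueError(
            f"need at least {n_splits} clusters, got {len(set(groups))}"
        )
    # strata rarer than n_splits cannot be stratified; pool them, and if
    # the pooled stratum is itself too small, fold it into the modal one
    lengths = lengths.copy()
    while True:
        values, counts = np.unique(lengths, return_counts=True)
        rare = [v for v, c in zip(values, counts) if c < n_splits]
        if not rare or len(values) == 1:
            break
        if -1 in rare or len(rare) == 1:
            modal = values[np.argmax(counts)]
            lengths[np.isin(lengths, rare)] = modal
        else:
            lengths[np.isin(lengths, rare)] = -1
    splitter = StratifiedGroupKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    train_idx, eval_idx = next(splitter.split(np.zeros(len(ids)), lengths, groups))
    partition = {}
    for i in train_idx:
        partition[ids[i]] = "train"
    for i in eval_idx:
        partition[ids[i]] = "eval"
    return SplitSpec({cid: partition[cid] for cid in ids})


def grouped_kfold(
    records: list[tuple[str, int]],
    clusters: ClusterAssignment,
    k: int = 10,
    seed: int = 0,
) -> dict[str, int]:
    """Cluster-atomic k-fold assignment: complex id -> fold index."""
    ids = _check_records(records, clusters)
    groups = np.array([clusters.mapping[cid] for cid in ids])
    if len(set(groups)) < k:
        raise ValueError(f"need at least {k} clusters, got {len(set(groups))}")
    splitter = GroupKFold(n_splits=k, shuffle=True, random_state=seed)
    folds: dict[str, int] = {}
    for fold, (_, test_idx) in enumerate(
        splitter.split(np.zeros(len(ids)), groups=groups)
    ):
        for i in test_idx:
            folds[ids[i]] = fold
    return {cid: folds[cid] for cid in ids}


def _alignment_identity(aligner: Align.PairwiseAligner, a: str, b: str) -> float:
    """Global-alignment identity: matches / alignment length (incl. gaps)."""
    alignment = aligner.align(a, b)[0]
    counts = alignment.counts()
    length = counts.identities + counts.mismatches + counts.gaps
    return counts.identities / length if length else 0.0


def greedy_identity_cluster(
    sequences: list[tuple[str, str]],
    threshold: float = 0.75,
) -> ClusterAssignment:
    """Greedy longest-first sequence-identity clustering.

    Sequences are visited longest-first; each joins the first existing
    cluster whose representative aligns with identity >= ``threshold``
    under unit match/mismatch/gap scoring, otherwise it founds a new
    cluster (and becomes its representative).
    """
    for sid, seq in sequences:
        if not seq:
            raise ValueError(f"empty sequence for {sid}")
    aligner = Align.PairwiseAligner(
        mode="global",
        match_score=1,
        mismatch_score=-1,
        open_gap_score=-1,
        extend_gap_score=-1,
    )
    ordered = sorted(sequences, key=lambda item: (-len(item[1]), item[0]))
    representatives: list[tuple[str, str]] = []  # (cluster label, sequence)
    mapping: dict[str, str] = {}
    for sid, seq in ordered:
        for label, rep_seq in representatives:
            if _alignment_identity(aligner, rep_seq, seq) >= threshold:
                mapping[sid] = label
                break
        else:
            representatives.append((sid, seq))
            mapping[sid] = sid
    return ClusterAssignment({sid: mapping[sid] for sid, _ in sequences})
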