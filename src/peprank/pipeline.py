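"""End-to-end synthetic workflow: simulate, split, clean, select, train,
score, and evaluate docking power and applicability domain.

This is the desk-scale counterpart of the full study workflow, used by
the acceptance script and the pipeline-level recovery tests.
"""

from __future__ import annotations

import numpy as np

from .datasplit import grouped_kfold, grouped_stratified_split
from .descriptors import FeatureTable
from .evaluation import ad_analysis, docking_power, ks_two_sample, nn_distance, rank_poses
from .model import (
    PoseRmsdModel,
    drop_collinear,
    mae,
    pearson_r,
    tree_importance_filter,
    variance_filter,
)
from .synthetic import SyntheticSpec, simulate_feature_dataset

__all__ = ["run_synthetic_pipeline"]


def _subset(table: FeatureTable, ids: set[str]) -> FeatureTable:
    mask = [cid in ids for cid in table.data.index.get_level_values(0)]
    return FeatureTable(
        table.data[mask], table.families,
        table.target[mask] if table.target is not None else None,
        table.groups[mask] if table.groups is not None else None,
    )


def run_synthetic_pipeline(
    spec: SyntheticSpec,
    algorithm: str = "hgb",
    sfs_algorithm: str = "linear",
    max_features: int = 8,
    k_folds: int = 5,
    dp_threshold: float = 2.0,
    seed: int | None = None,
) -> dict:
    """Run the full workflow on simulated data and report its metrics.

    Returns held-out MAE / Pearson R, the top-1..10 docking-power curve,
    and the applicability-domain quantities (p95 exclusion count, bin
    MAE correlation, KS statistic between train and eval 1-NN
    distances).
    """
    seed = spec.seed if seed is None else seed
    table, clusters = simulate_feature_dataset(spec)
    records = [
        (cid, int(table.data.loc[cid].filter(like="len_", axis=1).iloc[0].to_numpy()
                  .argmax() + 3))
        for cid in table.complex_ids()
    ]
    split = grouped_stratified_split(records, clusters, n_splits=4, seed=seed)
    train_ids, eval_ids = set(split.ids("train")), set(split.ids("eval"))
    train_table = _subset(table, train_ids)
    eval_table = _subset(table, eval_ids)

    train_table = drop_collinear(train_table, family="3D", r_threshold=0.9)
    if train_table.columns_of("PLEC"):
        train_table = variance_filter(train_table, family="PLEC", threshold=0.1)
    if train_table.columns_of("PLEC"):
        train_table = tree_importance_filter(
            train_table, family="PLEC", importance_threshold=0.001, seed=seed
        )

    train_records = [(cid, 0) for cid in train_table.complex_ids()]
    k = min(k_folds, len({clusters.mapping[cid] for cid, _ in train_records}))
    folds = grouped_kfold(train_records, clusters, k=k, seed=seed)
    model = PoseRmsdModel(train_table, algorithm, folds, seed=seed)
    results = model.fit(use_sfs=True, sfs_algorithm=sfs_algorithm,
                        max_features=max_features)

    preds = results.predict(eval_table.data)
    y_eval = eval_table.target.to_numpy(float)
    held_out_mae = mae(y_eval, preds)
    held_out_r = pearson_r(y_eval, preds)

    rankings = {}
    labels = {}
    eval_index = eval_table.data.index
    for cid in eval_table.complex_ids():
        rows = [i for i, c in enumerate(eval_index.get_level_values(0))
                if c == cid]
        scores = {eval_index[i][1]: float(preds[i]) for i in rows}
        rankings[cid] = rank_poses(scores, direction="asc")
        for i in rows:
            labels[(cid, eval_index[i][1])] = float(y_eval[i])
    curve = docking_power(rankings, labels, threshold=dp_threshold)

    ram_like = results.selected_features
    X_train = train_table.data[ram_like].to_numpy(float)
    X_eval = eval_table.data[ram_like].to_numpy(float)
    dist_eval = nn_distance(X_eval, X_train)
    from sklearn.neighbors import NearestNeighbors

    nn = NearestNeighbors(n_neighbors=2).fit(X_train)
    dist_train = nn.kneighbors(X_train)[0][:, 1]
    errors = np.abs(preds - y_eval)
    n_bins = min(10, max(2, len(dist_eval) // 20))
    ad = ad_analysis(dist_eval, errors, n_bins=n_bins)
    ks_stat, ks_p = ks_two_sample(dist_train, dist_eval)

    return {
        "results": results,
        "cv_report": results.cv_report,
        "split": split,
        "held_out_mae": held_out_mae,
        "held_out_r": held_out_r,
        "dp_curve": curve,
        "ad_report": ad,
        "ks_statistic": ks_stat,
        "ks_pvalue": ks_p,
        "n_train_rows": train_table.n_rows,
        "n_eval_rows": eval_table.n_rows,
        "n_clusters": clusters.n_clusters,
        "selected_features": results.selected_features,
    }
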