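"""Pose-RMSD regression: cleaning, CV, feature selection, persistence.

The learning core follows the statsmodels idiom: :class:`PoseRmsdModel`
is built from a :class:`~peprank.descriptors.FeatureTable` and a grouped
fold map, and ``fit()`` returns a :class:`PoseRmsdResults` carrying the
fitted scorer, the cross-validation report, the selected features and a
``summary()`` table.  The individual pipeline steps remain importable
functions so they can be composed and tested independently.

All estimators run with scikit-learn default hyperparameters: on this
problem, tuning was found to add nothing over the defaults, and defaults
keep the models reproducible and cheap.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from scipy.stats import pearsonr
from sklearn.ensemble import (
    GradientBoostingRegressor,
    HistGradientBoostingRegressor,
    RandomForestRegressor,
)
from sklearn.linear_model import ElasticNet, LinearRegression
from sklearn.svm import SVR

from .descriptors import FeatureTable

__all__ = [
    "ALGORITHMS",
    "CVReport",
    "TrainedScorer",
    "PoseRmsdModel",
    "PoseRmsdResults",
    "mae",
    "pearson_r",
    "drop_collinear",
    "variance_filter",
    "tree_importance_filter",
    "cross_validate",
    "sequential_forward_selection",
    "train_final",
    "predict_rmsd",
]

ALGORITHMS = ("linear", "elasticnet", "rf", "gb", "hgb", "svr")


def make_estimator(algorithm: str, seed: int = 0):
    """A fresh default-parameter estimator for the given algorithm id."""
    if algorithm == "linear":
        return LinearRegression()
    if algorithm == "elasticnet":
        return ElasticNet(random_state=seed)
    if algorithm == "rf":
        return RandomForestRegressor(random_state=seed)
    if algorithm == "gb":
        return GradientBoostingRegressor(random_state=seed)
    if algorithm == "hgb":
        return HistGradientBoostingRegressor(random_state=seed)
    if algorithm == "svr":
        return SVR()
    raise ValueError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")


# ---------------------------------------------------------------------------
# Metrics


def mae(y_true, y_pred) -> float:
    y_true = np.asarray(y_true, float)
    y_pred = np.asarray(y_pred, float)
    return float(np.mean(np.abs(y_true - y_pred)))


def pearson_r(y_true, y_pred) -> float:
    y_true = np.asarray(y_true, float)
    y_pred = np.asarray(y_pred, float)
    if np.std(y_true) == 0 or np.std(y_pred) == 0:
        raise ValueError("Pearson R undefined for zero-variance input")
    return float(pearsonr(y_true, y_pred).statistic)


# ---------------------------------------------------------------------------
# Feature cleaning


def drop_collinear(
    table: FeatureTable, family: str = "3D", r_threshold: float = 0.9
) -> FeatureTable:
    """Greedy collinearity filter within one feature family.

    Columns are scanned in table order; a column is dropped when its
    absolute Pearson correlation with any *retained* earlier column
    exceeds ``r_threshold``.  Constant columns are self-collinear and
    dropped with a warning.
    """
    cols = table.columns_of(family)
    if table.n_rows < 2:
        raise ValueError("need at least 2 rows")
    retained: list[str] = []
    data = table.data
    for col in cols:
        x = data[col].to_numpy(float)
        if np.std(x) == 0:
            warnings.warn(f"constant column {col!r} dropped")
            continue
        collinear = False
        for kept in retained:
            r = np.corrcoef(x, data[kept].to_numpy(float))[0, 1]
            if abs(r) > r_threshold:
                collinear = True
                break
        if not collinear:
            retained.append(col)
    keep = [c for c in data.columns if table.families[c] != family or c in retained]
    return table.with_columns(keep)


def variance_filter(
    table: FeatureTable, family: str = "PLEC", threshold: float = 0.1
) -> FeatureTable:
    """Drop family columns whose sample variance is below ``threshold``."""
    cols = table.columns_of(family)
    variances = table.data[cols].var(axis=0, ddof=1) if cols else pd.Series(dtype=float)
    dropped = {c for c in cols if variances[c] < threshold}
    keep = [c for c in table.data.columns if c not in dropped]
    return table.with_columns(keep)


def tree_importance_filter(
    table: FeatureTable,
    family: str = "PLEC",
    importance_threshold: float = 0.001,
    seed: int = 0,
) -> FeatureTable:
    """Keep family columns with forest impurity importance > threshold."""
    if table.target is None:
        raise ValueError("feature table has no RMSD target")
    y = table.target.to_numpy(float)
    if len(np.unique(y)) < 2:
        raise ValueError("target must have at least 2 distinct values")
    cols = table.columns_of(family)
    if not cols:
        return table
    forest = RandomForestRegressor(random_state=seed)
    forest.fit(table.data[cols].to_numpy(float), y)
    retained = {
        c for c, imp in zip(cols, forest.feature_importances_)
        if imp > importance_threshold
    }
    keep = [c for c in table.data.columns
            if table.families[c] != family or c in retained]
    return table.with_columns(keep)


# ---------------------------------------------------------------------------
# Cross-validation


@dataclass
class CVReport:
    fold_ids: list[int]
    fold_mae: list[float]
    fold_r: list[float | None]
    algorithm: str = ""

    @property
    def mean_mae(self) -> float:
        return float(np.mean(self.fold_mae))

    @property
    def mean_r(self) -> float:
        valid = [r for r in self.fold_r if r is not None]
        if not valid:
            raise ValueError("Pearson R undefined in every fold")
        return float(np.mean(valid))

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("fold\tmae\tpearson_r\n")
            for fold, m, r in zip(self.fold_ids, self.fold_mae, self.fold_r):
                fh.write(f"{fold}\t{m:.6f}\t{'' if r is None else f'{r:.6f}'}\n")
            fh.write(f"mean\t{self.mean_mae:.6f}\t{self.mean_r:.6f}\n")


def _row_folds(table: FeatureTable, folds: dict[str, int]) -> np.ndarray:
    complex_ids = table.data.index.get_level_values(0)
    missing = sorted(set(complex_ids) - set(folds))
    if missing:
        raise ValueError(f"complexes without fold assignment: {missing}")
    return np.array([folds[cid] for cid in complex_ids])


def _fold_scores(X: np.ndarray, y: np.ndarray, labels: np.ndarray,
                 algorithm: str, seed: int):
    for fold in np.unique(labels):
        test = labels == fold
        if test.sum() < 2 or (~test).sum() < 2:
            raise ValueError(f"fold {fold} has fewer than 2 rows on one side")
        est = make_estimator(algorithm, seed)
        est.fit(X[~test], y[~test])
        yield fold, y[test], est.predict(X[test])


def cross_validate(
    table: FeatureTable,
    algorithm: str,
    folds: dict[str, int],
    seed: int = 0,
) -> CVReport:
    """Grouped k-fold CV: fit on k-1 folds, score the held-out fold.

    Folds with zero prediction variance are flagged (R of ``None``) and
    excluded from the R average with a warning rather than poisoning it.
    """
    if table.target is None:
        raise ValueError("feature table has no RMSD target")
    X = table.data.to_numpy(float)
    y = table.target.to_numpy(float)
    labels = _row_folds(table, folds)
    fold_ids, fold_mae, fold_r = [], [], []
    for fold, y_test, y_hat in _fold_scores(X, y, labels, algorithm, seed):
        fold_ids.append(int(fold))
        fold_mae.append(mae(y_test, y_hat))
        if np.std(y_hat) == 0 or np.std(y_test) == 0:
            warnings.warn(f"fold {fold}: zero-variance predictions; R excluded")
            fold_r.append(None)
        else:
            fold_r.append(pearson_r(y_test, y_hat))
    return CVReport(fold_ids, fold_mae, fold_r, algorithm=algorithm)


# ---------------------------------------------------------------------------
# Sequential forward selection


def sequential_forward_selection(
    table: FeatureTable,
    algorithm: str,
    folds: dict[str, int],
    criterion: str = "mae",
    max_features: int | None = None,
    seed: int = 0,
    return_curve: bool = False,
):
    """Classic forward SFS minimizing CV-average MAE at each step.

    Returns the prefix of the selection order achieving the global best
    MAE (``k_features='best'`` semantics).  ``max_features`` caps the
    scan length; the default scans every feature.  With
    ``return_curve=True`` the full ``[(feature, cv_mae), ...]`` path is
    returned alongside the selected prefix.
    """
    if criterion != "mae":
        raise ValueError("only the MAE criterion is supported")
    if table.target is None:
        raise ValueError("feature table has no RMSD target")
    features = list(table.data.columns)
    if len(features) < 1:
        raise ValueError("no candidate features")
    X_all = table.data.to_numpy(float)
    y = table.target.to_numpy(float)
    labels = _row_folds(table, folds)
    col_of = {name: i for i, name in enumerate(features)}

    def cv_mae(col_idx: list[int]) -> float:
        X = X_all[:, col_idx]
        scores = [
            mae(y_test, y_hat)
            for _, y_test, y_hat in _fold_scores(X, y, labels, algorithm, seed)
        ]
        return float(np.mean(scores))

    selected: list[str] = []
    curve: list[tuple[str, float]] = []
    remaining = list(features)
    limit = len(features) if max_features is None else min(max_features, len(features))
    while remaining and len(selected) < limit:
        best_feat, best_score = None, np.inf
        for feat in remaining:
            score = cv_mae([col_of[f] for f in selected + [feat]])
            if score < best_score:
                best_feat, best_score = feat, score
        selected.append(best_feat)
        remaining.remove(best_feat)
        curve.append((best_feat, best_score))

    best_len = int(np.argmin([score for _, score in curve])) + 1
    chosen = selected[:best_len]
    return (chosen, curve) if return_curve else chosen


# ---------------------------------------------------------------------------
# Final model and persistence

_ARTIFACT_VERSION = 1


@dataclass
class TrainedScorer:
    """A fitted regressor bound to its ordered feature-name schema."""

    estimator: object
    feature_names: list[str]
    metadata: dict = field(default_factory=dict)

    def predict(self, rows: pd.DataFrame | FeatureTable) -> np.ndarray:
        data = rows.data if isinstance(rows, FeatureTable) else rows
        missing = [f for f in self.feature_names if f not in data.columns]
        if missing:
            raise ValueError(f"missing selected features: {missing}")
        X = data[self.feature_names].to_numpy(float)
        return np.clip(self.estimator.predict(X), 0.0, None)

    def save(self, path) -> None:
        joblib.dump(
            {
                "format": "peprank-scorer",
                "version": _ARTIFACT_VERSION,
                "estimator": self.estimator,
                "feature_names": self.feature_names,
                "metadata": self.metadata,
            },
            path,
        )

    @classmethod
    def load(cls, path) -> "TrainedScorer":
        payload = joblib.load(path)
        if payload.get("format") != "peprank-scorer":
            raise ValueError(f"{path}: not a peprank scorer artifact")
        return cls(payload["estimator"], payload["feature_names"], payload["metadata"])


def train_final(
    table: FeatureTable,
    algorithm: str = "hgb",
    selected: list[str] | None = None,
    seed: int = 0,
) -> TrainedScorer:
    """Fit the final scorer on all rows using the selected features."""
    if table.target is None:
        raise ValueError("feature table has no RMSD target")
    selected = list(selected) if selected is not None else list(table.data.columns)
    unknown = [f for f in selected if f not in table.data.columns]
    if unknown:
        raise ValueError(f"unknown feature names: {unknown}")
    est = make_estimator(algorithm, seed)
    est.fit(table.data[selected].to_numpy(float), table.target.to_numpy(float))
    fold_hash = hashlib.sha256(
        ",".join(sorted(table.complex_ids())).encode()
    ).hexdigest()[:16]
    return TrainedScorer(
        est,
        selected,
        metadata={
            "algorithm": algorithm,
            "seed": seed,
            "n_rows": table.n_rows,
            "complex_hash": fold_hash,
            "families": {f: table.families[f] for f in selected},
        },
    )


def predict_rmsd(scorer: TrainedScorer, rows: pd.DataFrame | FeatureTable) -> np.ndarray:
    """Predicted RMSD per row, in Angstrom, clipped below at zero."""
    return scorer.predict(rows)


# ---------------------------------------------------------------------------
# statsmodels-style surface


class PoseRmsdModel:
    """Pose-RMSD regression model over a feature table.

    Parameters
    ----------
    table
        Feature table with RMSD target (and group labels for CV).
    algorithm
        One of ``linear, elasticnet, rf, gb, hgb, svr``; default ``hgb``.
    folds
        Grouped fold map ``complex_id -> fold``; required for
        cross-validation and SFS.
    """

    def __init__(
        self,
        table: FeatureTable,
        algorithm: str = "hgb",
        folds: dict[str, int] | None = None,
        seed: int = 0,
    ) -> None:
        if algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {algorithm!r}")
        self.table = table
        self.algorithm = algorithm
        self.folds = folds
        self.seed = seed

    @classmethod
    def from_feature_table(cls, table: FeatureTable, **kwargs) -> "PoseRmsdModel":
        return cls(table, **kwargs)

    def fit(
        self,
        selected: list[str] | None = None,
        use_sfs: bool = False,
        sfs_algorithm: str | None = None,
        max_features: int | None = None,
    ) -> "PoseRmsdResults":
        """Optionally select features by SFS, cross-validate, and fit."""
        sfs_curve = None
        if use_sfs:
            if self.folds is None:
                raise ValueError("SFS requires a grouped fold map")
            selected, sfs_curve = sequential_forward_selection(
                self.table,
                sfs_algorithm or self.algorithm,
                self.folds,
                max_features=max_features,
                seed=self.seed,
                return_curve=True,
            )
        working = (
            self.table.with_columns(selected) if selected is not None else self.table
        )
        cv_report = None
        if self.folds is not None:
            cv_report = cross_validate(working, self.algorithm, self.folds, self.seed)
        scorer = train_final(working, self.algorithm, None, self.seed)
        return PoseRmsdResults(self, scorer, cv_report, sfs_curve)


class PoseRmsdResults:
    """Fit results: the trained scorer, CV diagnostics, selection path."""

    def __init__(self, model: PoseRmsdModel, scorer: TrainedScorer,
                 cv_report: CVReport | None, sfs_curve=None) -> None:
        self.model = model
        self.scorer = scorer
        self.cv_report = cv_report
        self.sfs_curve = sfs_curve

    @property
    def selected_features(self) -> list[str]:
        return list(self.scorer.feature_names)

    def predict(self, rows: pd.DataFrame | FeatureTable) -> np.ndarray:
        return self.scorer.predict(rows)

    def save(self, path) -> None:
        self.scorer.save(path)

    def summary(self) -> str:
        lines = [
            "Pose RMSD regression results",
            "=" * 40,
            f"algorithm:         {self.model.algorithm}",
            f"n training rows:   {self.model.table.n_rows}",
            f"n features:        {len(self.selected_features)}",
            f"seed:              {self.model.seed}",
        ]
        if self.cv_report is not None:
            lines += [
                f"CV folds:          {len(self.cv_report.fold_ids)}",
                f"CV mean MAE (A):   {self.cv_report.mean_mae:.3f}",
                f"CV mean Pearson R: {self.cv_report.mean_r:.3f}",
            ]
        if self.sfs_curve is not None:
            lines.append("SFS selection order (feature, CV MAE):")
            for feat, score in self.sfs_curve[: len(self.selected_features)]:
                lines.append(f"  {feat:<28s} {score:.3f}")
        return "\n".join(lines)
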