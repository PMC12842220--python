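"""Feature cleaning, cross-validation, SFS, training and persistence."""

import numpy as np
import pandas as pd
import pytest
from sklearn.tree import DecisionTreeRegressor

from peprank.descriptors import FeatureTable
from peprank.model import (
    PoseRmsdModel,
    TrainedScorer,
    cross_validate,
    drop_collinear,
    mae,
    pearson_r,
    predict_rmsd,
    sequential_forward_selection,
    train_final,
    tree_importance_filter,
    variance_filter,
)


def _table(data: dict, family="3D", target=None, groups=None):
    n = len(next(iter(data.values())))
    idx = pd.MultiIndex.from_tuples(
        [(f"c{i // 2}", f"p{i % 2}") for i in range(n)],
        names=["complex_id", "pose_id"],
    )
    df = pd.DataFrame(data, index=idx)
    fams = {c: family for c in df.columns}
    t = pd.Series(target, index=idx, name="RMSD") if target is not None else None
    g = pd.Series(groups, index=idx, name="cluster") if groups is not None else None
    return FeatureTable(df, fams, t, g)


def _folded_table(n_complexes=30, n_poses=10, n_features=5, noise=0.1, seed=0,
                  family="RESCORE"):
    rng = np.random.default_rng(seed)
    idx = pd.MultiIndex.from_tuples(
        [(f"c{i:02d}", f"p{j:02d}") for i in range(n_complexes)
         for j in range(n_poses)],
        names=["complex_id", "pose_id"],
    )
    y = rng.uniform(0, 20, size=len(idx))
    X = {}
    for k in range(n_features):
        X[f"f{k}"] = y * (k + 1) * 0.1 + rng.normal(0, noise, len(idx))
    df = pd.DataFrame(X, index=idx)
    table = FeatureTable(df, {c: family for c in df.columns},
                         pd.Series(y, index=idx, name="RMSD"))
    folds = {f"c{i:02d}": i % 5 for i in range(n_complexes)}
    return table, folds


class TestMetrics:
    def test_exact_agreement(self):
        y = np.array([1.0, 2.0, 3.0])
        assert mae(y, y) == 0.0
        assert pearson_r(y, y) == pytest.approx(1.0)

    def test_anticorrelation(self):
        y = np.array([1.0, 2.0, 5.0])
        assert pearson_r(y, -y) == pytest.approx(-1.0)

    def test_matches_textbook_formulas(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=50), rng.normal(size=50)
        assert mae(a, b) == pytest.approx(np.sum(np.abs(a - b)) / 50)
        am, bm = a - a.mean(), b - b.mean()
        expected = np.sum(am * bm) / np.sqrt(np.sum(am**2) * np.sum(bm**2))
        assert pearson_r(a, b) == pytest.approx(expected, rel=1e-12)

    def test_zero_variance_undefined(self):
        with pytest.raises(ValueError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestDropCollinear:
    def test_duplicate_column_dropped(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=20)
        table = _table({"a": x, "b": x.copy(), "c": rng.normal(size=20)})
        out = drop_collinear(table, family="3D", r_threshold=0.9)
        assert list(out.data.columns) == ["a", "c"]

    def test_orthogonal_columns_survive(self):
        rng = np.random.default_rng(3)
        cols = {f"x{i}": rng.normal(size=200) for i in range(6)}
        out = drop_collinear(_table(cols))
        assert list(out.data.columns) == list(cols)

    def test_constant_column_dropped_with_warning(self):
        table = _table({"const": np.ones(10), "x": np.arange(10.0)})
        with pytest.warns(UserWarning):
            out = drop_collinear(table)
        assert list(out.data.columns) == ["x"]

    def test_postcondition_on_random_tables(self):
        rng = np.random.default_rng(4)
        for trial in range(20):
            base = rng.normal(size=(60, 4))
            mix = base @ rng.normal(size=(4, 10)) + 0.3 * rng.normal(size=(60, 10))
            table = _table({f"m{i}": mix[:, i] for i in range(10)})
            out = drop_collinear(table, r_threshold=0.9)
            arr = out.data.to_numpy()
            corr = np.corrcoef(arr.T)
            off = np.abs(corr[np.triu_indices(arr.shape[1], 1)])
            assert np.all(off <= 0.9 + 1e-12)
            # dropped columns were collinear with something retained
            dropped = set(table.data.columns) - set(out.data.columns)
            for col in dropped:
                rs = [abs(np.corrcoef(table.data[col], out.data[kept])[0, 1])
                      for kept in out.data.columns]
                assert max(rs) > 0.9

    def test_other_families_untouched(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=30)
        idx = pd.MultiIndex.from_tuples(
            [(f"c{i}", "p0") for i in range(30)], names=["complex_id", "pose_id"]
        )
        df = pd.DataFrame({"a": x, "b": x.copy(), "r": x.copy()}, index=idx)
        table = FeatureTable(df, {"a": "3D", "b": "3D", "r": "RESCORE"})
        out = drop_collinear(table, family="3D")
        assert "r" in out.data.columns and "b" not in out.data.columns


class TestVarianceFilter:
    def test_constant_and_bernoulli(self):
        rng = np.random.default_rng(6)
        table = _table(
            {"zero": np.zeros(4000), "coin": rng.binomial(1, 0.5, 4000).astype(float)},
            family="PLEC",
        )
        out = variance_filter(table, threshold=0.1)
        assert list(out.data.columns) == ["coin"]

    def test_matches_direct_variance(self):
        rng = np.random.default_rng(7)
        cols = {f"b{i}": rng.binomial(1, rng.uniform(0.02, 0.5), 500).astype(float)
                for i in range(20)}
        table = _table(cols, family="PLEC")
        out = variance_filter(table, threshold=0.1)
        expected = [c for c in cols if np.var(cols[c], ddof=1) >= 0.1]
        assert list(out.data.columns) == expected


class TestTreeImportanceFilter:
    def test_planted_signal_recovered_and_deterministic(self):
        rng = np.random.default_rng(8)
        n = 300
        y = rng.uniform(0, 20, n)
        cols = {"signal": y + rng.normal(0, 0.5, n)}
        cols.update({f"n{i:02d}": rng.normal(size=n) for i in range(20)})
        table = _table(cols, family="PLEC", target=y)
        out = tree_importance_filter(table, family="PLEC", seed=0)
        assert "signal" in out.data.columns
        out2 = tree_importance_filter(table, family="PLEC", seed=0)
        assert list(out.data.columns) == list(out2.data.columns)

    def test_partition_law(self):
        rng = np.random.default_rng(9)
        y = rng.uniform(0, 10, 100)
        cols = {f"n{i}": rng.normal(size=100) for i in range(10)}
        table = _table(cols, family="PLEC", target=y)
        out = tree_importance_filter(table, family="PLEC", seed=1)
        retained = set(out.data.columns)
        assert retained <= set(cols)

    def test_degenerate_target_errors(self):
        table = _table({"x": np.arange(10.0)}, family="PLEC",
                       target=np.ones(10))
        with pytest.raises(ValueError):
            tree_importance_filter(table)


class TestCrossValidate:
    def test_perfect_linear_fit(self):
        table, folds = _folded_table(noise=0.0, seed=10)
        report = cross_validate(table, "linear", folds)
        assert all(m < 1e-8 for m in report.fold_mae)
        assert report.mean_r > 0.9999

    def test_null_features_give_no_correlation(self):
        rs = []
        for seed in range(5):
            rng = np.random.default_rng(1000 + seed)
            table, folds = _folded_table(noise=0.1, seed=seed)
            # overwrite target with pure noise, independent of features
            table = FeatureTable(
                table.data, table.families,
                pd.Series(rng.uniform(0, 20, table.n_rows),
                          index=table.data.index),
            )
            rs.append(cross_validate(table, "linear", folds).mean_r)
        assert abs(np.mean(rs)) < 0.2

    def test_mae_near_analytic_noise_floor(self):
        # absolute error of N(0, sigma) residuals has mean sigma*sqrt(2/pi)
        sigma = 1.0
        table, folds = _folded_table(n_complexes=60, n_poses=12, n_features=3,
                                     noise=0.0, seed=11)
        rng = np.random.default_rng(12)
        noisy = pd.Series(
            table.target.to_numpy() + 5.0 + rng.normal(0, sigma, table.n_rows),
            index=table.data.index,
        )
        table = FeatureTable(table.data, table.families, noisy)
        report = cross_validate(table, "linear", folds)
        floor = sigma * np.sqrt(2 / np.pi)
        assert report.mean_mae == pytest.approx(floor, rel=0.2)

    def test_small_fold_errors(self):
        table, _ = _folded_table(n_complexes=4, n_poses=1)
        folds = {f"c{i:02d}": i for i in range(4)}
        with pytest.raises(ValueError):
            cross_validate(table, "linear", folds)


class TestSequentialForwardSelection:
    def test_single_feature_selected(self):
        table, folds = _folded_table(n_features=1, seed=13)
        assert sequential_forward_selection(table, "linear", folds) == ["f0"]

    def test_duplicated_informative_feature_selected_once(self):
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(40 + seed)
            n = 200
            idx = pd.MultiIndex.from_tuples(
                [(f"c{i // 10}", f"p{i % 10}") for i in range(n)],
                names=["complex_id", "pose_id"],
            )
            y = rng.uniform(0, 20, n)
            sig = y + rng.normal(0, 0.3, n)
            data = {"sig_a": sig, "sig_b": sig.copy()}
            data.update({f"noise{i}": rng.normal(size=n) for i in range(6)})
            table = FeatureTable(
                pd.DataFrame(data, index=idx),
                {c: "RESCORE" for c in data},
                pd.Series(y, index=idx),
            )
            folds = {f"c{i}": i % 4 for i in range(20)}
            selected = sequential_forward_selection(
                table, "linear", folds, max_features=4
            )
            first_noise = next(
                (k for k, f in enumerate(selected) if f.startswith("noise")),
                len(selected),
            )
            n_sig = sum(1 for f in selected[:first_noise]
                        if f.startswith("sig"))
            hits += n_sig == 1
        assert hits >= 4

    def test_curve_non_increasing_to_best_prefix(self):
        table, folds = _folded_table(n_features=6, noise=2.0, seed=14)
        selected, curve = sequential_forward_selection(
            table, "linear", folds, return_curve=True
        )
        maes = [score for _, score in curve[: len(selected)]]
        assert all(b <= a + 1e-12 for a, b in zip(maes, maes[1:]))
        assert len(selected) == int(np.argmin([s for _, s in curve])) + 1


class TestTrainPredictPersist:
    def test_fits_better_than_mean_predictor(self):
        table, _ = _folded_table(noise=0.5, seed=15)
        scorer = train_final(table, algorithm="hgb")
        preds = scorer.predict(table)
        assert mae(table.target, preds) < np.std(table.target.to_numpy())

    def test_save_load_prediction_identity(self, tmp_path):
        table, _ = _folded_table(seed=16)
        scorer = train_final(table, algorithm="rf")
        path = tmp_path / "model.joblib"
        scorer.save(path)
        back = TrainedScorer.load(path)
        rng = np.random.default_rng(17)
        rows = pd.DataFrame(
            rng.uniform(0, 2, size=(100, len(scorer.feature_names))),
            columns=scorer.feature_names,
        )
        assert np.array_equal(scorer.predict(rows), back.predict(rows))

    def test_column_order_irrelevant_at_predict_time(self):
        table, _ = _folded_table(seed=18)
        scorer = train_final(table, algorithm="linear")
        shuffled = table.data[list(table.data.columns)[::-1]]
        assert np.allclose(scorer.predict(shuffled), scorer.predict(table.data))

    def test_predictions_clipped_at_zero(self):
        table, _ = _folded_table(seed=19)
        scorer = train_final(table, algorithm="linear")
        rows = pd.DataFrame(
            -50.0 * np.ones((5, len(scorer.feature_names))),
            columns=scorer.feature_names,
        )
        assert (scorer.predict(rows) >= 0).all()

    def test_memorizing_tree_reproduces_training_targets(self):
        table, _ = _folded_table(n_complexes=10, n_poses=4, seed=20)
        tree = DecisionTreeRegressor(random_state=0)
        X = table.data.to_numpy()
        y = table.target.to_numpy()
        tree.fit(X, y)
        scorer = TrainedScorer(tree, list(table.data.columns))
        assert np.allclose(predict_rmsd(scorer, table.data), y)

    def test_unknown_feature_errors(self):
        table, _ = _folded_table(seed=21)
        with pytest.raises(ValueError):
            train_final(table, selected=["nope"])
        scorer = train_final(table)
        with pytest.raises(ValueError, match="missing"):
            scorer.predict(table.data.drop(columns=["f0"]))


class TestModelResultsSurface:
    def test_fit_summary_and_determinism(self):
        table, folds = _folded_table(seed=22)
        res_a = PoseRmsdModel(table, "hgb", folds, seed=3).fit()
        res_b = PoseRmsdModel(table, "hgb", folds, seed=3).fit()
        assert np.array_equal(res_a.predict(table.data), res_b.predict(table.data))
        text = res_a.summary()
        assert "hgb" in text and "CV mean MAE" in text

    def test_sfs_path_exposed(self):
        table, folds = _folded_table(n_features=4, noise=1.0, seed=23)
        res = PoseRmsdModel(table, "linear", folds).fit(use_sfs=True,
                                                        max_features=3)
        assert 1 <= len(res.selected_features) <= 3
        assert res.sfs_curve is not None
        assert "SFS selection order" in res.summary()
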