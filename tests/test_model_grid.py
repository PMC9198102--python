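import numpy as np
import pandas as pd
import pytest

from georadiomics import FeatureTable
from georadiomics.model_grid import (
    ClassifierSpec,
    FSKind,
    FSMethodSpec,
    default_classifier_specs,
    default_fs_specs,
    make_preprocessor,
    run_grid,
    select_features,
    stratified_split,
    train_eval,
    zscore_fit_apply,
)


def make_table(n=100, k=10, n_bm=None, informative=0, sep=3.0, seed=0, roi="SP20"):
    """Synthetic feature table; first `informative` columns shift by class."""
    n_bm = int(0.48 * n) if n_bm is None else n_bm
    rng = np.random.default_rng(seed)
    labels = np.array(["BM"] * n_bm + ["HB"] * (n - n_bm))
    rng.shuffle(labels)
    X = rng.standard_normal((n, k))
    X[:, :informative] += np.where(labels == "BM", sep, 0.0)[:, None]
    data = {
        "patient_id": [f"p{i}" for i in range(n)],
        "point_id": [f"pt{i}" for i in range(n)],
        "roi": [roi] * n,
        "label": labels,
    }
    for j in range(k):
        data[f"f{j}"] = X[:, j]
    return FeatureTable(pd.DataFrame(data))


class TestZScore:
    def test_population_sd_example(self):
        scaled, _, params = zscore_fit_apply(np.array([[1.0], [2.0], [3.0]]))
        np.testing.assert_allclose(scaled.ravel(), [-1.224744871, 0.0, 1.224744871])

    def test_constant_column_zeroed_and_flagged(self):
        train = np.column_stack([np.ones(5), np.arange(5.0)])
        scaled, _, params = zscore_fit_apply(train)
        assert np.all(scaled[:, 0] == 0.0)
        assert params["constant"].tolist() == [True, False]

    def test_train_statistics_only(self):
        train = np.array([[0.0], [2.0]])
        test = np.array([[4.0]])
        _, scaled_test, _ = zscore_fit_apply(train, test)
        assert scaled_test[0, 0] == pytest.approx(3.0)  # (4-1)/1

    def test_scaled_train_mean_zero_sd_one(self, rng):
        train = rng.normal(5, 3, (40, 6))
        scaled, _, _ = zscore_fit_apply(train)
        np.testing.assert_allclose(scaled.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(scaled.std(axis=0), 1.0, atol=1e-10)


class TestStratifiedSplit:
    def test_split_arithmetic_48_52(self):
        table = make_table(n=100, n_bm=48)
        train, test = stratified_split(table, 0.3, seed=0)
        assert test.n_samples == 30
        n_bm_test = int((test.labels == "BM").sum())
        assert n_bm_test in (14, 15)  # within one sample of 0.48 * 30
        assert train.n_samples == 70

    def test_same_seed_same_split(self):
        table = make_table()
        a = stratified_split(table, 0.3, seed=5)
        b = stratified_split(table, 0.3, seed=5)
        pd.testing.assert_frame_equal(a[0].data, b[0].data)

    def test_partition_exact(self):
        table = make_table()
        train, test = stratified_split(table, 0.3, seed=1)
        ids = sorted(train.data["point_id"]) + sorted(test.data["point_id"])
        assert sorted(ids) == sorted(table.data["point_id"])
        assert set(train.data["point_id"]).isdisjoint(test.data["point_id"])

    def test_single_class_rejected(self):
        table = make_table(n=10, n_bm=10)
        with pytest.raises(ValueError, match="single-class"):
            stratified_split(table, 0.3, seed=0)


class TestFeatureSelection:
    def test_none_keeps_everything(self):
        assert select_features(FSMethodSpec(FSKind.NONE)) is None
        prep = make_preprocessor(FSMethodSpec(FSKind.NONE))
        X = np.random.default_rng(0).standard_normal((20, 7))
        assert prep.fit_transform(X, None).shape == (20, 7)

    @pytest.mark.parametrize("n", [20, 24, 30])
    def test_pca_component_counts(self, n):
        table = make_table(n=120, k=107)
        prep = make_preprocessor(FSMethodSpec(FSKind.PCA, n_components=n))
        Z = prep.fit_transform(table.feature_matrix(), table.binary_labels())
        assert Z.shape[1] == n

    def test_lasso_selects_the_informative_feature(self):
        table = make_table(n=120, k=51, informative=1, sep=4.0, seed=3)
        prep = make_preprocessor(FSMethodSpec(FSKind.LASSO, alpha=1.0))
        prep.fit(table.feature_matrix(), table.binary_labels())
        support = prep.named_steps["fs"].support_
        assert support[0]  # the label-correlated column survives the L1 penalty

    def test_lasso_zero_selection_falls_back_to_one(self, caplog):
        # pure noise + savage penalty: keep exactly one feature, logged
        table = make_table(n=30, k=10, informative=0, seed=1)
        sel = select_features(FSMethodSpec(FSKind.LASSO, alpha=1000.0))
        scaled, _, _ = zscore_fit_apply(table.feature_matrix())
        with caplog.at_level("WARNING"):
            sel.fit(scaled, table.binary_labels())
        assert sel.support_.sum() == 1

    def test_vt_runs_before_scaling(self):
        # one near-constant raw feature: VT_0.8 must see raw variances
        rng = np.random.default_rng(0)
        table = make_table(n=80, k=5, seed=2)
        table.data["f0"] = 100.0 + 0.01 * rng.standard_normal(80)
        prep = make_preprocessor(FSMethodSpec(FSKind.VT, variance_threshold=0.8))
        Z = prep.fit_transform(table.feature_matrix(), table.binary_labels())
        assert Z.shape[1] == 4  # f0 dropped despite z-scoring downstream

    def test_thirteen_plus_none(self):
        specs = default_fs_specs()
        assert len(specs) == 14
        assert len({s.name for s in specs}) == 14
        assert specs[0].kind == FSKind.NONE


class TestTrainEval:
    def test_separable_table_gives_auc_one(self):
        table = make_table(n=80, k=5, informative=2, sep=6.0, seed=0)
        train, test = stratified_split(table, 0.3, seed=0)
        cell = train_eval(
            train, test, FSMethodSpec(FSKind.NONE), ClassifierSpec("L-SVM", "L-SVM")
        )
        assert not cell.failed
        assert cell.test_auc == 1.0

    def test_permuted_labels_give_null_cv_auc(self):
        table = make_table(n=120, k=8, informative=2, sep=4.0, seed=0)
        rng = np.random.default_rng(7)
        permuted = table.data.copy()
        permuted["label"] = rng.permutation(permuted["label"].to_numpy())
        ptable = FeatureTable(permuted)
        train, test = stratified_split(ptable, 0.3, seed=0)
        cell = train_eval(
            train, test, FSMethodSpec(FSKind.NONE), ClassifierSpec("L-SVM", "L-SVM")
        )
        # CV AUC consistent with chance: mean within 3 SE of 0.5
        se = cell.cv_auc_sd / np.sqrt(5)
        assert abs(cell.cv_auc_mean - 0.5) < 3 * max(se, 1e-6)

    def test_auc_invariant_under_monotone_score_transform(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 60)
        scores = rng.standard_normal(60) + y
        a = roc_auc_score(y, scores)
        b = roc_auc_score(y, np.exp(2 * scores))
        assert a == pytest.approx(b, abs=1e-12)

    def test_leakage_canary(self):
        """A feature that encodes the label on *test* rows only (noise on
        training rows) must not inflate training CV AUC: the scaler and FS
        never see test data."""
        table = make_table(n=120, k=6, informative=0, seed=4)
        train, test = stratified_split(table, 0.3, seed=0)
        canary_train = train.data.copy()
        canary_test = test.data.copy()
        canary_test["f0"] = canary_test["label"].eq("BM").astype(float) * 10.0
        tr, te = FeatureTable(canary_train), FeatureTable(canary_test)
        cell = train_eval(
            tr, te, FSMethodSpec(FSKind.LASSO, alpha=0.5), ClassifierSpec("L-SVM", "L-SVM")
        )
        se = max(cell.cv_auc_sd / np.sqrt(5), 1e-6)
        assert abs(cell.cv_auc_mean - 0.5) < 4 * se

    def test_failed_classifier_recorded_not_raised(self):
        table = make_table(n=20, k=3)
        train, test = stratified_split(table, 0.3, seed=0)
        # inject a classifier whose fit always blows up
        from georadiomics.model_grid import _CLASSIFIER_BUILDERS

        _CLASSIFIER_BUILDERS["__boom__"] = lambda seed: (_ for _ in ()).throw(
            RuntimeError("no fit")
        )
        try:
            cell = train_eval(
                train, test, FSMethodSpec(FSKind.NONE), ClassifierSpec("boom", "__boom__")
            )
        finally:
            del _CLASSIFIER_BUILDERS["__boom__"]
        assert cell.failed and "no fit" in cell.reason


class TestRunGrid:
    def test_cell_count_arithmetic(self):
        tables = {
            "SP20": make_table(n=40, k=6, informative=1, seed=0),
            "SP30": make_table(n=40, k=6, informative=1, seed=1, roi="SP30"),
        }
        fs = [FSMethodSpec(FSKind.NONE), FSMethodSpec(FSKind.VT, variance_threshold=0.0)]
        clf = [ClassifierSpec("NB", "NB"), ClassifierSpec("DT", "DT"), ClassifierSpec("kNN", "kNN")]
        grid = run_grid(tables, fs, clf, seed=0)
        assert len(grid.cells) == 2 * 2 * 3

    def test_default_grid_dimensions(self):
        assert len(default_fs_specs()) * len(default_classifier_specs()) * 13 == 2184

    def test_rerun_is_identical(self):
        tables = {"SP20": make_table(n=40, k=6, informative=1)}
        fs = [FSMethodSpec(FSKind.LASSO, alpha=0.5)]
        clf = [ClassifierSpec("RF", "RF")]
        a = run_grid(tables, fs, clf, seed=3)
        b = run_grid(tables, fs, clf, seed=3)
        pd.testing.assert_frame_equal(a.to_dataframe(), b.to_dataframe())

    def test_empty_table_rejected_before_training(self):
        empty = FeatureTable(
            pd.DataFrame(columns=["patient_id", "point_id", "roi", "label", "f0"])
        )
        with pytest.raises(ValueError, match="empty"):
            run_grid({"SP20": empty}, [FSMethodSpec(FSKind.NONE)], [ClassifierSpec("NB", "NB")])

    def test_twelve_classifiers(self):
        specs = default_classifier_specs()
        assert len(specs) == 12
        names = {s.name for s in specs}
        assert {"L-SVM", "SVM", "NB", "kNN", "QDA", "GPR", "DT", "RF",
                "Bagging", "AdaBoost", "NNet-SGD", "NNet-LBFGS"} == names
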