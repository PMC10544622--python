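"""Splitting, SMOTE, tuning and the experiment grid."""

import numpy as np
import pytest

from mepkit.learning import (
    Algorithm,
    DEFAULT_GRIDS,
    ModelSpec,
    Paradigm,
    Representation,
    TrainTestSplit,
    raw_split,
    run_experiment,
    smote_balance,
    split_by_patient,
    train_and_predict,
    tune_hyperparameters,
)


class TestSplitByPatient:
    def test_default_28_8_split_on_36_patients(self, small_preselected):
        # synthesize 36 patient ids by re-labelling the small cohort
        traces = small_preselected
        patients = sorted({t.patient_id for t in traces})
        split = split_by_patient(traces, n_train=len(patients) - 2, n_test=2, seed=1)
        assert len(split.train_patients) == len(patients) - 2
        assert len(split.test_patients) == 2
        assert set(split.train_patients).isdisjoint(split.test_patients)

    def test_same_seed_same_assignment(self, small_preselected):
        a = split_by_patient(small_preselected, 4, 2, seed=7)
        b = split_by_patient(small_preselected, 4, 2, seed=7)
        assert a == b
        c = split_by_patient(small_preselected, 4, 2, seed=8)
        assert a != c  # almost surely

    def test_inconsistent_counts_raise(self, small_preselected):
        with pytest.raises(ValueError):
            split_by_patient(small_preselected, 28, 8, seed=0)

    def test_raw_split_is_patient_disjoint(self, small_preselected):
        assignment = split_by_patient(small_preselected, 4, 2, seed=3)
        split = raw_split(small_preselected, assignment)
        assert set(split.patients_train).isdisjoint(split.patients_test)
        assert split.X_train.shape[1] == 1650
        assert len(split.X_train) + len(split.X_test) == len(small_preselected)


class TestSmote:
    def test_already_balanced_input_is_returned_unchanged(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 3))
        y = np.repeat(["a", "b"], 10)
        Xb, yb = smote_balance(X, y, seed=1)
        assert np.array_equal(Xb, X)
        assert np.array_equal(yb, y)

    def test_two_point_minority_interpolates_on_the_diagonal(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0],
                      [5.0, 5.0], [6.0, 5.0], [5.0, 6.0]])
        y = np.array(["min", "min", "maj", "maj", "maj"])
        Xb, yb = smote_balance(X, y, k_neighbors=1, seed=2)
        synth = Xb[5:]
        assert len(synth) == 1
        (t1, t2) = synth[0]
        assert t1 == pytest.approx(t2)
        assert 0.0 <= t1 <= 1.0

    def test_counts_are_equalized_to_the_majority(self):
        rng = np.random.default_rng(3)
        X = np.vstack([rng.normal(0, 1, (100, 4)), rng.normal(5, 1, (40, 4))])
        y = np.array(["maj"] * 100 + ["min"] * 40)
        Xb, yb = smote_balance(X, y, seed=4)
        _, counts = np.unique(yb, return_counts=True)
        assert counts.tolist() == [100, 100]
        # originals preserved as the leading rows
        assert np.array_equal(Xb[:140], X)

    def test_singleton_class_error_names_the_class(self):
        X = np.zeros((3, 2))
        y = np.array(["a", "a", "lonely"])
        with pytest.raises(ValueError, match="lonely"):
            smote_balance(X, y)

    def test_synthetic_rows_are_exact_convex_combinations(self):
        rng = np.random.default_rng(5)
        X = np.vstack([rng.normal(0, 1, (30, 5)), rng.normal(3, 1, (12, 5))])
        y = np.array(["A"] * 30 + ["B"] * 12)
        Xb, yb = smote_balance(X, y, seed=6)
        Xmin = X[y == "B"]
        for row in Xb[42:]:
            on_segment = False
            for i in range(len(Xmin)):
                for j in range(len(Xmin)):
                    if i == j:
                        continue
                    d = Xmin[j] - Xmin[i]
                    v = row - Xmin[i]
                    denom = float(d @ d)
                    u = float(v @ d) / denom
                    if 0.0 <= u <= 1.0 and np.allclose(v, u * d, atol=1e-9):
                        on_segment = True
                        break
                if on_segment:
                    break
            assert on_segment

    def test_invalid_k_raises(self):
        X = np.zeros((4, 2))
        y = np.array(["a", "a", "b", "b"])
        with pytest.raises(ValueError):
            smote_balance(X, y, k_neighbors=0)


def _clustered_data(n=15, seed=0):
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(0, 0.3, (n, 2)), rng.normal(4, 0.3, (n, 2))])
    y = np.array(["a"] * n + ["b"] * n)
    return X, y


class TestTuning:
    def test_single_point_grid_is_selected(self):
        X, y = _clustered_data()
        spec = ModelSpec(Algorithm.KNN, grid={"n_neighbors": [3]}, cv_folds=3)
        tuned = tune_hyperparameters(spec, X, y)
        assert tuned.tuned == {"n_neighbors": 3}

    def test_knn_prefers_small_k_on_tightly_clustered_data(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(0, 0.3, (25, 2)), rng.normal(4, 0.3, (15, 2))])
        y = np.array(["a"] * 25 + ["b"] * 15)
        spec = ModelSpec(Algorithm.KNN, grid={"n_neighbors": [1, 31]}, cv_folds=5)
        tuned = tune_hyperparameters(spec, X, y)
        # k=31 spans both clusters, so the minority cluster is outvoted;
        # k=1 separates them perfectly
        assert tuned.tuned["n_neighbors"] == 1

    def test_tuned_values_are_grid_members(self):
        X, y = _clustered_data(seed=2)
        spec = ModelSpec(Algorithm.RF,
                         grid={"n_estimators": [10, 20], "max_depth": [None, 3]},
                         cv_folds=3, seed=0)
        tuned = tune_hyperparameters(spec, X, y)
        for key, value in tuned.tuned.items():
            assert value in spec.grid[key]

    def test_degenerate_grid_raises(self):
        X, y = _clustered_data()
        spec = ModelSpec(Algorithm.KNN, grid={"n_neighbors": []}, cv_folds=3)
        with pytest.raises(ValueError):
            tune_hyperparameters(spec, X, y)


class TestTrainAndPredict:
    def _split(self, X_train, y_train, X_test, y_test):
        return TrainTestSplit(
            X_train=X_train, y_train=np.asarray(y_train),
            patients_train=np.zeros(len(X_train)),
            X_test=X_test, y_test=np.asarray(y_test),
            patients_test=np.ones(len(X_test)),
            representation=Representation.FE, seed=0)

    def test_single_class_training_predicts_that_class(self):
        rng = np.random.default_rng(0)
        split = self._split(rng.normal(size=(10, 3)), ["only"] * 10,
                            rng.normal(size=(5, 3)), ["only"] * 5)
        spec = ModelSpec(Algorithm.KNN, tuned={"n_neighbors": 1})
        preds = train_and_predict(spec, split)
        assert all(p == "only" for p in preds.y_pred)
        assert np.allclose(preds.scores.sum(axis=1), 1.0)

    def test_knn_identity_on_a_memorized_point(self):
        X, y = _clustered_data(seed=3)
        split = self._split(X, y, X[[0, -1]], y[[0, -1]])
        spec = ModelSpec(Algorithm.KNN, tuned={"n_neighbors": 1})
        preds = train_and_predict(spec, split)
        assert preds.y_pred.tolist() == [y[0], y[-1]]

    def test_dimension_mismatch_raises(self):
        rng = np.random.default_rng(1)
        split = self._split(rng.normal(size=(8, 3)), ["a"] * 4 + ["b"] * 4,
                            rng.normal(size=(2, 5)), ["a", "b"])
        with pytest.raises(ValueError):
            train_and_predict(ModelSpec(Algorithm.RF, tuned={}), split)

    def test_probability_rows_sum_to_one(self):
        X, y = _clustered_data(seed=4)
        split = self._split(X, y, X[:6], y[:6])
        for algo in Algorithm:
            spec = ModelSpec(algo, tuned={})
            preds = train_and_predict(spec, split)
            assert np.allclose(preds.scores.sum(axis=1), 1.0)


TINY_GRIDS = {Algorithm.RF: {"n_estimators": [25]},
              Algorithm.KNN: {"n_neighbors": [1, 3]},
              Algorithm.LOGREG: {"C": [1.0]}}


@pytest.fixture(scope="module")
def toy_reports(small_preselected):
    return run_experiment(small_preselected, seed=2, n_train=4, n_test=2,
                          cv_folds=3, grids=TINY_GRIDS)


class TestRunExperiment:
    def test_grid_has_27_cells(self, toy_reports):
        assert len(toy_reports) == 27
        assert {k[0] for k in toy_reports} == {a.value for a in Algorithm}
        assert {k[1] for k in toy_reports} == {p.value for p in Paradigm}
        assert {k[2] for k in toy_reports} == {r.value for r in Representation}

    def test_two_class_cells_contain_only_their_muscles(self, toy_reports):
        cell = toy_reports[("RF", "EXT_VS_APB", "FE")]
        assert set(cell.class_order) == {"EXT", "APB"}
        cell = toy_reports[("KNN", "EXT_VS_TA", "RAW")]
        assert set(cell.class_order) == {"EXT", "TA"}

    def test_raw_cells_have_dimension_1650(self, toy_reports):
        for (algo, paradigm, rep), r in toy_reports.items():
            if rep == "RAW":
                assert r.dimension == 1650
            elif rep == "FE":
                assert r.dimension == 7

    def test_tuned_parameters_are_recorded(self, toy_reports):
        for r in toy_reports.values():
            assert r.tuned_params is not None

    def test_determinism_of_a_cell(self, small_preselected):
        a = run_experiment(small_preselected, paradigms=[Paradigm.EXT_VS_TA],
                           representations=[Representation.FE],
                           algorithms=[Algorithm.RF], seed=5, n_train=4,
                           n_test=2, cv_folds=3, grids=TINY_GRIDS)
        b = run_experiment(small_preselected, paradigms=[Paradigm.EXT_VS_TA],
                           representations=[Representation.FE],
                           algorithms=[Algorithm.RF], seed=5, n_train=4,
                           n_test=2, cv_folds=3, grids=TINY_GRIDS)
        ra = a[("RF", "EXT_VS_TA", "FE")]
        rb = b[("RF", "EXT_VS_TA", "FE")]
        assert ra.accuracy == rb.accuracy
        assert np.array_equal(ra.confusion, rb.confusion)


class TestLeakageFreedom:
    def test_pca_mean_comes_from_training_rows_only(self, small_preselected):
        from mepkit.features import fit_pca

        assignment = split_by_patient(small_preselected, 4, 2, seed=9)
        split = raw_split(small_preselected, assignment)
        model = fit_pca(split.X_train)
        assert np.allclose(model.mean, split.X_train.mean(axis=0))
        assert not np.allclose(model.mean,
                               np.vstack([split.X_train, split.X_test]).mean(axis=0))

    def test_smote_rows_stay_inside_the_training_class_hull(self, small_preselected):
        assignment = split_by_patient(small_preselected, 4, 2, seed=9)
        split = raw_split(small_preselected, assignment)
        Xb, yb = smote_balance(split.X_train, split.y_train, seed=9)
        n_orig = len(split.X_train)
        for cls in np.unique(yb):
            cls_rows = Xb[n_orig:][yb[n_orig:] == cls]
            train_cls = split.X_train[split.y_train == cls]
            lo, hi = train_cls.min(axis=0), train_cls.max(axis=0)
            if len(cls_rows):
                assert np.all(cls_rows >= lo - 1e-9)
                assert np.all(cls_rows <= hi + 1e-9)
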