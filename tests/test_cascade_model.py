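"""Cascade training and prediction: determinism, error collection as an
out-of-fold partition, the 1:1 error set, the rescue-union rule, and model
archive round-trips."""

import numpy as np
import pytest

import promcascade as pc
from promcascade.cascade_model import balance_error_sets
from conftest import FixedClassifier


@pytest.fixture(scope="module")
def tiny():
    """Cheap separable dataset for training-contract tests."""
    cfg = pc.SyntheticConfig(n_per_class=120, seed=3, mutation_rate=0.0)
    ds, _ = pc.generate(cfg)
    X, y, ids = ds.encode()
    return X, y, ids


class TestTrainStage1:
    def test_default_hyperparameters_are_tuned_config(self, tiny):
        X, y, _ = tiny
        clf = pc.train_stage1(X, y, rng_seed=0)
        assert clf.n_estimators == 200
        assert clf.learning_rate == 0.2
        assert clf.max_depth == 7

    def test_same_seed_identical_predictions(self, tiny):
        X, y, _ = tiny
        a = pc.train_stage1(X, y, rng_seed=5).predict_proba(X)
        b = pc.train_stage1(X, y, rng_seed=5).predict_proba(X)
        assert np.array_equal(a, b)

    def test_single_class_rejected(self, tiny):
        X, y, _ = tiny
        with pytest.raises(pc.DataError):
            pc.train_stage1(X[y == 1], y[y == 1], rng_seed=0)


class TestGridSearch:
    SMALL_GRID = {
        "n_estimators": [10, 20, 30],
        "learning_rate": [0.01, 0.1, 0.2],
        "max_depth": [3, 5, 7],
    }

    def test_full_grid_evaluates_every_combination(self, tiny):
        X, y, _ = tiny
        best, table = pc.grid_search_stage1(X, y, grid=self.SMALL_GRID, rng_seed=0, cv=3)
        assert len(table) == 27
        assert set(best) == {"n_estimators", "learning_rate", "max_depth"}
        assert table["mean_cv_accuracy"].max() == pytest.approx(
            table.set_index(["n_estimators", "learning_rate", "max_depth"])
            .loc[(best["n_estimators"], best["learning_rate"], best["max_depth"]),
                 "mean_cv_accuracy"]
        )

    def test_single_configuration_returned(self, tiny):
        X, y, _ = tiny
        grid = {"n_estimators": [25], "learning_rate": [0.1], "max_depth": [4]}
        best, table = pc.grid_search_stage1(X, y, grid=grid, rng_seed=0, cv=3)
        assert best == {"n_estimators": 25, "learning_rate": 0.1, "max_depth": 4}
        assert len(table) == 1

    def test_tie_break_prefers_simplest(self, tiny):
        # mutation-free data is perfectly separable, so every config scores
        # 1.0 and the tie-break must pick the simplest model
        X, y, _ = tiny
        best, table = pc.grid_search_stage1(X, y, grid=self.SMALL_GRID, rng_seed=0, cv=3)
        top = table["mean_cv_accuracy"].max()
        tied = table[table["mean_cv_accuracy"] == top]
        if len(tied) > 1:
            assert best["n_estimators"] == tied["n_estimators"].min()


class TestCollectErrors:
    def test_partition_law(self, weak_split):
        X, y = weak_split["Xtr"], weak_split["ytr"]
        errors = pc.collect_errors(X, y, rng_seed=4)
        n_correct = int((errors.oof_labels == y).sum())
        assert errors.n_fp + errors.n_fn + n_correct == len(y)
        assert (errors.oof_labels >= 0).all()  # every record predicted once

    def test_error_sets_match_definitions(self, weak_split):
        X, y = weak_split["Xtr"], weak_split["ytr"]
        errors = pc.collect_errors(X, y, rng_seed=4)
        assert np.all(y[errors.fp_indices] == 0)
        assert np.all(y[errors.fn_indices] == 1)
        assert np.all(errors.oof_labels[errors.fp_indices] == 1)
        assert np.all(errors.oof_labels[errors.fn_indices] == 0)

    def test_perfect_separation_no_errors(self, rng):
        # wide-margin data: out-of-fold prediction cannot err
        X = rng.normal(size=(200, 59))
        y = np.repeat([0, 1], 100)
        X[:, 0] = np.where(y == 1, 5.0, -5.0)
        errors = pc.collect_errors(X, y, rng_seed=4)
        assert errors.n_fp == 0 and errors.n_fn == 0


class TestTrainStage2:
    def test_min_size_downsampling(self, rng):
        X_fp = rng.normal(size=(10, 59))
        X_fn = rng.normal(size=(25, 59))
        X2, y2 = balance_error_sets(X_fp, X_fn, np.random.default_rng(1))
        assert len(X2) == 20
        assert (y2 == 0).sum() == 10 and (y2 == 1).sum() == 10
        # FPs (all kept, smaller set) come first with label 0
        assert np.array_equal(X2[:10], X_fp)

    def test_empty_error_set_degenerates(self, rng):
        assert pc.train_stage2(np.empty((0, 59)), rng.normal(size=(5, 59))) is None
        assert pc.train_stage2(rng.normal(size=(5, 59)), np.empty((0, 59))) is None

    def test_trains_on_both_sets(self, weak_split):
        X, y = weak_split["Xtr"], weak_split["ytr"]
        errors = pc.collect_errors(X, y, rng_seed=4)
        clf = pc.train_stage2(X[errors.fp_indices], X[errors.fn_indices], rng_seed=4)
        assert clf is not None
        assert clf.n_features_in_ == 59


class TestPredictRule:
    def _cascade(self, p1, p2):
        return pc.CascadeModel(
            stage1=FixedClassifier(p1, n_features=2),
            stage2=FixedClassifier(p2, n_features=2),
            table=pc.default_table(),
        )

    def test_truth_table(self):
        """final = stage1 OR stage2, stage 2 consulted only on stage-1 negatives."""
        X = np.array([[0.0, 0], [1.0, 0], [2.0, 0], [3.0, 0]])
        stage1 = FixedClassifier({0.0: 0.9, 1.0: 0.8, 2.0: 0.1, 3.0: 0.2}, n_features=2)
        stage2 = FixedClassifier({2.0: 0.9, 3.0: 0.1}, n_features=2)
        model = pc.CascadeModel(stage1=stage1, stage2=stage2, table=pc.default_table())
        recs = model.predict(X, ids=list("abcd"))
        # stage1 positive -> final positive, stage2 untouched
        assert recs[0].final_label == 1 and recs[0].stage2_label is None
        assert recs[1].final_label == 1
        # stage1 negative, stage2 positive -> rescued
        assert recs[2].stage1_label == 0 and recs[2].stage2_label == 1
        assert recs[2].final_label == 1
        # both negative -> negative
        assert recs[3].final_label == 0 and recs[3].stage2_label == 0

    def test_absent_stage2(self):
        X = np.array([[0.0, 0], [1.0, 0]])
        stage1 = FixedClassifier({0.0: 0.9, 1.0: 0.1}, n_features=2)
        model = pc.CascadeModel(stage1=stage1, stage2=None, table=pc.default_table())
        recs = model.predict(X)
        assert [r.final_label for r in recs] == [1, 0]
        assert all(r.stage2_score is None for r in recs)

    def test_feature_width_mismatch(self, clean_model):
        model, _ = clean_model
        with pytest.raises(pc.ShapeError):
            model.predict(np.zeros((3, 10)))

    def test_recall_and_specificity_monotonicity(self, weak_model, weak_split):
        """The union rule can only add positives: recall never drops,
        specificity never rises, relative to stage 1."""
        model, _ = weak_model
        recs = model.predict(weak_split["Xte"], weak_split["idte"])
        y = weak_split["yte"]
        s1 = np.array([r.stage1_label for r in recs])
        fin = np.array([r.final_label for r in recs])
        m1 = pc.compute_metrics(pc.ConfusionCounts.from_labels(y, s1))
        mf = pc.compute_metrics(pc.ConfusionCounts.from_labels(y, fin))
        assert mf.recall >= m1.recall
        assert mf.specificity <= m1.specificity


class TestFitCascadeAndArchive:
    def test_manifest_records_provenance(self, clean_model):
        model, errors = clean_model
        m = model.manifest
        assert m["stage1_params"] == pc.DEFAULT_STAGE1_PARAMS
        assert m["n_fp"] == errors.n_fp and m["n_fn"] == errors.n_fn
        assert m["error_fold_scheme"] == {"n_folds": 10, "stratified": True}
        assert m["table_checksum"] == pc.default_table().checksum()

    def test_end_to_end_determinism(self, weak_split):
        # balanced 400-record slice (the training block is ordered by label)
        ytr = weak_split["ytr"]
        idx = np.r_[np.flatnonzero(ytr == 1)[:200], np.flatnonzero(ytr == 0)[:200]]
        X, y = weak_split["Xtr"][idx], ytr[idx]
        a, _ = pc.fit_cascade(X, y, rng_seed=12, n_folds=5)
        b, _ = pc.fit_cascade(X, y, rng_seed=12, n_folds=5)
        probe = weak_split["Xte"][:50]
        ra = [(r.stage1_score, r.final_label) for r in a.predict(probe)]
        rb = [(r.stage1_score, r.final_label) for r in b.predict(probe)]
        assert ra == rb

    def test_save_load_roundtrip(self, clean_model, clean_split, tmp_path):
        model, _ = clean_model
        path = tmp_path / "model.pcm"
        pc.save_model(model, path)
        loaded = pc.load_model(path)
        probe = clean_split["Xte"][:40]
        before = [(r.stage1_score, r.stage2_score, r.final_label) for r in model.predict(probe)]
        after = [(r.stage1_score, r.stage2_score, r.final_label) for r in loaded.predict(probe)]
        assert before == after
        assert loaded.manifest == model.manifest

    def test_tampered_table_checksum(self, clean_model, tmp_path):
        import joblib

        model, _ = clean_model
        path = tmp_path / "model.pcm"
        pc.save_model(model, path)
        payload = joblib.load(path)
        payload["table"]["values"]["AA"] += 0.5
        joblib.dump(payload, path)
        with pytest.raises(pc.VersionError):
            pc.load_model(path)

    def test_wrong_version(self, clean_model, tmp_path):
        import joblib

        model, _ = clean_model
        path = tmp_path / "model.pcm"
        pc.save_model(model, path)
        payload = joblib.load(path)
        payload["format_version"] = 999
        joblib.dump(payload, path)
        with pytest.raises(pc.VersionError):
            pc.load_model(path)

    def test_missing_file_mentions_path(self, tmp_path):
        with pytest.raises(FileNotFoundError, match="nowhere.pcm"):
            pc.load_model(tmp_path / "nowhere.pcm")
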