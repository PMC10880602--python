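"""Metric identities against brute-force counting, the six-family comparison,
stratified CV internals, and the external-validation protocol."""

import numpy as np
import pytest

import promcascade as pc
from promcascade.evaluation import make_stage1_factory
from conftest import FixedClassifier, random_acgt


def brute_force_metrics(y_true, y_pred):
    """Pair-by-pair counting oracle, independent of ConfusionCounts."""
    tp = sum(1 for t, p in zip(y_true, y_pred) if t == 1 and p == 1)
    fp = sum(1 for t, p in zip(y_true, y_pred) if t == 0 and p == 1)
    tn = sum(1 for t, p in zip(y_true, y_pred) if t == 0 and p == 0)
    fn = sum(1 for t, p in zip(y_true, y_pred) if t == 1 and p == 0)
    out = {}
    out["accuracy"] = (tp + tn) / len(y_true) if len(y_true) else None
    out["precision"] = tp / (tp + fp) if (tp + fp) else None
    out["recall"] = tp / (tp + fn) if (tp + fn) else None
    out["specificity"] = tn / (tn + fp) if (tn + fp) else None
    if out["precision"] and out["recall"]:
        out["f1"] = 2 * out["precision"] * out["recall"] / (out["precision"] + out["recall"])
    else:
        out["f1"] = None
    return out


class TestComputeMetrics:
    def test_balanced_example(self):
        m = pc.compute_metrics(pc.ConfusionCounts(tp=8, fp=2, tn=8, fn=2))
        assert m.accuracy == pytest.approx(0.8)
        assert m.precision == pytest.approx(0.8)
        assert m.recall == pytest.approx(0.8)
        assert m.specificity == pytest.approx(0.8)
        assert m.f1 == pytest.approx(0.8)

    def test_recall_on_positives_only(self):
        # an all-positive validation set has no negatives: recall defined,
        # specificity undefined
        m = pc.compute_metrics(pc.ConfusionCounts(tp=2316, fp=0, tn=0, fn=1545))
        assert m.recall == pytest.approx(2316 / 3861)
        assert m.specificity is None

    def test_zero_denominators_undefined(self):
        m = pc.compute_metrics(pc.ConfusionCounts(tp=0, fp=0, tn=5, fn=5))
        assert m.precision is None
        assert m.accuracy == pytest.approx(0.5)

    def test_agrees_with_brute_force_on_random_configurations(self, rng):
        for _ in range(1000):
            n = int(rng.integers(1, 40))
            y_true = rng.integers(0, 2, size=n)
            y_pred = rng.integers(0, 2, size=n)
            m = pc.compute_metrics(pc.ConfusionCounts.from_labels(y_true, y_pred))
            expected = brute_force_metrics(y_true.tolist(), y_pred.tolist())
            for key, val in expected.items():
                got = getattr(m, key)
                if val is None:
                    assert got is None, key
                else:
                    assert got == pytest.approx(val), key

    def test_auc_perfect_and_random(self, rng):
        y = np.array([0, 1] * 1000)
        perfect = pc.compute_metrics(
            pc.ConfusionCounts.from_labels(y, y), scores=y.astype(float), y_true=y
        )
        assert perfect.auc == pytest.approx(1.0)
        noise = rng.random(2000)
        rand = pc.compute_metrics(
            pc.ConfusionCounts.from_labels(y, (noise > 0.5).astype(int)),
            scores=noise, y_true=y,
        )
        assert rand.auc == pytest.approx(0.5, abs=0.05)


@pytest.fixture(scope="module")
def split():
    cfg = pc.SyntheticConfig(n_per_class=150, seed=9, mutation_rate=0.1)
    ds, _ = pc.generate(cfg)
    train, test = pc.split_train_test(ds, 0.2, rng_seed=2)
    Xtr, ytr, _ = train.encode()
    Xte, yte, _ = test.encode()
    return Xtr, ytr, Xte, yte


class TestCompareAlgorithms:
    def test_six_families_reported(self, split):
        table, best = pc.compare_algorithms(*split, rng_seed=1)
        assert list(table["algorithm"]) == list(pc.ALGORITHM_NAMES)
        assert len(table) == 6
        assert set(table.columns) == {"algorithm", "accuracy", "precision", "recall", "f1"}
        assert best in pc.ALGORITHM_NAMES
        assert table["accuracy"].max() == table.loc[table["algorithm"] == best, "accuracy"].item()

    def test_determinism(self, split):
        a, _ = pc.compare_algorithms(*split, rng_seed=1)
        b, _ = pc.compare_algorithms(*split, rng_seed=1)
        assert a.equals(b)

    def test_unknown_algorithm(self, split):
        with pytest.raises(pc.ConfigError):
            pc.compare_algorithms(*split, algorithms=["Perceptron"], rng_seed=1)


class TestCrossValidate:
    def test_fold_metrics_and_mean_consistency(self, clean_split):
        y_all = np.concatenate([clean_split["ytr"], clean_split["yte"]])
        X_all = np.vstack([clean_split["Xtr"], clean_split["Xte"]])
        idx = np.r_[np.flatnonzero(y_all == 1)[:500], np.flatnonzero(y_all == 0)[:500]]
        X, y = X_all[idx], y_all[idx]
        report = pc.cross_validate(make_stage1_factory(), X, y, k=10, rng_seed=6)
        assert len(report.per_fold) == 10
        assert len(report.roc_curves) == 10
        for metric in ("accuracy", "precision", "recall", "specificity", "auc"):
            vals = [getattr(f, metric) for f in report.per_fold]
            assert getattr(report, metric) == pytest.approx(np.mean(vals))
            mean, sd = report.mean_sd[metric]
            assert mean == pytest.approx(np.mean(vals))
            assert sd == pytest.approx(np.std(vals, ddof=1))

    def test_k_too_small(self, clean_split):
        with pytest.raises(ValueError):
            pc.cross_validate(make_stage1_factory(), clean_split["Xtr"],
                              clean_split["ytr"], k=1, rng_seed=0)

    def test_single_class_data_rejected(self, clean_split):
        X, y = clean_split["Xtr"][:100], np.ones(100, dtype=int)
        with pytest.raises((pc.DataError, ValueError)):
            pc.cross_validate(make_stage1_factory(), X, y, k=5, rng_seed=0)


class TestValidateExternal:
    def test_accounting_identity(self, clean_model, rng):
        model, _ = clean_model
        seqs = [(f"p{i}", random_acgt(rng, 60)) for i in range(50)]
        res = pc.validate_external(model, seqs)
        assert res.total == res.stage1_hits + res.stage2_rescues
        assert res.n_encoded == 50 and res.n_skipped == 0
        assert 0.0 <= res.fraction <= 1.0

    def test_long_sequences_trimmed_short_skipped(self, clean_model, rng):
        model, _ = clean_model
        seqs = [("long", random_acgt(rng, 90)), ("short", random_acgt(rng, 59))]
        res = pc.validate_external(model, seqs)
        assert res.n_skipped == 1 and res.n_encoded == 1

    def test_known_positives_mostly_recovered(self, clean_model, clean_synth, clean_split):
        """Held-out planted promoters are the analogue of an external set of
        verified promoters; the cascade should recover the large majority."""
        model, _ = clean_model
        _, ds, _ = clean_synth
        seq_of = {r.id: r.sequence for r in ds.records}
        pos = [(i, seq_of[i]) for i, lab in zip(clean_split["idte"], clean_split["yte"])
               if lab == 1]
        res = pc.validate_external(model, pos)
        assert res.n_encoded == len(pos)
        assert res.fraction > 0.8

    def test_absent_stage2_no_rescues(self, clean_model, rng):
        model, _ = clean_model
        solo = pc.CascadeModel(stage1=model.stage1, stage2=None, table=model.table)
        seqs = [(f"p{i}", random_acgt(rng, 60)) for i in range(30)]
        res = pc.validate_external(solo, seqs)
        assert res.stage2_rescues == 0
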