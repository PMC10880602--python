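"""Shared fixtures: synthetic benchmarks and trained cascades.

Expensive objects (encoded datasets, fitted models) are session-scoped so the
suite trains each configuration once.  All randomness is seeded.
"""

from __future__ import annotations

import numpy as np
import pytest

import promcascade as pc


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240221)


def random_acgt(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


@pytest.fixture(scope="session")
def clean_synth():
    """Strong-signal benchmark: 2000/class, motif mutation rate 0.10."""
    cfg = pc.SyntheticConfig(n_per_class=2000, seed=7, mutation_rate=0.10)
    ds, manifest = pc.generate(cfg)
    return cfg, ds, manifest


@pytest.fixture(scope="session")
def clean_split(clean_synth):
    _, ds, _ = clean_synth
    train, test = pc.split_train_test(ds, 0.2, rng_seed=11)
    Xtr, ytr, idtr = train.encode()
    Xte, yte, idte = test.encode()
    return {"Xtr": Xtr, "ytr": ytr, "idtr": idtr, "Xte": Xte, "yte": yte, "idte": idte}


@pytest.fixture(scope="session")
def clean_model(clean_split):
    model, errors = pc.fit_cascade(clean_split["Xtr"], clean_split["ytr"], rng_seed=3)
    return model, errors


@pytest.fixture(scope="session")
def weak_synth():
    """Benchmark with a 30% weak-promoter subpopulation (elevated motif
    mutation rate), the regime the cascade's rescue path targets."""
    cfg = pc.SyntheticConfig(
        n_per_class=2000, seed=7, mutation_rate=0.15,
        weak_fraction=0.3, weak_mutation_rate=0.45,
    )
    ds, manifest = pc.generate(cfg)
    return cfg, ds, manifest


@pytest.fixture(scope="session")
def weak_split(weak_synth):
    _, ds, _ = weak_synth
    train, test = pc.split_train_test(ds, 0.2, rng_seed=11)
    Xtr, ytr, idtr = train.encode()
    Xte, yte, idte = test.encode()
    return {"Xtr": Xtr, "ytr": ytr, "idtr": idtr, "Xte": Xte, "yte": yte, "idte": idte}


@pytest.fixture(scope="session")
def weak_model(weak_split):
    model, errors = pc.fit_cascade(weak_split["Xtr"], weak_split["ytr"], rng_seed=3)
    return model, errors


@pytest.fixture(scope="session")
def small_dataset():
    """Cheap dataset for plumbing tests (I/O, CLI, shapes)."""
    cfg = pc.SyntheticConfig(n_per_class=150, seed=42, mutation_rate=0.10)
    ds, _ = pc.generate(cfg)
    return ds


class FixedClassifier:
    """predict_proba stub returning preset positive-class probabilities by
    row index; lets cascade logic be tested without training."""

    def __init__(self, probs, n_features=59):
        self._probs = dict(probs) if isinstance(probs, dict) else None
        self._default = None if isinstance(probs, dict) else float(probs)
        self.n_features_in_ = n_features
        self._calls = 0

    def predict_proba(self, X):
        self._calls += 1
        import numpy as np

        n = len(X)
        if self._probs is None:
            p1 = np.full(n, self._default)
        else:
            # keyed by the row's first feature value (set by the test)
            p1 = np.array([self._probs[float(row[0])] for row in X])
        return np.column_stack([1 - p1, p1])
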