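from __future__ import annotations

import itertools

import numpy as np
import pytest

from ecgcascade import classifiers
from ecgcascade.types import WINDOW_SAMPLES, BeatDataset


def make_dataset(windows, labels, split="train", label_space=("N", "S", "V", "F", "Q")):
    n = len(labels)
    return BeatDataset(
        windows=np.asarray(windows, float),
        labels=np.asarray(labels, dtype=object),
        record_ids_per_beat=np.array([f"r{i % 3}" for i in range(n)], dtype=object),
        r_peak_indices=np.arange(n) * 300 + 108,
        original_symbols=np.array(["N"] * n, dtype=object),
        split=split,
        label_space=label_space,
    )


def separable_dataset(n_per_class=30, seed=0):
    """Two classes in disjoint value ranges: trivially separable."""
    rng = np.random.default_rng(seed)
    low = rng.uniform(0.0, 0.3, size=(n_per_class, WINDOW_SAMPLES))
    high = rng.uniform(0.7, 1.0, size=(n_per_class, WINDOW_SAMPLES))
    windows = np.vstack([low, high])
    labels = ["N"] * n_per_class + ["V"] * n_per_class
    return make_dataset(windows, labels)


class StubModel:
    """Fixed-output stand-in for a fitted forest."""

    def __init__(self, label, label_space):
        self.label = label
        self.label_space = tuple(label_space)
        self.calls = 0

    def predict(self, windows):
        windows = np.atleast_2d(windows)
        self.calls += 1
        return np.array([self.label] * len(windows), dtype=object)


class TestTrainForest:
    def test_separable_classes_fit_perfectly(self):
        ds = separable_dataset()
        model = classifiers.train_forest(ds, n_trees=30, candidate_count=2, seed=0)
        assert list(classifiers.predict(model, ds)) == list(ds.labels)

    def test_same_seed_reproduces_predictions(self):
        ds = separable_dataset()
        rng = np.random.default_rng(9)
        probe = rng.uniform(0, 1, size=(20, WINDOW_SAMPLES))
        m1 = classifiers.train_forest(ds, n_trees=30, candidate_count=3, seed=5)
        m2 = classifiers.train_forest(ds, n_trees=30, candidate_count=3, seed=5)
        assert np.array_equal(m1.predict(probe), m2.predict(probe))

    def test_training_beats_memorized(self):
        rng = np.random.default_rng(3)
        windows = rng.uniform(0, 1, size=(60, WINDOW_SAMPLES))
        labels = list(rng.choice(["N", "S", "V"], size=60))
        ds = make_dataset(windows, labels)
        model = classifiers.train_forest(ds, n_trees=120, candidate_count=1, seed=0)
        agreement = np.mean(classifiers.predict(model, ds) == np.asarray(labels, object))
        assert agreement > 0.9  # fully grown bagged trees memorize their sample

    def test_single_class_rejected(self):
        ds = make_dataset(np.random.default_rng(0).uniform(0, 1, (10, WINDOW_SAMPLES)),
                          ["N"] * 10)
        with pytest.raises(ValueError, match="2 classes"):
            classifiers.train_forest(ds, n_trees=10)

    def test_empty_dataset_rejected(self):
        ds = make_dataset(np.empty((0, WINDOW_SAMPLES)), [])
        with pytest.raises(ValueError, match="empty"):
            classifiers.train_forest(ds, n_trees=10)


class TestPredict:
    def test_empty_input_gives_empty_output(self):
        ds = separable_dataset()
        model = classifiers.train_forest(ds, n_trees=10, candidate_count=1, seed=0)
        assert len(model.predict(np.empty((0, WINDOW_SAMPLES)))) == 0

    def test_unfitted_model_rejected(self):
        model = classifiers.ForestModel(
            n_trees=10, label_space=("N", "V"), seed=0, candidate_count=1
        )
        with pytest.raises(RuntimeError, match="not fitted"):
            model.predict(np.zeros((1, WINDOW_SAMPLES)))

    def test_vote_tie_breaks_in_canonical_order(self):
        class TiedForest:
            classes_ = np.array(["V", "S"])  # deliberately unsorted

            def predict_proba(self, windows):
                return np.full((len(windows), 2), 0.5)

        model = classifiers.ForestModel(
            n_trees=2, label_space=("S", "V"), seed=0, candidate_count=1,
            forest=TiedForest(),
        )
        out = model.predict(np.zeros((3, WINDOW_SAMPLES)))
        assert list(out) == ["S", "S", "S"]  # S precedes V in N<S<V<F<Q


class TestComposite:
    def test_cascade_matches_hand_enumeration(self):
        """All 2x4 stub output combinations reproduce the cascade truth table."""
        windows = np.zeros((2, WINDOW_SAMPLES))
        for a_out, b_out in itertools.product(["N", "A"], ["S", "V", "F", "Q"]):
            model_a = StubModel(a_out, ("N", "A"))
            model_b = StubModel(b_out, ("S", "V", "F", "Q"))
            composite = classifiers.CompositeModel(model_a=model_a, model_b=model_b)
            out = classifiers.predict_composite(composite, windows)
            expected = "N" if a_out == "N" else b_out
            assert list(out) == [expected, expected]

    def test_subtype_model_not_invoked_for_normals(self):
        model_a = StubModel("N", ("N", "A"))
        model_b = StubModel("V", ("S", "V", "F", "Q"))
        composite = classifiers.CompositeModel(model_a=model_a, model_b=model_b)
        out = classifiers.predict_composite(composite, np.zeros((5, WINDOW_SAMPLES)))
        assert list(out) == ["N"] * 5
        assert model_b.calls == 0

    def test_wrong_label_spaces_rejected(self):
        with pytest.raises(ValueError, match="label space"):
            classifiers.CompositeModel(
                model_a=StubModel("N", ("N", "V")),
                model_b=StubModel("V", ("S", "V", "F", "Q")),
            )

    def test_perfect_oracle_submodels_give_perfect_composite(self):
        rng = np.random.default_rng(4)
        labels = np.array(rng.choice(["N", "S", "V", "F", "Q"], size=40), dtype=object)
        windows = rng.uniform(0, 1, size=(40, WINDOW_SAMPLES))
        lookup = {tuple(w): lab for w, lab in zip(windows, labels)}

        class OracleA:
            label_space = ("N", "A")

            def predict(self, ws):
                return np.array(
                    ["N" if lookup[tuple(w)] == "N" else "A" for w in np.atleast_2d(ws)],
                    dtype=object)

        class OracleB:
            label_space = ("S", "V", "F", "Q")

            def predict(self, ws):
                return np.array([lookup[tuple(w)] for w in np.atleast_2d(ws)], dtype=object)

        composite = classifiers.CompositeModel(model_a=OracleA(), model_b=OracleB())
        assert np.array_equal(classifiers.predict_composite(composite, windows), labels)


class TestSerialization:
    def test_forest_round_trip(self, tmp_path):
        ds = separable_dataset()
        model = classifiers.train_forest(ds, n_trees=15, candidate_count=1, seed=2)
        path = tmp_path / "model.joblib"
        classifiers.save_model(model, path)
        back = classifiers.load_model(path)
        assert back.n_trees == 15 and back.seed == 2
        probe = np.random.default_rng(0).uniform(0, 1, (10, WINDOW_SAMPLES))
        assert np.array_equal(back.predict(probe), model.predict(probe))
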