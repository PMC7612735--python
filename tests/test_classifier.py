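"""The SGD classifier: mini-batching, fitting, feature selection, prediction,
markers, model update and serialization."""

import numpy as np
import pytest

from sctyper.classifier import (
    UNASSIGNED,
    CellTypeClassifier,
    ClassifierModel,
    TrainingConfig,
    extract_markers,
    fit_round,
    load_model,
    make_minibatches,
    predict_probabilities,
    save_model,
    select_top_features,
    train_two_round,
    update_model,
)
from sctyper.data_model import LabelHierarchy, ValidationError
from sctyper.preprocessing import NormalizedMatrix


class TestMakeMinibatches:
    @pytest.mark.parametrize("n, bs, sizes", [(10, 5, [5, 5]), (10, 4, [4, 4, 2]), (3, 7, [3])])
    def test_partition_sizes(self, n, bs, sizes):
        batches = make_minibatches(n, bs, seed=0)
        assert [len(b) for b in batches] == sizes
        assert sorted(np.concatenate(batches)) == list(range(n))

    def test_seed_determinism(self):
        a = make_minibatches(50, 8, seed=4)
        b = make_minibatches(50, 8, seed=4)
        c = make_minibatches(50, 8, seed=5)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))
        assert any(not np.array_equal(x, y) for x, y in zip(a, c))

    def test_invalid_batch_size(self):
        with pytest.raises(ValidationError):
            make_minibatches(10, 0, seed=0)


def _two_class_instance():
    """40 cells, one perfectly separating gene (5 in class A, 0 in class B)."""
    X = np.zeros((40, 3))
    X[:20, 0] = 5.0
    X[:, 1] = 1.0  # uninformative
    y = np.array(["A"] * 20 + ["B"] * 20, dtype=object)
    return X, y


class TestFitting:
    def test_separable_two_class_accuracy(self):
        X, y = _two_class_instance()
        est = CellTypeClassifier(two_round=False, random_state=0)
        est.fit(X, y)
        assert (est.predict(X) == y).mean() == 1.0

    def test_single_class_rejected(self):
        X, _ = _two_class_instance()
        with pytest.raises(ValidationError, match="2 distinct"):
            CellTypeClassifier().fit(X, np.array(["A"] * 40))

    def test_nan_rejected(self):
        X, y = _two_class_instance()
        X[0, 0] = np.nan
        with pytest.raises(ValidationError, match="NaN"):
            CellTypeClassifier().fit(X, y)

    def test_huge_penalty_gives_near_uniform_probabilities(self):
        X, y = _two_class_instance()
        est = CellTypeClassifier(two_round=False, l2_strength=1e6, random_state=0)
        est.fit(X, y)
        proba = est.predict_proba(X)
        assert np.abs(proba - 0.5).max() < 0.05
        assert np.abs(est.coef_).max() < 1e-3

    def test_history_iterations_strictly_increasing(self, small_separable):
        config = TrainingConfig(seed=0, epochs=3, batch_size=16, n_top_genes=10)
        _, history = train_two_round(small_separable["X"], small_separable["labels"], config)
        its = [r["iteration"] for r in history.records]
        assert all(b > a for a, b in zip(its, its[1:]))
        assert {r["round"] for r in history.records} == {1, 2}

    def test_labels_all_checked(self, small_separable):
        with pytest.raises(ValidationError, match="one label per cell"):
            fit_round(small_separable["X"], ["A"], TrainingConfig(seed=0))


class TestFeatureSelection:
    def _model(self):
        return ClassifierModel(
            class_names=["A", "B"],
            feature_genes=["g1", "g2", "g3", "g4"],
            weights=np.array([[3.0, 1.0, -2.0, 0.0], [0.0, 2.0, 5.0, 1.0]]),
            intercepts=np.zeros(2),
        )

    def test_union_in_gene_order(self):
        assert select_top_features(self._model(), 2) == ["g1", "g2", "g3"]

    def test_n_top_at_least_gene_count(self):
        assert select_top_features(self._model(), 10) == ["g1", "g2", "g3", "g4"]

    def test_extract_markers_signed_ranking(self):
        assert extract_markers(self._model(), "A", 1) == [("g1", 3.0)]
        assert [g for g, _ in extract_markers(self._model(), "B", 10)] == [
            "g3", "g2", "g4", "g1",
        ]

    def test_extract_markers_unknown_class(self):
        with pytest.raises(ValidationError, match="unknown class"):
            extract_markers(self._model(), "Z", 1)

    def test_planted_marker_recovery(self, small_separable):
        config = TrainingConfig(seed=0, epochs=30, batch_size=30, n_top_genes=10)
        model, _ = fit_round(small_separable["X"], small_separable["labels"], config)
        selected = set(select_top_features(model, small_separable["cfg"].markers_per_type))
        for cls, markers in small_separable["truth"].items():
            hit = len(set(markers) & selected) / len(markers)
            assert hit >= 0.9
            top10 = {g for g, _ in extract_markers(model, cls, 10)}
            assert len(top10 & set(markers)) >= 8


class TestTwoRound:
    def test_feature_genes_are_selected_subset(self, small_separable):
        config = TrainingConfig(seed=0, epochs=10, batch_size=30, n_top_genes=5)
        model, _ = train_two_round(small_separable["X"], small_separable["labels"], config)
        assert set(model.feature_genes) <= set(small_separable["X"].gene_ids)
        assert len(model.feature_genes) <= 3 * config.n_top_genes

    def test_n_top_equal_to_gene_count_degenerates(self, small_separable):
        X = small_separable["X"]
        config = TrainingConfig(seed=0, epochs=5, batch_size=30, n_top_genes=X.n_genes)
        model, _ = train_two_round(X, small_separable["labels"], config)
        assert model.feature_genes == X.gene_ids


class TestPrediction:
    def test_zero_model_uniform(self):
        model = ClassifierModel(
            class_names=["A", "B", "C", "D"],
            feature_genes=["g1", "g2"],
            weights=np.zeros((4, 2)),
            intercepts=np.zeros(4),
        )
        X = NormalizedMatrix(np.array([[1.0, 2.0]]), ["c"], ["g1", "g2"])
        res = predict_probabilities(model, X)
        np.testing.assert_allclose(res.probabilities, 0.25)

    def test_two_class_closed_form(self):
        model = ClassifierModel(
            class_names=["A", "B"],
            feature_genes=["g1", "g2"],
            weights=np.array([[1.0, 0.0], [0.0, 1.0]]),
            intercepts=np.zeros(2),
        )
        X = NormalizedMatrix(np.array([[1.0, 0.0]]), ["c"], ["g1", "g2"])
        res = predict_probabilities(model, X)
        e = np.e
        np.testing.assert_allclose(
            res.probabilities[0], [e / (e + 1), 1 / (e + 1)], rtol=1e-12
        )
        assert res.predicted_label == ["A"]
        assert res.confidence[0] == pytest.approx(e / (e + 1))

    def test_unassigned_threshold(self):
        model = ClassifierModel(
            class_names=["A", "B"],
            feature_genes=["g1", "g2"],
            weights=np.array([[1.0, 0.0], [0.0, 1.0]]),
            intercepts=np.zeros(2),
        )
        X = NormalizedMatrix(np.array([[1.0, 0.0]]), ["c"], ["g1", "g2"])
        res = predict_probabilities(model, X, unassigned_threshold=0.8)
        assert res.predicted_label == [UNASSIGNED]  # max prob ~0.73 < 0.8

    def test_probability_rows_sum_to_one(self, benchmark_model, benchmark_split):
        res = predict_probabilities(benchmark_model["model"], benchmark_split["Xte"])
        np.testing.assert_allclose(res.probabilities.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(res.probabilities > 0) and np.all(res.probabilities < 1)

    def test_gene_permutation_invariance(self, small_separable):
        config = TrainingConfig(seed=0, epochs=10, batch_size=30, n_top_genes=10)
        model, _ = train_two_round(small_separable["X"], small_separable["labels"], config)
        X = small_separable["X"]
        rng = np.random.default_rng(1)
        perm = rng.permutation(X.n_genes)
        Xp = NormalizedMatrix(
            X.values[:, perm], X.cell_ids, [X.gene_ids[j] for j in perm]
        )
        a = predict_probabilities(model, X)
        b = predict_probabilities(model, Xp)
        np.testing.assert_allclose(a.probabilities, b.probabilities, atol=1e-12)


class TestShrinkage:
    def test_weight_norm_non_increasing_in_lambda(self, small_separable):
        norms = []
        for lam in [1e-4, 1e-2, 1e0, 1e2]:
            est = CellTypeClassifier(
                two_round=False, l2_strength=lam, epochs=20, batch_size=30,
                random_state=0,
            )
            est.fit(small_separable["X"].values, small_separable["labels"])
            norms.append(np.linalg.norm(est.coef_))
        assert all(b <= a + 1e-12 for a, b in zip(norms, norms[1:]))


class TestUpdateModel:
    def _corpora(self, small_separable):
        X = small_separable["X"]
        labels = small_separable["labels"]
        mask = labels != "type03"
        old_X = NormalizedMatrix(
            X.values[mask], [c for c, m in zip(X.cell_ids, mask) if m], X.gene_ids
        )
        new_X = NormalizedMatrix(
            X.values[~mask], [c for c, m in zip(X.cell_ids, mask) if not m], X.gene_ids
        )
        return (old_X, labels[mask]), (new_X, labels[~mask])

    def test_new_class_added_and_version_incremented(self, small_separable):
        old, new = self._corpora(small_separable)
        config = TrainingConfig(seed=0, epochs=10, batch_size=30, n_top_genes=10)
        old_model, _ = train_two_round(old[0], old[1], config)
        hierarchy = small_separable["hierarchy"]
        updated = update_model(old_model, old, new, hierarchy, config)
        assert set(updated.class_names) == {"type01", "type02", "type03"}
        assert updated.version == old_model.version + 1
        assert len(updated.provenance) == len(old_model.provenance) + 1

    def test_label_missing_from_hierarchy_rejected(self, small_separable):
        old, new = self._corpora(small_separable)
        config = TrainingConfig(seed=0, epochs=5, batch_size=30, n_top_genes=10)
        old_model, _ = train_two_round(old[0], old[1], config)
        bad_hierarchy = LabelHierarchy({"type01": "g1", "type02": "g1"})
        with pytest.raises(ValidationError, match="missing from hierarchy"):
            update_model(old_model, old, new, bad_hierarchy, config)

    def test_empty_new_corpus_is_noop_retrain(self, small_separable):
        old, _ = self._corpora(small_separable)
        config = TrainingConfig(seed=0, epochs=5, batch_size=30, n_top_genes=10)
        old_model, _ = train_two_round(old[0], old[1], config)
        updated = update_model(old_model, old, None, small_separable["hierarchy"], config)
        assert updated.version == 2
        assert set(updated.class_names) == set(old_model.class_names)
        assert "no-op" in updated.provenance[-1]


class TestSerialization:
    def test_round_trip_exact(self, tmp_path, small_separable):
        config = TrainingConfig(seed=0, epochs=5, batch_size=30, n_top_genes=10)
        model, _ = train_two_round(small_separable["X"], small_separable["labels"], config)
        p = str(tmp_path / "model.json")
        save_model(model, p)
        back = load_model(p)
        assert back.class_names == model.class_names
        assert back.feature_genes == model.feature_genes
        assert back.weights.tobytes() == model.weights.tobytes()
        assert back.intercepts.tobytes() == model.intercepts.tobytes()
        assert back.version == model.version
        assert back.normalization == model.normalization

    def test_truncated_file_rejected(self, tmp_path, small_separable):
        config = TrainingConfig(seed=0, epochs=5, batch_size=30, n_top_genes=10)
        model, _ = train_two_round(small_separable["X"], small_separable["labels"], config)
        p = tmp_path / "model.json"
        save_model(model, str(p))
        p.write_text(p.read_text()[: len(p.read_text()) // 2])
        with pytest.raises(ValidationError, match="parse"):
            load_model(str(p))

    def test_format_version_mismatch(self, tmp_path):
        p = tmp_path / "model.json"
        p.write_text('{"format_version": 99}\n')
        with pytest.raises(ValidationError, match="expected 1, found 99"):
            load_model(str(p))

    def test_single_class_model_cannot_exist(self):
        with pytest.raises(ValidationError, match="at least 2 classes"):
            ClassifierModel(
                class_names=["A"], feature_genes=["g"],
                weights=np.zeros((1, 1)), intercepts=np.zeros(1),
            )

    def test_seed_determinism_bitwise(self, tmp_path, small_separable):
        config = TrainingConfig(seed=9, epochs=5, batch_size=30, n_top_genes=10)
        paths = []
        for name in ("a.json", "b.json"):
            model, _ = train_two_round(
                small_separable["X"], small_separable["labels"], config
            )
            p = tmp_path / name
            save_model(model, str(p))
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    def test_different_seeds_differ(self, tmp_path, small_separable):
        blobs = []
        for seed in (1, 2):
            config = TrainingConfig(seed=seed, epochs=5, batch_size=30, n_top_genes=10)
            model, _ = train_two_round(
                small_separable["X"], small_separable["labels"], config
            )
            p = tmp_path / f"{seed}.json"
            save_model(model, str(p))
            blobs.append(p.read_bytes())
        assert blobs[0] != blobs[1]
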