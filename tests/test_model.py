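import numpy as np
import pytest

from treestrat import (
    BinaryDataset,
    CutSolution,
    FitConfig,
    SchemaError,
    TreeTopology,
    evaluate,
    fit,
    identify_module_function,
    load_model,
    random_planted_truth,
    sample_dataset,
    save_model,
)

from .conftest import random_dataset


class TestIdentifyModuleFunction:
    def test_zero_graph_gives_constant_function(self):
        cut = CutSolution(np.zeros(8), 0.0, "exact")
        func = identify_module_function(cut, 1)
        assert (func.lookup == 0).all()

    def test_forced_two_vertex_partition(self):
        cut = CutSolution(np.array([0, 1]), 1.0, "exact")
        func = identify_module_function(cut, 1)
        assert func(1) == 0 and func(2) == 1

    def test_canonical_orientation_vertex_one_to_zero(self):
        cut = CutSolution(np.array([1, 0, 1]), 2.0, "exact")
        func = identify_module_function(cut, 1)
        assert func.lookup.tolist() == [0, 1, 0]

    def test_planted_bipartition_recovered(self):
        """A graph whose edges only join the two level sets of a Boolean
        function is cut exactly along that function (or its complement)."""
        planted = np.array([0, 1, 1, 0, 1, 0, 0, 1])
        W = np.zeros((8, 8))
        for a in range(8):
            for b in range(8):
                if planted[a] != planted[b]:
                    W[a, b] = 1
        from treestrat import solve_maxcut_exact

        func = identify_module_function(solve_maxcut_exact(W), 1)
        flip = func.lookup[0] != planted[0]
        assert np.array_equal(func.lookup ^ flip, planted)


class TestFit:
    def test_planted_recovery_noiseless(self, simple_truth, exhaustive_dataset):
        model = fit(exhaustive_dataset, simple_truth.topology, FitConfig(seed=0))
        preds = model.predict(exhaustive_dataset.X)
        assert (preds["label"].to_numpy() == exhaustive_dataset.y).all()
        assert not preds["out_of_support"].any()

    def test_module_functions_match_planted_up_to_complement(
        self, simple_truth, fitted_model
    ):
        for learned, planted in zip(
            fitted_model.module_functions, simple_truth.module_lookups
        ):
            flip = learned.lookup[0] != planted[0]
            assert np.array_equal(learned.lookup ^ flip, planted)

    def test_all_labels_zero(self, simple_topology):
        ds = random_dataset(simple_topology, 50, seed=1, label_prob=0.0)
        with pytest.warns(UserWarning, match="single class"):
            model = fit(ds, simple_topology, FitConfig(seed=0))
        preds = model.predict(ds.X)
        assert (preds["risk"] == 0.0).all()
        assert (preds["label"] == 0).all()

    def test_duplicated_dataset_gives_identical_model(self, simple_topology):
        ds = random_dataset(simple_topology, 80, seed=6)
        doubled = BinaryDataset(
            np.vstack([ds.X, ds.X]), np.concatenate([ds.y, ds.y]),
            ds.feature_names,
        )
        a = fit(ds, simple_topology, FitConfig(seed=4))
        b = fit(doubled, simple_topology, FitConfig(seed=4))
        for fa, fb in zip(a.module_functions, b.module_functions):
            assert np.array_equal(fa.lookup, fb.lookup)
        assert np.array_equal(a.output.func, b.output.func)
        assert np.allclose(a.output.risk, b.output.risk)
        assert np.array_equal(2 * a.output.counter1, b.output.counter1)

    def test_deterministic_given_seed(self, simple_topology):
        ds = random_dataset(simple_topology, 120, seed=2)
        a = fit(ds, simple_topology, FitConfig(seed=33))
        b = fit(ds, simple_topology, FitConfig(seed=33))
        assert np.array_equal(a.output.risk, b.output.risk)
        for fa, fb in zip(a.module_functions, b.module_functions):
            assert np.array_equal(fa.lookup, fb.lookup)


class TestPrediction:
    def test_risk_ratio_from_counters(self, fitted_model):
        """Risk at each seen configuration is exactly counter1/(c0+c1)."""
        out = fitted_model.output
        seen = ~out.unseen
        expected = out.counter1[seen] / (out.counter0[seen] + out.counter1[seen])
        assert np.array_equal(out.risk[seen], expected)

    def test_label_risk_consistency_over_all_configurations(self, fitted_model):
        out = fitted_model.output
        for i in range(len(out.func)):
            if out.unseen[i]:
                assert out.func[i] == fitted_model.output.default_label
            elif out.risk[i] > 0.5:
                assert out.func[i] == 1
            elif out.risk[i] < 0.5:
                assert out.func[i] == 0
            else:  # tie: risk exactly 0.5 resolves to flagging risk
                assert out.func[i] == 1

    def test_tie_resolves_to_one(self, simple_topology):
        row = [0, 1, 0, 1, 0, 0, 1]
        ds = BinaryDataset(
            np.array([row, row]),
            np.array([0, 1]),
            simple_topology.feature_names,
        )
        model = fit(ds, simple_topology, FitConfig(seed=0))
        assert model.predict_risk(row) == 0.5
        assert model.predict_label(row) == 1

    def test_out_of_support_gets_prevalence(self, simple_topology):
        """Configurations never reached in training fall back to the
        training prevalence with the out-of-support flag raised."""
        ds = random_dataset(simple_topology, 6, seed=12, label_prob=0.4)
        model = fit(ds, simple_topology, FitConfig(seed=0))
        if model.metadata["n_unseen_configurations"] == 0:
            pytest.skip("tiny dataset happened to cover every configuration")
        preds = model.predict(ds.X)
        assert not preds["out_of_support"].any()  # training rows are seen
        assert model.output.default_risk == pytest.approx(ds.y.mean())

    def test_shape_error_on_wrong_length(self, fitted_model):
        from treestrat import ShapeError

        with pytest.raises(ShapeError):
            fitted_model.predict_risk([0, 1])


class TestEvaluate:
    def test_perfect_predictions(self, fitted_model, exhaustive_dataset):
        metrics = evaluate(fitted_model, exhaustive_dataset)
        assert metrics["accuracy"] == 1.0
        assert metrics["f1"] == 1.0
        assert metrics["roc_auc"] == 1.0

    def test_hand_built_confusion_table(self, simple_topology):
        """TP=3, FP=1, FN=1, TN=5 gives precision = recall = 0.75."""
        truth = random_planted_truth([3, 2, 2], seed=21)
        ds = sample_dataset(truth, mode="exhaustive")
        model = fit(ds, truth.topology, FitConfig(seed=0))
        preds = model.predict(ds.X)["label"].to_numpy()
        pos = np.flatnonzero(preds == 1)
        neg = np.flatnonzero(preds == 0)
        rows = np.concatenate([pos[:4], neg[:6]])
        y = np.concatenate([[1, 1, 1, 0], [1, 0, 0, 0, 0, 0]]).astype(np.int8)
        eval_ds = BinaryDataset(ds.X[rows], y, ds.feature_names)
        metrics = evaluate(model, eval_ds)
        assert metrics["precision"] == pytest.approx(0.75)
        assert metrics["recall"] == pytest.approx(0.75)

    def test_single_class_dataset_has_no_auc(self, fitted_model, simple_topology):
        ds = random_dataset(simple_topology, 30, seed=5, label_prob=0.0)
        with pytest.warns(UserWarning, match="ROC AUC"):
            metrics = evaluate(fitted_model, ds)
        assert metrics["roc_auc"] is None


class TestSerialization:
    def test_round_trip_predictions_identical(self, fitted_model, tmp_path):
        path = tmp_path / "model.json"
        save_model(fitted_model, path)
        loaded = load_model(path)
        rng = np.random.default_rng(0)
        X = rng.integers(0, 2, size=(1000, 7))
        a = fitted_model.predict(X)
        b = loaded.predict(X)
        assert np.array_equal(a["risk"], b["risk"])
        assert np.array_equal(a["label"], b["label"])
        assert loaded.metadata["seed"] == fitted_model.metadata["seed"]

    def test_truncated_file_raises_schema_error(self, fitted_model, tmp_path):
        path = tmp_path / "model.json"
        save_model(fitted_model, path)
        path.write_text(path.read_text()[: 100])
        with pytest.raises(SchemaError):
            load_model(path)

    def test_unknown_schema_version_refused(self, fitted_model, tmp_path):
        import json

        path = tmp_path / "model.json"
        save_model(fitted_model, path)
        payload = json.loads(path.read_text())
        payload["schema_version"] = 999
        path.write_text(json.dumps(payload))
        with pytest.raises(SchemaError, match="version"):
            load_model(path)
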