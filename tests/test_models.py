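"""Sequence classifiers: pooling heads vs brute-force oracles, gradient
correctness, early stopping, SVM baseline, training behaviour."""

import numpy as np
import pytest

from emovid.datamodel import APPEARANCE_DIM, EmotionLabel, FeatureSequence, VideoRecord
from emovid.models import (
    BINARY_CLASSES,
    MULTICLASS_CLASSES,
    DegenerateTrainingError,
    LeakageError,
    ModelConfig,
    TrainedModel,
    _init_params,
    _net_backward,
    _net_forward,
    attention_pool,
    average_pool,
    conv_pool,
    fit_svm_baseline,
    forward,
    map_to_valence,
    run_early_stopping,
    train_model,
)


# ---------------------------------------------------------------------------
# Pooling heads
# ---------------------------------------------------------------------------

class TestAveragePool:
    def test_single_frame_is_that_row(self, rng):
        H = rng.normal(size=(1, 4))
        np.testing.assert_array_equal(average_pool(H), H[0])

    def test_constant_rows_give_that_constant(self):
        H = np.tile([1.0, 2.0, 3.0], (5, 1))
        np.testing.assert_allclose(average_pool(H), [1, 2, 3])

    def test_matches_column_mean_oracle(self, rng):
        H = rng.normal(size=(4, 3))
        oracle = [sum(H[t, j] for t in range(4)) / 4 for j in range(3)]
        np.testing.assert_allclose(average_pool(H), oracle, atol=1e-12)

    def test_mask_excludes_padded_frames(self, rng):
        H = rng.normal(size=(2, 5, 3))
        mask = np.array([[1, 1, 1, 0, 0], [1, 1, 1, 1, 1]], float)
        out = average_pool(H, mask)
        np.testing.assert_allclose(out[0], H[0, :3].mean(axis=0))


class TestAttentionPool:
    def test_zero_parameters_reproduce_average_bitwise(self, rng):
        H = rng.normal(size=(3, 7, 5))
        mask = np.ones((3, 7))
        mask[1, 4:] = 0
        pooled, alpha = attention_pool(H, np.zeros((5, 5)), np.zeros(5), np.zeros(5), mask)
        avg = average_pool(H, mask)
        assert (pooled == avg).all()  # exact, not approximate
        np.testing.assert_allclose(alpha.sum(axis=1), 1.0)

    def test_single_frame_gets_weight_one(self, rng):
        H = rng.normal(size=(1, 4))
        W, b, c = rng.normal(size=(4, 4)), rng.normal(size=4), rng.normal(size=4)
        pooled, alpha = attention_pool(H, W, b, c)
        np.testing.assert_allclose(alpha, [1.0])
        np.testing.assert_allclose(pooled, H[0])

    def test_matches_two_loop_oracle(self, rng):
        T, h = 6, 4
        H = rng.normal(size=(T, h))
        W, b, c = rng.normal(size=(h, h)), rng.normal(size=h), rng.normal(size=h)
        # literal evaluation of the formulas
        scores = [np.tanh(W @ H[t] + b) @ c for t in range(T)]
        e = np.exp(scores - max(scores))
        a = e / e.sum()
        oracle = sum(a[t] * H[t] for t in range(T))
        pooled, alpha = attention_pool(H, W, b, c)
        np.testing.assert_allclose(pooled, oracle, atol=1e-12)
        np.testing.assert_allclose(alpha, a, atol=1e-12)


class TestConvPool:
    def test_identity_kernel_reduces_to_time_mean(self, rng):
        H = rng.normal(size=(5, 3))
        kernel = np.zeros((3, 3))
        kernel[1] = 1.0  # centre tap only
        np.testing.assert_allclose(conv_pool(H, kernel), H.mean(axis=0), atol=1e-12)

    def test_single_frame_uses_centre_tap_with_zero_padding(self, rng):
        H = rng.normal(size=(1, 3))
        kernel = rng.normal(size=(3, 3))
        np.testing.assert_allclose(conv_pool(H, kernel), kernel[1] * H[0], atol=1e-12)

    def test_matches_sliding_window_oracle(self, rng):
        T, h = 7, 4
        H = rng.normal(size=(T, h))
        kernel = rng.normal(size=(3, h))
        bias = rng.normal(size=h)
        padded = np.vstack([np.zeros(h), H, np.zeros(h)])
        y = np.array(
            [
                sum(kernel[k] * padded[t + k] for k in range(3)) + bias
                for t in range(T)
            ]
        )
        np.testing.assert_allclose(conv_pool(H, kernel, bias), y.mean(axis=0), atol=1e-12)

    def test_all_heads_output_h_dimensions(self, rng):
        H = rng.normal(size=(6, 5))
        assert average_pool(H).shape == (5,)
        assert attention_pool(H, np.zeros((5, 5)), np.zeros(5), np.zeros(5))[0].shape == (5,)
        assert conv_pool(H, np.zeros((3, 5))).shape == (5,)


# ---------------------------------------------------------------------------
# Gradient correctness of the full network
# ---------------------------------------------------------------------------

class TestGradients:
    @pytest.mark.parametrize("head", ["average", "attention", "convolution"])
    def test_backprop_matches_finite_differences(self, head, rng):
        cfg = ModelConfig(task="binary", head=head, gru_layers=2, gru_hidden=4,
                          mlp_hidden=(5,), seed=0)
        params = _init_params(cfg, 3, rng)
        for k in params:  # nonzero attention params for a meaningful check
            if k.startswith("att"):
                params[k] = rng.normal(0, 0.5, size=params[k].shape)
        X = rng.normal(size=(3, 6, 3))
        mask = np.ones((3, 6))
        mask[1, 4:] = 0
        X[1, 4:] = 0
        y = np.array([0, 1, 0])

        def loss():
            p, _ = _net_forward(params, cfg, X, mask)
            return -np.mean(np.log(p[np.arange(3), y]))

        _, cache = _net_forward(params, cfg, X, mask)
        grads = _net_backward(params, cfg, cache, y)
        eps = 1e-6
        for k, v in params.items():
            flat = v.reshape(-1)
            for idx in range(0, flat.size, max(1, flat.size // 5)):
                orig = flat[idx]
                flat[idx] = orig + eps
                lp = loss()
                flat[idx] = orig - eps
                lm = loss()
                flat[idx] = orig
                num = (lp - lm) / (2 * eps)
                assert grads[k].reshape(-1)[idx] == pytest.approx(num, abs=5e-7)

    def test_masked_frames_do_not_influence_output(self, rng):
        cfg = ModelConfig(task="binary", head="attention", gru_layers=1, gru_hidden=4,
                          mlp_hidden=(5,), seed=1)
        params = _init_params(cfg, 3, rng)
        X = rng.normal(size=(1, 6, 3))
        mask = np.ones((1, 6))
        mask[0, 4:] = 0
        p1, _ = _net_forward(params, cfg, X, mask)
        X2 = X.copy()
        X2[0, 4:] = 99.0  # garbage in padded frames
        p2, _ = _net_forward(params, cfg, X2, mask)
        np.testing.assert_allclose(p1, p2, atol=1e-12)


# ---------------------------------------------------------------------------
# Early stopping
# ---------------------------------------------------------------------------

class TestEarlyStopping:
    def test_hand_traced_plateau(self):
        # improvements at epochs 1 and 2, then a plateau; patience 3 fires
        # after epochs 3, 4, 5 without improvement
        history = [0.5, 0.6, 0.6, 0.6, 0.6, 0.6, 0.6]
        assert run_early_stopping(history, patience=3) == (5, 2)

    def test_monotone_improvement_never_stops(self):
        history = [0.1 * i for i in range(1, 11)]
        assert run_early_stopping(history, patience=3) == (10, 10)

    def test_equal_values_do_not_count_as_improvement(self):
        assert run_early_stopping([0.5, 0.5, 0.5], patience=2) == (3, 1)

    @pytest.mark.parametrize("patience", [1, 5, 30])
    def test_matches_naive_replay(self, patience, rng):
        history = list(rng.random(60))
        # naive hand-executed trace
        best, best_e, since, stop = -1.0, 0, 0, len(history)
        for e, v in enumerate(history, 1):
            if v > best:
                best, best_e, since = v, e, 0
            else:
                since += 1
            if since >= patience:
                stop = e
                break
        assert run_early_stopping(history, patience) == (stop, best_e)


# ---------------------------------------------------------------------------
# SVM baseline
# ---------------------------------------------------------------------------

class TestSvmBaseline:
    def test_separable_gaussians_reach_training_uar_one(self, rng):
        X = np.vstack([rng.normal(0, 1, (100, 35)), rng.normal(6, 1, (100, 35))])
        y = np.array(["a"] * 100 + ["b"] * 100)
        model = fit_svm_baseline(X, y)
        from emovid.evaluation import contingency, uar

        assert uar(contingency(list(y), list(model.predict(X)), ["a", "b"])) == 1.0

    def test_shuffled_labels_stay_in_chance_band(self, rng):
        X = rng.normal(size=(200, 35))
        y = rng.permutation(np.array(["a", "b"] * 100))
        model = fit_svm_baseline(X[:150], y[:150])
        acc = np.mean(model.predict(X[150:]) == y[150:])
        assert 0.25 <= acc <= 0.75  # wide band around 0.5 for n=50

    def test_deterministic_fit(self, rng):
        X = rng.normal(size=(60, 35))
        y = np.array(["a", "b", "c"] * 20)
        p1 = fit_svm_baseline(X, y).predict(X)
        p2 = fit_svm_baseline(X, y).predict(X)
        np.testing.assert_array_equal(p1, p2)

    def test_single_class_rejected(self, rng):
        with pytest.raises(DegenerateTrainingError):
            fit_svm_baseline(rng.normal(size=(10, 35)), ["a"] * 10)


# ---------------------------------------------------------------------------
# Training and inference
# ---------------------------------------------------------------------------

def _labelled_records(rng, n_per_class=8, subjects=("sA", "sB"), t=10):
    """Binary-separable toy records: JOY vs ANGER via a mean shift."""
    records = []
    for lab, shift in ((EmotionLabel.JOY, 1.0), (EmotionLabel.ANGER, -1.0)):
        for i in range(n_per_class):
            values = shift + rng.normal(0, 0.3, size=(t, APPEARANCE_DIM))
            values = np.clip(values, -4, 4)
            records.append(
                VideoRecord(subjects[i % len(subjects)], lab, FeatureSequence(values))
            )
    return records


class TestTrainModel:
    def _cfg(self, **kw):
        defaults = dict(task="binary", head="average", gru_layers=1, gru_hidden=8,
                        mlp_hidden=(8,), max_epochs=15, patience=20, batch_size=8, seed=0)
        defaults.update(kw)
        return ModelConfig(**defaults)

    def test_learns_a_separable_binary_problem(self, rng):
        train = _labelled_records(rng, subjects=("sA", "sB"))
        val = _labelled_records(rng, n_per_class=4, subjects=("sC",))
        model = train_model(train, val, self._cfg())
        assert max(model.history) >= 0.9
        assert model.best_epoch <= len(model.history)

    def test_subject_overlap_raises_leakage_error(self, rng):
        train = _labelled_records(rng, subjects=("sA",))
        val = _labelled_records(rng, subjects=("sA",))
        with pytest.raises(LeakageError):
            train_model(train, val, self._cfg())

    def test_empty_split_and_single_class_rejected(self, rng):
        train = _labelled_records(rng, subjects=("sA",))
        with pytest.raises(ValueError):
            train_model(train, [], self._cfg())
        mono = [r for r in train if r.label is EmotionLabel.JOY]
        val = _labelled_records(rng, subjects=("sC",))
        with pytest.raises(DegenerateTrainingError):
            train_model(mono, val, self._cfg())

    def test_patience_beyond_max_epochs_runs_all_epochs(self, rng):
        train = _labelled_records(rng, n_per_class=4, subjects=("sA",))
        val = _labelled_records(rng, n_per_class=2, subjects=("sC",))
        model = train_model(train, val, self._cfg(max_epochs=5, patience=50))
        assert len(model.history) == 5

    def test_seeded_training_is_reproducible(self, rng):
        train = _labelled_records(rng, n_per_class=4, subjects=("sA", "sB"))
        val = _labelled_records(rng, n_per_class=2, subjects=("sC",))
        cfg = self._cfg(max_epochs=4)
        m1 = train_model(train, val, cfg)
        m2 = train_model(train, val, cfg)
        assert m1.history == m2.history
        for k in m1.params:
            np.testing.assert_array_equal(m1.params[k], m2.params[k])

    def test_checkpoint_roundtrip(self, rng, tmp_path):
        train = _labelled_records(rng, n_per_class=4, subjects=("sA", "sB"))
        val = _labelled_records(rng, n_per_class=2, subjects=("sC",))
        model = train_model(train, val, self._cfg(max_epochs=3))
        path = tmp_path / "model.npz"
        model.save(path)
        loaded = TrainedModel.load(path)
        assert loaded.config == model.config
        assert loaded.history == model.history
        np.testing.assert_array_equal(
            forward(model, val[0].features), forward(loaded, val[0].features)
        )


class TestForward:
    def _model(self, rng, head="attention"):
        train = _labelled_records(rng, n_per_class=4, subjects=("sA", "sB"))
        val = _labelled_records(rng, n_per_class=2, subjects=("sC",))
        cfg = ModelConfig(task="binary", head=head, gru_layers=1, gru_hidden=8,
                          mlp_hidden=(8,), max_epochs=2, patience=5, seed=0)
        return train_model(train, val, cfg)

    def test_output_lies_on_the_probability_simplex(self, rng):
        model = self._model(rng)
        seq = FeatureSequence(rng.normal(size=(12, APPEARANCE_DIM)))
        p = forward(model, seq)
        assert p.shape == (2,)
        assert (p >= 0).all() and p.sum() == pytest.approx(1.0)

    def test_fixed_input_twice_is_identical(self, rng):
        model = self._model(rng)
        seq = FeatureSequence(rng.normal(size=(12, APPEARANCE_DIM)))
        np.testing.assert_array_equal(forward(model, seq), forward(model, seq))

    def test_dimension_mismatch_rejected(self, rng):
        model = self._model(rng)
        seq = FeatureSequence(rng.normal(size=(5, 2048)), feature_kind="deep")
        with pytest.raises(ValueError):
            forward(model, seq)

    def test_constant_sequence_is_frame_order_invariant(self, rng):
        """Permuting frames of a constant sequence cannot change any head."""
        for head in ("average", "attention", "convolution"):
            model = self._model(rng, head=head)
            row = rng.normal(size=APPEARANCE_DIM)
            seq = FeatureSequence(np.tile(row, (9, 1)))
            p1 = forward(model, seq)
            p2 = forward(model, FeatureSequence(np.tile(row, (9, 1))[::-1]))
            np.testing.assert_allclose(p1, p2, atol=1e-10)


class TestValenceMapping:
    def test_negative_and_positive_assignments(self):
        assert map_to_valence(EmotionLabel.ANGER) == "negative"
        assert map_to_valence(EmotionLabel.PRIDE) == "positive"

    def test_mapping_partitions_all_sixteen(self):
        vals = [map_to_valence(l) for l in EmotionLabel]
        assert vals.count("negative") == 4 and vals.count("positive") == 12

    def test_class_name_constants(self):
        assert BINARY_CLASSES == ("negative", "positive")
        assert len(MULTICLASS_CLASSES) == 16
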