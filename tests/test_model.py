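"""CRS classifier: architecture, inference contracts, training behavior."""

import numpy as np
import pytest

from crsdetect.model import (
    CnnClassifier,
    ModelConfig,
    SensorWindow,
    TrainConfig,
    build_model,
    classify,
    load_model,
    parameter_count,
    predict_proba,
    save_model,
    train,
    window_from_recording,
    windows_from_recordings,
)

# Hand tally under same padding:
#   conv1 5·5·1·8+8 = 208; conv2 3·3·8·16+16 = 1168; conv3 3·3·16·32+32 = 4640
#   feature map after two 2×1 pools: 50·6·32 = 9600
#   dense 9600·1024+1024 = 9_831_424; head 1024·K+K
PARAMS_2_CLASS = 208 + 1168 + 4640 + 9_831_424 + 1024 * 2 + 2
PARAMS_16_CLASS = 208 + 1168 + 4640 + 9_831_424 + 1024 * 16 + 16


def _toy_windows(n_per_class, n_classes=2, seed=0):
    """Separable Gaussian blobs shaped as 200×6 windows."""
    rng = np.random.default_rng(seed)
    xs, ys = [], []
    for k in range(n_classes):
        mean = np.zeros(6)
        mean[k % 6] = 2.0 * (1 + k // 6)
        xs.append(rng.normal(mean, 0.3, size=(n_per_class, 200, 6)))
        ys.extend([k] * n_per_class)
    return np.concatenate(xs).astype(np.float32), np.array(ys)


class TestArchitecture:
    def test_default_config_binary_output(self):
        m = build_model()
        assert m.layer_shapes()[-1] == (2,)

    def test_16_class_output_width(self):
        m = build_model(ModelConfig(n_classes=16))
        assert m.layer_shapes()[-1] == (16,)

    @pytest.mark.parametrize(
        "n_classes,expected",
        [(2, PARAMS_2_CLASS), (16, PARAMS_16_CLASS)],
    )
    def test_parameter_count_matches_hand_tally(self, n_classes, expected):
        m = build_model(ModelConfig(n_classes=n_classes))
        assert parameter_count(m) == expected

    def test_parameter_count_invariant_to_seed(self):
        assert parameter_count(build_model(seed=0)) == parameter_count(build_model(seed=99))

    def test_variants_share_all_but_output_layer(self):
        m2, m16 = build_model(), build_model(ModelConfig(n_classes=16))
        shapes2, shapes16 = m2.layer_shapes(), m16.layer_shapes()
        assert shapes2[:-1] == shapes16[:-1]

    def test_rejects_single_class(self):
        with pytest.raises(ValueError):
            ModelConfig(n_classes=1)


class TestInference:
    def test_untrained_model_outputs_simplex(self):
        m = build_model(seed=0)
        rng = np.random.default_rng(0)
        p = predict_proba(m, rng.normal(size=(200, 6)))
        assert p.shape == (2,)
        assert (p >= 0).all() and abs(p.sum() - 1.0) < 1e-6

    def test_inference_determinism(self):
        m = build_model(seed=0)
        w = np.random.default_rng(1).normal(size=(200, 6)).astype(np.float32)
        np.testing.assert_array_equal(predict_proba(m, w), predict_proba(m, w))

    def test_batched_equals_single_predictions(self):
        m = build_model(seed=0)
        batch = np.random.default_rng(2).normal(size=(5, 200, 6)).astype(np.float32)
        stacked = predict_proba(m, batch)
        singles = np.stack([predict_proba(m, w) for w in batch])
        np.testing.assert_allclose(stacked, singles, atol=1e-6)

    def test_wrong_shape_error_names_expected_dims(self):
        m = build_model()
        with pytest.raises(ValueError, match="200x6"):
            predict_proba(m, np.zeros((100, 6)))

    def test_window_validation(self):
        with pytest.raises(ValueError):
            SensorWindow(np.zeros((200, 5)))
        with pytest.raises(ValueError):
            SensorWindow(np.full((200, 6), np.nan))

    def test_classify_tie_breaks_to_lowest_index(self):
        m = build_model(seed=0)
        # zero the output head: logits identical → uniform probabilities → tie
        head = m.layers[-1]
        head.params[0][...] = 0
        head.params[1][...] = 0
        label, score = classify(m, np.random.default_rng(3).normal(size=(200, 6)))
        assert label == 0
        assert abs(score - 0.5) < 1e-9

    def test_classify_returns_argmax_probability(self):
        m = build_model(seed=0)
        w = np.random.default_rng(4).normal(size=(200, 6))
        label, score = classify(m, w)
        p = predict_proba(m, w)
        assert label == int(np.argmax(p))
        assert score == pytest.approx(float(p.max()))


class TestTraining:
    def test_zero_epochs_leaves_model_unchanged(self):
        m = build_model(seed=0)
        before = [p.copy() for l in m.layers for p in l.params]
        x, y = _toy_windows(4)
        history = train(m, x, y, TrainConfig(epochs=0, seed=0))
        assert history == []
        after = [p for l in m.layers for p in l.params]
        for b, a in zip(before, after):
            np.testing.assert_array_equal(b, a)

    def test_single_class_input_rejected(self):
        m = build_model(seed=0)
        x, _ = _toy_windows(4)
        with pytest.raises(ValueError, match="2 classes"):
            train(m, x, np.zeros(len(x), dtype=int), TrainConfig(epochs=1))

    def test_seeded_training_reproducible(self):
        x, y = _toy_windows(6)
        weights = []
        for _ in range(2):
            m = build_model(seed=5)
            train(m, x, y, TrainConfig(epochs=2, seed=5))
            weights.append(np.concatenate([p.ravel() for l in m.layers for p in l.params]))
        np.testing.assert_array_equal(weights[0], weights[1])

    def test_loss_decreases_on_separable_data(self):
        m = build_model(seed=0)
        x, y = _toy_windows(16)
        history = train(m, x, y, TrainConfig(epochs=4, seed=0))
        assert history[-1]["loss"] < history[0]["loss"]

    def test_overfits_32_memorized_windows(self):
        # capacity check: training loss near zero well within 100 epochs
        m = build_model(seed=1)
        rng = np.random.default_rng(7)
        x = rng.normal(size=(32, 200, 6)).astype(np.float32)
        y = rng.integers(0, 2, 32)
        y[:2] = [0, 1]  # both classes present
        history = train(m, x, y, TrainConfig(epochs=40, seed=1))
        assert history[-1]["loss"] < 0.1

    def test_normalization_stats_fit_once_on_training_data(self):
        m = build_model(seed=0)
        x, y = _toy_windows(4)
        train(m, x, y, TrainConfig(epochs=1, seed=0))
        mean_after_first = m.norm_mean.copy()
        train(m, x * 100, y, TrainConfig(epochs=1, seed=0))
        np.testing.assert_array_equal(m.norm_mean, mean_after_first)

    def test_labelled_sensor_windows_accepted(self):
        m = build_model(seed=0)
        x, y = _toy_windows(3)
        windows = [SensorWindow(v, label=int(lab)) for v, lab in zip(x, y)]
        history = train(m, windows, tc=TrainConfig(epochs=1, seed=0))
        assert len(history) == 1


class TestCheckpointRoundTrip:
    def test_save_load_preserves_predictions(self, tmp_path):
        m = build_model(seed=2)
        x, y = _toy_windows(4)
        train(m, x, y, TrainConfig(epochs=1, seed=2))
        path = tmp_path / "model.npz"
        save_model(m, path)
        restored = load_model(path)
        w = np.random.default_rng(8).normal(size=(200, 6)).astype(np.float32)
        np.testing.assert_allclose(predict_proba(m, w), predict_proba(restored, w), atol=1e-7)
        assert restored.config == m.config


class TestWindowAssembly:
    def test_trial_tiles_to_200_rows(self, small_cohort):
        _, recordings, _ = small_cohort
        w = window_from_recording(recordings[0])
        assert w.shape == (200, 6)
        # two repeats of a 100-sample trial: halves are identical in the
        # gyro channels (gravity filter state differs only transiently)
        np.testing.assert_array_equal(w[:100, 3:], w[100:, 3:])

    def test_binary_and_multiclass_labels(self, small_cohort):
        _, recordings, _ = small_cohort
        x, y, pids, names = windows_from_recordings(recordings)
        assert x.shape == (len(recordings), 200, 6)
        assert set(np.unique(y)) == {0, 1}
        assert y.mean() == pytest.approx(1 / 16)
        _, y16, _, names16 = windows_from_recordings(recordings, binary=False)
        assert len(names16) == 16
        assert set(np.unique(y16)) == set(range(16))

    def test_cnn_classifier_adapter(self):
        x, y = _toy_windows(8)
        clf = CnnClassifier(epochs=12, seed=0)
        pred = clf.fit(x, y).predict(x)
        assert (pred == y).mean() >= 0.9
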