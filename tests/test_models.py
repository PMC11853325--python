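"""Stratified splitting, the three architectures, training and prediction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from liftrisk import _nn, models


def feature_table(n_rows, n_features=96, n_pos=None, separable=False, seed=0):
    """Synthetic feature table in the 96+3-column layout."""
    rng = np.random.default_rng(seed)
    n_pos = n_rows // 2 if n_pos is None else n_pos
    y = np.r_[np.ones(n_pos, dtype=int), np.zeros(n_rows - n_pos, dtype=int)]
    x = rng.normal(size=(n_rows, n_features))
    if separable:
        # a wide-margin signal in every 12th column
        x[:, ::12] = (y * 4.0 - 2.0)[:, None] + 0.05 * rng.normal(
            size=(n_rows, x[:, ::12].shape[1]))
    names = [f"Sensor {c + 1}_{f}" for c in range(8)
             for f in ("Min", "Max", "Mean", "Std", "RMS", "Skewness", "Kurtosis",
                       "Crest", "Shape", "MeanAD", "MedianAD", "L2")][:n_features]
    df = pd.DataFrame(x, columns=names)
    df["Participant"] = [f"P{i % 4}" for i in range(n_rows)]
    df["EMG_Time"] = np.arange(n_rows, dtype=float)
    df["Risk"] = y
    return df


class TestStratifiedSplit:
    def test_per_class_counts(self):
        table = feature_table(1000, n_pos=400)
        split = models.stratified_split(table, 0.8, seed=0)
        y = table["Risk"].to_numpy()
        assert len(split.test) == 200
        assert y[split.test].sum() == 80
        assert y[split.train].sum() == 320

    def test_deterministic_and_partition(self):
        table = feature_table(500, n_pos=123)
        a = models.stratified_split(table, 0.8, seed=3)
        b = models.stratified_split(table, 0.8, seed=3)
        assert np.array_equal(a.train, b.train) and np.array_equal(a.test, b.test)
        union = np.sort(np.r_[a.train, a.test])
        assert np.array_equal(union, np.arange(len(table)))

    def test_degenerate_ratio_rejected(self):
        table = feature_table(100)
        for ratio in (0.0, 1.0):
            with pytest.raises(models.ModelError):
                models.stratified_split(table, ratio)

    def test_single_class_rejected(self):
        table = feature_table(100, n_pos=100)
        with pytest.raises(models.ModelError):
            models.stratified_split(table, 0.8)

    @given(st.integers(10, 300), st.integers(10, 300),
           st.floats(0.5, 0.9), st.integers(0, 5))
    def test_stratification_property(self, n_pos, n_neg, ratio, seed):
        table = feature_table(n_pos + n_neg, n_pos=n_pos, seed=seed)
        split = models.stratified_split(table, ratio, seed=seed)
        y = table["Risk"].to_numpy()
        for cls, n_cls in ((1, n_pos), (0, n_neg)):
            in_train = int(np.sum(y[split.train] == cls))
            assert abs(in_train - ratio * n_cls) <= 0.5 + 1e-9

    def test_grouped_split_keeps_participants_whole(self):
        table = feature_table(400)
        split = models.grouped_split(table, 0.75, seed=1)
        groups = table["Participant"].to_numpy()
        assert set(groups[split.train]).isdisjoint(groups[split.test])
        assert len(split.train) + len(split.test) == len(table)


class TestBuildModel:
    def test_mlp_layer_widths(self):
        model = models.build_model(models.ModelSpec("MLP"), 96)
        dense = [l for l in model.layers if isinstance(l, _nn.Dense)]
        assert [d.W.shape for d in dense] == [(96, 64), (64, 32), (32, 16), (16, 1)]
        assert isinstance(model.layers[-1], _nn.Sigmoid)

    def test_lstm_recurrent_width(self):
        model = models.build_model(models.ModelSpec("LSTM"), 96)
        lstm = model.layers[0]
        assert isinstance(lstm, _nn.LSTM)
        assert lstm.hidden == 32
        assert lstm.Wx.shape == (1, 128)

    def test_cnn_forward_on_zero_input_is_finite_probability(self):
        model = models.build_model(models.ModelSpec("CNN1D"), 96)
        out = model.forward(np.zeros((3, 96, 1)))
        assert out.shape == (3, 1)
        assert np.all(np.isfinite(out)) and np.all((out > 0) & (out < 1))

    def test_sensor_sequence_layout(self):
        spec = models.ModelSpec("CNN1D", input_layout="seq_per_sensor")
        model = models.build_model(spec, 96)
        out = model.forward(np.zeros((2, 12, 8)))
        assert out.shape == (2, 1)

    def test_unknown_architecture_rejected(self):
        with pytest.raises(models.ModelError):
            models.ModelSpec("GRU")


class TestTrainPredict:
    @pytest.mark.parametrize("arch", ["MLP", "CNN1D"])
    def test_separable_features_reach_high_training_accuracy(self, arch):
        table = feature_table(600, separable=True, seed=1)
        split = models.stratified_split(table, 0.8, seed=1)
        spec = models.ModelSpec(arch, seed=1, max_epochs=40, batch_size=64)
        trained = models.train_model(table, split, spec)
        train_table = table.iloc[split.train]
        acc = np.mean(models.predict_labels(trained, train_table)
                      == train_table["Risk"].to_numpy())
        assert acc >= 0.99

    def test_lstm_learns_separable_features(self):
        table = feature_table(400, n_features=24, separable=True, seed=2)
        split = models.stratified_split(table, 0.8, seed=2)
        spec = models.ModelSpec("LSTM", seed=2, max_epochs=40, batch_size=64)
        trained = models.train_model(table, split, spec)
        test_table = table.iloc[split.test]
        acc = np.mean(models.predict_labels(trained, test_table)
                      == test_table["Risk"].to_numpy())
        assert acc >= 0.9

    def test_label_permutation_null(self):
        """Training on permuted labels gives chance-level test accuracy."""
        accs = []
        for seed in (0, 1, 2):
            table = feature_table(3000, seed=seed)
            split = models.stratified_split(table, 0.8, seed=seed)
            spec = models.ModelSpec("MLP", seed=seed, max_epochs=15)
            trained = models.train_model(table, split, spec)
            test_table = table.iloc[split.test]
            accs.append(np.mean(models.predict_labels(trained, test_table)
                                == test_table["Risk"].to_numpy()))
        assert 0.45 <= np.mean(accs) <= 0.55

    def test_training_is_deterministic(self):
        table = feature_table(500, separable=True, seed=3)
        split = models.stratified_split(table, 0.8, seed=3)
        spec = models.ModelSpec("MLP", seed=3, max_epochs=5)
        s1 = models.predict_scores(models.train_model(table, split, spec), table)
        s2 = models.predict_scores(models.train_model(table, split, spec), table)
        assert np.array_equal(s1, s2)

    def test_non_finite_features_rejected(self):
        table = feature_table(100)
        table.iloc[3, 0] = np.nan
        split_source = feature_table(100)
        split = models.stratified_split(split_source, 0.8, seed=0)
        with pytest.raises(models.ModelError):
            models.train_model(table, split, models.ModelSpec("MLP"))

    def test_threshold_semantics(self):
        table = feature_table(200, separable=True, seed=4)
        split = models.stratified_split(table, 0.8, seed=4)
        trained = models.train_model(table, split,
                                     models.ModelSpec("MLP", seed=4, max_epochs=5))
        scores = models.predict_scores(trained, table)
        assert np.all((scores >= 0) & (scores <= 1))
        assert np.all(models.predict_labels(trained, table, threshold=1e-12) == 1)
        if np.any(scores < 1.0):
            labels = models.predict_labels(trained, table, threshold=1.0)
            assert np.all(labels[scores < 1.0] == 0)
        assert np.array_equal(models.predict_labels(trained, table, 0.5),
                              (scores >= 0.5).astype(int))

    def test_checkpoint_roundtrip(self, tmp_path):
        table = feature_table(200, separable=True, seed=5)
        split = models.stratified_split(table, 0.8, seed=5)
        trained = models.train_model(table, split,
                                     models.ModelSpec("MLP", seed=5, max_epochs=3))
        models.save_checkpoint(trained, tmp_path / "ckpt")
        loaded = models.load_checkpoint(tmp_path / "ckpt")
        assert np.array_equal(models.predict_scores(loaded, table),
                              models.predict_scores(trained, table))
        assert loaded.spec == trained.spec
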