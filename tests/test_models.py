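"""Network training, prediction, tuning and bundle persistence."""

from dataclasses import replace

import numpy as np
import pytest

import rxncontext as rc
from rxncontext.featurize import FingerprintConfig
from rxncontext.models import (
    SEARCH_SPACE,
    default_config,
    load_bundle,
    predict,
    sample_config,
    save_bundle,
    train,
    tune,
)


@pytest.fixture(scope="module")
def trained(small_synthetic):
    cfg, ds, result, X = small_synthetic
    mcfg = replace(default_config("single", seed=5), hidden_size=256,
                   epochs=12, dropout_rate=0.2, learning_rate=2e-3)
    bundle = train(result.single_table, X, mcfg, result.label_space,
                   split_seed=2)
    return bundle, result, X


class TestDefaultConfig:
    def test_single_label_architecture(self):
        cfg = default_config("single")
        assert (cfg.hidden_size, cfg.n_hidden_layers) == (1024, 1)
        assert cfg.dropout_rate == pytest.approx(0.60)
        assert cfg.learning_rate == pytest.approx(6.1e-4)
        assert (cfg.epochs, cfg.batch_size) == (10, 64)
        assert cfg.final_activation == "softmax"

    def test_multi_label_architecture(self):
        cfg = default_config("multi")
        assert (cfg.hidden_size, cfg.n_hidden_layers) == (512, 1)
        assert cfg.dropout_rate == pytest.approx(0.64)
        assert cfg.learning_rate == pytest.approx(9.2e-4)
        assert (cfg.epochs, cfg.batch_size) == (20, 64)
        assert cfg.final_activation == "softmax"


class TestTrain:
    def test_identical_seeds_reproduce_history_exactly(
        self, small_synthetic
    ):
        _, _, result, X = small_synthetic
        mcfg = replace(default_config("single", seed=7), hidden_size=64,
                       epochs=3)
        h1 = train(result.single_table, X, mcfg, result.label_space,
                   split_seed=1).history
        h2 = train(result.single_table, X, mcfg, result.label_space,
                   split_seed=1).history
        assert h1.equals(h2)

    def test_noiseless_rule_is_learned(self, trained):
        bundle, _, _ = trained
        assert bundle.history.val_metric.iloc[-1] >= 0.90

    def test_training_loss_decreases(self, trained):
        bundle, _, _ = trained
        assert (
            bundle.history.train_loss.iloc[-1]
            < bundle.history.train_loss.iloc[0]
        )

    def test_misaligned_features_raise(self, small_synthetic):
        _, _, result, X = small_synthetic
        mcfg = replace(default_config("single"), hidden_size=32, epochs=1)
        with pytest.raises(ValueError, match="align"):
            train(result.single_table, X[:-1], mcfg, result.label_space)

    def test_multi_mode_trains_with_bce(self, small_synthetic):
        _, _, result, X = small_synthetic
        mcfg = replace(default_config("multi", seed=3), hidden_size=64,
                       epochs=3)
        bundle = train(result.multi_table, X, mcfg, result.label_space,
                       split_seed=2)
        assert bundle.history.val_loss.notna().all()
        assert 0.0 <= bundle.history.val_metric.iloc[-1] <= 1.0


class TestPredict:
    def test_softmax_rows_sum_to_one(self, trained):
        bundle, _, X = trained
        scores = predict(bundle, X[:20])
        assert np.allclose(scores.sum(axis=1), 1.0, atol=1e-5)
        assert scores.min() >= 0.0

    def test_prediction_is_stateless_per_row(self, trained):
        # identical rows score identically wherever they sit in the batch
        # (up to BLAS blocking noise, well below any ranking difference)
        bundle, _, X = trained
        doubled = np.vstack([X[:5], X[:5]])
        scores = predict(bundle, doubled)
        assert np.allclose(scores[:5], scores[5:], atol=1e-6)

    def test_all_zero_fingerprint_is_valid_input(self, trained):
        bundle, _, _ = trained
        scores = predict(bundle, np.zeros((1, 1024), dtype=np.float32))
        assert scores.shape == (1, len(bundle.label_space))
        assert np.isfinite(scores).all()

    def test_wrong_feature_width_raises(self, trained):
        bundle, _, _ = trained
        with pytest.raises(ValueError, match="width"):
            predict(bundle, np.zeros((1, 100)))

    def test_mismatched_fp_config_is_refused(self, trained):
        bundle, _, X = trained
        other = FingerprintConfig(use_chirality=True)
        with pytest.raises(ValueError, match="configuration"):
            predict(bundle, X[:1], fp_config=other)


class TestBundlePersistence:
    def test_round_trip_predictions_are_bit_identical(self, trained, tmp_path):
        bundle, _, X = trained
        rng = np.random.default_rng(0)
        probe = rng.integers(-2, 2, (50, 1024)).astype(np.float32)
        save_bundle(bundle, str(tmp_path / "bundle"))
        back = load_bundle(str(tmp_path / "bundle"))
        assert np.array_equal(predict(bundle, probe), predict(back, probe))
        assert back.config == bundle.config
        assert back.label_space.contexts == bundle.label_space.contexts

    def test_corrupted_weights_raise_cleanly(self, trained, tmp_path):
        bundle, _, _ = trained
        save_bundle(bundle, str(tmp_path / "bundle"))
        (tmp_path / "bundle" / "weights.npz").write_bytes(b"not a npz file")
        with pytest.raises(ValueError, match="weights"):
            load_bundle(str(tmp_path / "bundle"))


class TestTune:
    def test_sampled_configs_stay_inside_the_search_space(self):
        rng = np.random.default_rng(0)
        for mode in ("single", "multi"):
            space = SEARCH_SPACE[mode]
            for _ in range(50):
                cfg = sample_config(mode, rng)
                assert cfg.batch_size in space["batch_size"]
                assert cfg.epochs in space["epochs"]
                assert cfg.hidden_size in space["hidden_size"]
                assert cfg.n_hidden_layers in space["n_hidden_layers"]
                lo, hi = space["learning_rate"]
                assert lo <= cfg.learning_rate <= hi
                assert 0.0 <= cfg.dropout_rate <= 0.9

    def test_single_trial_returns_that_config(self, small_synthetic,
                                              tmp_path):
        _, _, result, X = small_synthetic
        rng = np.random.default_rng(9)
        expected = sample_config("single", rng, seed=9)
        got = tune(result.single_table[:120], X[:120], "single",
                   result.label_space, n_trials=1, cv_folds=2, seed=9,
                   trial_log_path=str(tmp_path / "trials.csv"))
        assert got == expected
        assert (tmp_path / "trials.csv").exists()

    def test_fixed_seed_reproduces_the_trial_sequence(
        self, small_synthetic
    ):
        _, _, result, X = small_synthetic
        kwargs = dict(n_trials=2, cv_folds=2, seed=21)
        a = tune(result.single_table[:120], X[:120], "single",
                 result.label_space, **kwargs)
        b = tune(result.single_table[:120], X[:120], "single",
                 result.label_space, **kwargs)
        assert a == b

    def test_zero_trials_raises(self, small_synthetic):
        _, _, result, X = small_synthetic
        with pytest.raises(ValueError, match="n_trials"):
            tune(result.single_table, X, "single", result.label_space,
                 n_trials=0)
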