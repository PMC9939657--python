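import numpy as np
import pytest

import hergfit as hf
from hergfit import regressor as reg
from hergfit.errors import ModelFormatError


class TestMseLoss:
    def test_zero_for_identical(self):
        x = np.random.default_rng(0).uniform(size=(5, 9))
        assert hf.mse_loss(x, x) == 0.0

    def test_single_coordinate_unit_error(self):
        a = np.zeros((1, 9))
        b = np.zeros((1, 9))
        b[0, 3] = 1.0
        assert hf.mse_loss(a, b) == 1.0

    def test_batch_is_mean_of_singles(self):
        rng = np.random.default_rng(1)
        a, b = rng.uniform(size=(6, 9)), rng.uniform(size=(6, 9))
        singles = [hf.mse_loss(a[i:i+1], b[i:i+1]) for i in range(6)]
        assert hf.mse_loss(a, b) == pytest.approx(np.mean(singles), rel=1e-12)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            hf.mse_loss(np.zeros((2, 9)), np.zeros((3, 9)))


def model_val_mse(model):
    return model.training_log[-1]["val_mse"]


def quick_config(epochs=(15, 10), **kw):
    return hf.RegressorConfig(
        seed=0,
        stage_schedule=(
            reg.StageSpec(resolution=(97, 97), n_examples=None, epochs=epochs[0]),
            reg.StageSpec(resolution=(129, 129), n_examples=None, epochs=epochs[1]),
        ),
        **kw,
    )


class TestTrain:
    def test_beats_constant_mean_baseline(self, trained_model, training_corpus):
        train, val = training_corpus
        baseline = np.mean(np.sum((val.targets - train.targets.mean(0)) ** 2, axis=1))
        assert model_val_mse(trained_model) < baseline

    def test_overfits_tiny_set(self, small_dataset):
        # capacity check: with regularization off the net memorizes 64 examples
        tiny = reg._subset(small_dataset, 64)
        cfg = quick_config(epochs=(800, 400), alpha=0.0, learning_rate=3e-3,
                           batch_size=8)
        model = reg.train(cfg, tiny)
        assert model.training_log[-1]["final_train_mse"] < 1e-3

    def test_stage_schedule_logged(self, trained_model):
        log = trained_model.training_log
        assert [e["resolution"] for e in log] == [[97, 97], [129, 129]]
        assert log[0]["n_examples"] < log[1]["n_examples"]
        assert all(np.isfinite(e["loss_curve"]).all() for e in log)

    def test_empty_training_set_rejected(self):
        empty = hf.Dataset(traces=np.empty((0, 1540)), targets=np.empty((0, 9)),
                           theta=np.empty((0, 9)), manifest={})
        with pytest.raises(ValueError):
            reg.train(quick_config(), empty)


class TestPredict:
    def test_output_in_unit_box(self, trained_model, small_dataset):
        out = trained_model.predict_trace(small_dataset.example(0).trace)
        assert out.shape == (9,)
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_deterministic(self, trained_model, small_dataset):
        tr = small_dataset.example(1).trace
        np.testing.assert_array_equal(trained_model.predict_trace(tr),
                                      trained_model.predict_trace(tr))

    def test_resolution_mismatch_rejected(self, trained_model):
        bad = hf.Spectrogram(grid=np.ones((97, 97)))
        with pytest.raises(ValueError, match="resolution"):
            trained_model.predict(bad)

    def test_denormalizable(self, trained_model, small_dataset):
        out = trained_model.predict_trace(small_dataset.example(2).trace)
        theta = hf.from_normalized(out, trained_model.norm)
        assert np.all(theta.as_array() > 0)

    def test_rank_correlation_on_heldout(self, trained_model):
        """Predictions track the generating parameters on noiseless cells."""
        from scipy.stats import spearmanr
        ds = hf.generate_dataset(200, noise=hf.NoiseModel(sigma=0.0), seed=777)
        preds = np.stack([
            trained_model.predict_trace(hf.CurrentTrace(ds.traces[i], 100.0))
            for i in range(len(ds))
        ])
        rho = [spearmanr(preds[:, j], ds.targets[:, j]).statistic for j in range(9)]
        assert sum(r > 0 for r in rho) >= 7

    def test_better_than_random_draws(self, trained_model, staircase):
        """De-normalized predictions beat random prior draws as trace explanations."""
        ds = hf.generate_dataset(50, noise=hf.NoiseModel(sigma=0.0), seed=778)
        rand = hf.sample_params_array(n=50, seed=909)
        wins = 0
        for i in range(50):
            tr = hf.CurrentTrace(ds.traces[i], 100.0)
            pred = hf.from_normalized(trained_model.predict_trace(tr), trained_model.norm)
            r_pred = hf.objective_rmse(pred, tr, staircase)
            r_rand = hf.objective_rmse(hf.ChannelParams.from_array(rand[i]), tr, staircase)
            wins += r_pred < r_rand
        assert wins >= 40  # >= 80% of 50 cells


class TestSaveLoad:
    def test_round_trip_predicts_identically(self, trained_model, small_dataset, tmp_path):
        path = tmp_path / "m.bin"
        reg.save(trained_model, path)
        back = reg.load(path)
        tr = small_dataset.example(3).trace
        np.testing.assert_allclose(back.predict_trace(tr),
                                   trained_model.predict_trace(tr), atol=1e-6)

    def test_config_embedded(self, trained_model, tmp_path):
        path = tmp_path / "m.bin"
        reg.save(trained_model, path)
        assert reg.load(path).config == trained_model.config

    def test_truncated_file_rejected(self, trained_model, tmp_path):
        path = tmp_path / "m.bin"
        reg.save(trained_model, path)
        path.write_bytes(path.read_bytes()[:100])
        with pytest.raises(ModelFormatError):
            reg.load(path)

    def test_garbage_file_rejected(self, tmp_path):
        path = tmp_path / "junk.bin"
        path.write_bytes(b"not a model")
        with pytest.raises(ModelFormatError):
            reg.load(path)
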