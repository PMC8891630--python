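"""Flux regressor: loss analytics, architecture contracts, training, evaluation."""

import numpy as np
import pytest
from scipy import optimize

from octflux.model import (
    FluxPrediction,
    FluxRegressor,
    ModelConfig,
    TrainConfig,
    build_model,
    evaluate,
    gaussian_nll_loss,
    train,
)
from octflux.simulate import generate_dataset


class TestLossAnalytics:
    def test_zero_error_unit_sigma(self):
        # ln(1) + 0.5 ln(2 pi) = 0.91894
        assert gaussian_nll_loss([10.0], [1.0], [10.0]) == pytest.approx(
            0.9189385, abs=1e-6
        )

    def test_unit_error_adds_half(self):
        assert gaussian_nll_loss([10.0], [1.0], [11.0]) == pytest.approx(
            1.4189385, abs=1e-6
        )

    def test_sigma_argmin_equals_absolute_error(self):
        # for fixed error e, the loss is minimized at sigma = |e|
        for e in (0.5, 2.0, 7.0):
            res = optimize.minimize_scalar(
                lambda s: gaussian_nll_loss([0.0], [s], [e]),
                bounds=(1e-3, 50.0), method="bounded",
            )
            assert res.x == pytest.approx(e, rel=1e-3)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            gaussian_nll_loss([0.0], [0.0], [1.0])

    def test_batch_mean(self):
        single = gaussian_nll_loss([1.0], [2.0], [3.0])
        batch = gaussian_nll_loss([1.0, 1.0], [2.0, 2.0], [3.0, 3.0])
        assert batch == pytest.approx(single)


class TestArchitecture:
    def test_two_outputs_for_any_length(self, tiny_model):
        rng = np.random.default_rng(0)
        for length in (64, 100, 256):
            out = tiny_model.forward(rng.uniform(0, 1, (3, length)).astype(np.float32))
            assert out.shape == (3, 2)

    def test_default_config_accepts_length_512(self):
        m = build_model(seed=0)
        out = m.forward(np.zeros((1, 512), dtype=np.float32))
        assert out.shape == (1, 2)

    def test_parameter_count_deterministic(self, tiny_model_config):
        a = build_model(tiny_model_config, seed=0)
        b = build_model(tiny_model_config, seed=5)
        assert a.n_parameters == b.n_parameters > 0

    def test_input_shorter_than_kernel_rejected(self, tiny_model):
        with pytest.raises(ValueError):
            tiny_model.forward(np.zeros((1, 4), dtype=np.float32))

    def test_config_rejects_input_below_kernel(self):
        with pytest.raises(ValueError):
            ModelConfig(input_length=8, kernel_sizes=(10, 20, 40))


class TestPrediction:
    def test_sigma_strictly_positive(self, tiny_model, rng):
        preds = tiny_model.predict(rng.uniform(0, 1, (5, 64)).astype(np.float32))
        assert all(p.sigma > 0 for p in preds)
        assert all(p.flux >= 0 for p in preds)

    def test_duplicate_inputs_identical_predictions(self, tiny_model, rng):
        x = rng.uniform(0, 1, 64).astype(np.float32)
        preds = tiny_model.predict(np.stack([x, x]))
        assert preds[0] == preds[1]

    def test_batch_equals_one_by_one(self, tiny_model, rng):
        x = rng.uniform(0, 1, (6, 64)).astype(np.float32)
        batched = tiny_model.predict(x, batch_size=6)
        single = [tiny_model.predict(x[i : i + 1])[0] for i in range(6)]
        for a, b in zip(batched, single):
            assert a.flux == pytest.approx(b.flux, abs=1e-4)
            assert a.sigma == pytest.approx(b.sigma, abs=1e-4)

    def test_nan_input_rejected(self, tiny_model):
        bad = np.full((1, 64), np.nan, dtype=np.float32)
        with pytest.raises(ValueError):
            tiny_model.predict(bad)


@pytest.fixture(scope="module")
def toy_run(tiny_model_config):
    ds = generate_dataset(per_category=6, n_samples=64, rng=31)
    model = build_model(tiny_model_config, seed=1)
    cfg = TrainConfig(epochs=4, batch_size=16, seed=7)
    history = train(model, ds, cfg)
    return ds, model, cfg, history


class TestTraining:

    def test_loss_decreases(self, toy_run):
        _, _, _, history = toy_run
        assert history["train_loss"][-1] < history["train_loss"][0]

    def test_augmentation_doubles_training_set(self, toy_run, tiny_model_config):
        ds, _, cfg, history = toy_run
        n_train_frac = int(round(0.7 * len(ds)))
        assert history["n_train"] == 2 * n_train_frac
        no_aug = train(
            build_model(tiny_model_config, seed=1), ds,
            TrainConfig(epochs=1, batch_size=16, seed=7, augment_reversal=False),
        )
        assert no_aug["n_train"] == n_train_frac

    def test_identical_seeds_identical_histories(self, toy_run, tiny_model_config):
        ds, _, cfg, history = toy_run
        rerun = train(build_model(tiny_model_config, seed=1), ds, cfg)
        assert np.allclose(rerun["train_loss"], history["train_loss"])
        assert np.allclose(rerun["val_loss"], history["val_loss"])

    def test_warm_start_continues_training(self, toy_run, tiny_model_config):
        ds, model, _, history = toy_run
        more = train(model, ds, TrainConfig(epochs=1, batch_size=16, seed=8))
        assert len(more["train_loss"]) == 1

    def test_empty_split_rejected(self, tiny_model_config):
        ds = generate_dataset(per_category=1, n_samples=64, rng=32)
        with pytest.raises(ValueError):
            train(build_model(tiny_model_config, seed=0), ds,
                  TrainConfig(epochs=1, split=(0.99999, 1e-6, 1 - 0.99999 - 1e-6)))


class TestEvaluate:
    def test_perfect_predictions(self):
        truth = np.linspace(0, 120, 50)
        preds = [FluxPrediction(t, 1.0) for t in truth]
        met = evaluate(preds, truth)
        assert met.slope == pytest.approx(1.0)
        assert met.r2 == pytest.approx(1.0)

    def test_constant_predictions(self):
        truth = np.linspace(0, 120, 50)
        met = evaluate(np.full(50, 30.0), truth)
        assert met.slope == 0.0
        assert met.r2 <= 0.0

    def test_noisy_identity_matches_ols_expectation(self):
        # preds = truth + N(0, 5): slope ~ 1, R^2 ~ 1 - 25/var(truth)
        rng = np.random.default_rng(17)
        truth = rng.uniform(0, 120, 4000)
        preds = truth + rng.normal(0, 5, truth.size)
        met = evaluate(preds, truth)
        assert 0.98 < met.slope < 1.02
        assert met.r2 == pytest.approx(1 - 25 / np.var(truth), abs=0.01)

    def test_uncertainty_filter_keeps_quantile(self):
        rng = np.random.default_rng(18)
        truth = rng.uniform(0, 120, 100)
        preds = [FluxPrediction(t, s) for t, s in zip(truth, rng.uniform(1, 10, 100))]
        met = evaluate(preds, truth, uncertainty_quantile=0.5)
        assert met.n_kept == pytest.approx(50, abs=1)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            evaluate(np.array([1.0, 2.0]), np.array([1.0, 2.0]))


def test_input_size_study_harness_contract(tiny_model_config):
    """The study runs end-to-end at reduced scale and reports both methods
    per length."""
    from octflux.model import input_size_study
    from octflux.simulate import DEFAULT_DT, generate_dataset

    def generator(length):
        train_ds = generate_dataset(per_category=6, n_samples=length, rng=41)
        test_ds = generate_dataset(per_category=3, n_samples=length, rng=42)
        return train_ds, test_ds

    rows = input_size_study(
        generator, lengths=(64, 128), dt=DEFAULT_DT,
        train_config=TrainConfig(epochs=1, batch_size=16, seed=1),
    )
    assert [r["length"] for r in rows] == [64, 128]
    for r in rows:
        assert set(r) == {"length", "cnn_slope", "cnn_r2",
                          "baseline_slope", "baseline_r2"}
        assert np.isfinite(r["baseline_slope"])


class TestPersistence:
    def test_save_load_round_trip(self, tiny_model, tmp_path, rng):
        x = rng.uniform(0, 1, (4, 64)).astype(np.float32)
        before = tiny_model.predict(x)
        path = tmp_path / "model.npz"
        tiny_model.save(path)
        loaded = FluxRegressor.load(path)
        after = loaded.predict(x)
        for a, b in zip(before, after):
            assert a.flux == pytest.approx(b.flux, abs=1e-6)
            assert a.sigma == pytest.approx(b.sigma, abs=1e-6)
        assert loaded.config == tiny_model.config
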