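"""LSTM nowcaster: gradient correctness, training, prediction, grid search."""

import numpy as np
import pytest

from sfnowcast import lstm, windowing
from sfnowcast.lstm import (NowcastConfig, TrainingDivergenceError, _backward,
                            _forward, _LSTMParams, build_feature_set,
                            fit_nowcaster, get_combination, grid_search,
                            predict, standard_combinations)
from sfnowcast.windowing import WindowSample, targets

from conftest import linear_target_samples


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        """Numerical-gradient oracle: analytic BPTT gradients agree with
        central finite differences on a small random network."""
        rng = np.random.default_rng(0)
        for n_layers in (1, 2):
            params = _LSTMParams(n_features=3, hidden_dim=4, n_layers=n_layers, rng=rng)
            X = rng.normal(size=(5, 2, 3))
            y = rng.normal(size=5)

            def loss():
                yhat, _ = _forward(params, X)
                return np.mean((yhat - y) ** 2)

            yhat, caches = _forward(params, X)
            grads = _backward(params, caches, X, 2 * (yhat - y) / len(y))
            eps = 1e-6
            for name, holder, key in params.tensors():
                W = holder[key]
                flat = W.ravel()
                for idx in rng.choice(flat.size, size=min(6, flat.size), replace=False):
                    orig = flat[idx]
                    flat[idx] = orig + eps
                    lp = loss()
                    flat[idx] = orig - eps
                    lm = loss()
                    flat[idx] = orig
                    num = (lp - lm) / (2 * eps)
                    assert grads[name].ravel()[idx] == pytest.approx(num, abs=1e-5), \
                        f"{name}[{idx}] layers={n_layers}"


class TestFitNowcaster:
    def test_tiny_overfit_linear_target(self):
        """A 1-layer dim-16 model fits target = 3*(sum of features) on 20
        samples to train RMSE < 0.1 within 300 epochs."""
        samples = linear_target_samples()
        model = fit_nowcaster(NowcastConfig(hidden_layers=1, hidden_dim=16,
                                            epochs=300, seed=0), samples)
        preds = predict(model, samples)
        y = targets(samples)
        assert float(np.sqrt(np.mean((preds - y) ** 2))) < 0.1
        assert np.max(np.abs(preds - y)) < 0.5

    def test_learns_constant_target_bias(self):
        c = 0.5
        samples = [WindowSample(features=np.zeros((2, 1)), target_week=(2016, k + 1),
                                target=c, feature_names=["x"]) for k in range(10)]
        model = fit_nowcaster(NowcastConfig(hidden_layers=1, hidden_dim=16,
                                            epochs=150, seed=0), samples)
        preds = predict(model, samples)
        assert np.all(np.abs(preds - c) <= 0.05 * c)

    def test_seeded_training_is_bitwise_reproducible(self):
        samples = linear_target_samples()
        cfg = NowcastConfig(hidden_layers=2, hidden_dim=16, epochs=30, seed=5)
        a = fit_nowcaster(cfg, samples)
        b = fit_nowcaster(cfg, samples)
        assert np.array_equal(predict(a, samples), predict(b, samples))
        assert a.history.equals(b.history)

    def test_history_records_every_epoch(self):
        samples = linear_target_samples()
        model = fit_nowcaster(NowcastConfig(epochs=25, seed=0), samples, samples[:5])
        assert list(model.history.columns) == ["epoch", "train_loss", "val_loss"]
        assert len(model.history) == 25
        assert model.history["val_loss"].notna().all()

    def test_divergence_reports_epoch(self):
        samples = linear_target_samples(scale=1.0)
        cfg = NowcastConfig(epochs=50, learning_rate=1e160, seed=0)
        with pytest.raises(TrainingDivergenceError) as exc:
            fit_nowcaster(cfg, samples)
        assert exc.value.epoch >= 0

    def test_empty_train_rejected(self):
        with pytest.raises(ValueError):
            fit_nowcaster(NowcastConfig(), [])


class TestPredict:
    def test_repeat_and_permutation_equivariance(self, trained_all_sources):
        model, _, _, test = trained_all_sources
        a = predict(model, test)
        assert np.array_equal(a, predict(model, test))
        perm = np.random.default_rng(0).permutation(len(test))
        b = predict(model, [test[i] for i in perm])
        assert np.allclose(b, a[perm])

    def test_predictions_nonnegative(self, trained_all_sources):
        model, _, _, test = trained_all_sources
        assert (predict(model, test) >= 0).all()

    def test_layout_mismatch_rejected(self, trained_all_sources):
        model, *_ = trained_all_sources
        bad = [WindowSample(features=np.zeros((2, 1)), target_week=(2018, 1),
                            target=0.0, feature_names=["x"])]
        with pytest.raises(ValueError, match="layout"):
            predict(model, bad)


@pytest.fixture(scope="module")
def splits(informative_panel):
    samples = build_feature_set(informative_panel, get_combination("all_sources"))
    return windowing.split_windows(samples)


class TestGridSearch:
    def test_singleton_grid_selects_that_config(self, splits):
        train, val, _ = splits
        res = grid_search(train, val, seed=0, hidden_layers=(1,), hidden_dims=(16,),
                          epochs_grid=(150,))
        assert len(res.table) == 1
        assert (res.selected.hidden_layers, res.selected.hidden_dim,
                res.selected.epochs) == (1, 16, 150)

    def test_reduced_grid_selected_attains_table_minimum(self, splits):
        """Independent re-scan oracle: the selected config's validation RMSE
        equals the minimum of the retained table."""
        train, val, _ = splits
        res = grid_search(train, val, seed=0, hidden_layers=(1,), hidden_dims=(16, 32),
                          epochs_grid=(150, 200))
        assert len(res.table) == 4
        sel = res.table[(res.table.hidden_layers == res.selected.hidden_layers)
                        & (res.table.hidden_dim == res.selected.hidden_dim)
                        & (res.table.epochs == res.selected.epochs)]
        assert sel.val_rmse.iloc[0] == res.table.val_rmse.min()

    def test_empty_grid_rejected(self, splits):
        train, val, _ = splits
        with pytest.raises(ValueError):
            grid_search(train, val, hidden_layers=())


class TestSourceCombinations:
    def test_standard_combination_inventory(self):
        combos = standard_combinations()
        assert combos["historical_only"].sources == ()
        assert combos["historical_only"].include_lagged_deaths
        assert combos["all_sources"].n_features == 6
        assert {f"single:{s}" for s in
                ("google_trends", "youtube_trends", "twitter", "ed_visits", "phq9")
                } <= set(combos)

    def test_study_selected_configs_are_expressible(self):
        # one hidden layer everywhere; dims 32/16/64/16 all lie on the grid
        for dim in (32, 16, 64, 16):
            cfg = NowcastConfig(hidden_layers=1, hidden_dim=dim)
            assert cfg.hidden_layers in lstm.GRID_HIDDEN_LAYERS
            assert cfg.hidden_dim in lstm.GRID_HIDDEN_DIMS

    @pytest.mark.parametrize("name, n_feat", [
        ("historical_only", 1),
        ("all_sources", 6),
        ("single:google_trends", 1),
        ("online_only", 3),
        ("health_only", 2),
    ])
    def test_feature_dimension_per_combination(self, informative_panel, name, n_feat):
        samples = build_feature_set(informative_panel, get_combination(name))
        assert samples[0].features.shape == (2, n_feat)

    def test_missing_source_named_in_error(self, informative_panel):
        p = informative_panel
        crippled = p.restrict_weeks(p.weeks[0], p.weeks[-1])
        crippled.sources = crippled.sources.drop(columns=["twitter"])
        with pytest.raises(ValueError, match="twitter"):
            build_feature_set(crippled, get_combination("all_sources"))
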